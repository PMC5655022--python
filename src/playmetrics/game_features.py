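"""Per-game feature extraction against a canonical feature registry.

Each of the five games has a fixed, ordered list of named features; an
extractor always returns exactly that key set. Statistics computed over an
empty collection (e.g. no unsuccessful hits) yield the explicit
not-available marker (NaN), never silent zeros — imputation is a separate,
logged step downstream.

Registry sizes per game: boxes 29, sharing 44, pinwheel 41, creativity 41,
catdog 27 (182 in total). Percentages are stored as fractions in [0, 1].
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np

from . import kinematics as kin
from .kinematics import PlanarPath, TILT_DIRECTIONS
from .session import ExtractionConfig, GameRecording

NA = math.nan

BALL_COLOURS: tuple[str, ...] = ("red", "blue", "green", "yellow", "purple")
SHARING_CHARACTERS: tuple[int, ...] = (1, 2, 3, 4)
DISTRACTOR_GROUPS: tuple[str, ...] = ("lamps", "shelf", "bird", "pinwheel")

FLOW, TOUCH, INERTIAL = "flow", "touch", "inertial"


class Feature(NamedTuple):
    name: str
    source: str
    definition_ref: str


@dataclass(frozen=True)
class FeatureVector:
    game_id: str
    values: dict[str, float]
    config: ExtractionConfig

    def as_array(self) -> np.ndarray:
        return np.array([self.values[f.name] for f in REGISTRY[self.game_id]])


def _stats_block(prefix: str, stats: Sequence[str], ref: str, source: str) -> list[Feature]:
    return [Feature(f"{prefix}_{s}", source, ref) for s in stats]


def _boxes_features() -> list[Feature]:
    feats = [
        Feature("total_time", FLOW, "game duration"),
        Feature("total_moves", FLOW, "count of ball-drag gestures"),
    ]
    for c in BALL_COLOURS:
        feats.append(Feature(f"success_count_{c}", FLOW, "correct-box placements of this ball"))
    for c in BALL_COLOURS:
        feats.append(Feature(f"fail_count_{c}", FLOW, "wrong-box placements of this ball"))
    feats += [
        Feature("success_move_rate", FLOW, "successful placements per second"),
        Feature("fail_move_rate", FLOW, "unsuccessful placements per second"),
        Feature("total_move_rate", FLOW, "all ball moves per second"),
    ]
    for scope in ("all", "short"):
        feats.append(Feature(f"{scope}_path_count", TOUCH, "box-ending drag paths"))
        feats += _stats_block(f"{scope}_efficiency", ("avg", "min", "max"), "straight/actual path ratio", TOUCH)
        feats += _stats_block(f"{scope}_speed", ("avg", "min", "max"), "mean drag speed per path", TOUCH)
    return feats


def _sharing_features() -> list[Feature]:
    feats = [
        Feature("total_time", FLOW, "game duration"),
        Feature("action_rate", FLOW, "all actions per second"),
        Feature("success_action_rate", FLOW, "food table-to-plate drags per second"),
        Feature("avg_round_length", FLOW, "mean seconds per round"),
        Feature("food_to_plate_rate", FLOW, "food drags from table per second"),
        Feature("object_table_rate", FLOW, "other-object table-to-plate drags per second"),
        Feature("object_plate_rate", FLOW, "other-object plate-to-plate drags per second"),
    ]
    for g in DISTRACTOR_GROUPS + ("all",):
        feats.append(Feature(f"distractor_rate_{g}", FLOW, "distractor uses per second"))
    for ch in SHARING_CHARACTERS:
        feats += _stats_block(f"char{ch}_efficiency", ("avg", "min", "max", "median"), "straight/actual drag ratio", TOUCH)
        feats += _stats_block(f"char{ch}_speed", ("avg", "min", "max", "median"), "mean drag speed per path", TOUCH)
    return feats


def _pinwheel_features() -> list[Feature]:
    feats = [
        Feature("total_time", FLOW, "game duration"),
        Feature("success_hit_rate", FLOW, "successful petal hits per second"),
        Feature("fail_hit_rate", FLOW, "unsuccessful petal hits per second"),
        Feature("ball_fall_rate", FLOW, "ball falls per second"),
        Feature("round_rate", FLOW, "rounds per second"),
        Feature("touch_rate", TOUCH, "screen touches per second"),
        Feature("rt_success_mean", TOUCH, "mean round-to-hit time, successful"),
        Feature("rt_fail_mean", TOUCH, "mean round-to-hit time, unsuccessful"),
        Feature("rt_all_mean", TOUCH, "mean round-to-hit time, all"),
    ]
    for d in TILT_DIRECTIONS:
        for suffix, ref in (
            ("fraction", "fraction of time tilted"),
            ("rate", "tilt episodes per second"),
            ("peak_mean", "mean per-episode maximum tilt"),
            ("peak_sd", "sd of per-episode maximum tilt"),
            ("peak_median", "median per-episode maximum tilt"),
            ("osc_mean", "mean per-episode oscillation count"),
            ("osc_sd", "sd of per-episode oscillation count"),
            ("osc_median", "median per-episode oscillation count"),
        ):
            feats.append(Feature(f"tilt_{d}_{suffix}", INERTIAL, ref))
    return feats


_FIVE = ("mean", "sd", "min", "max", "median")


def _creativity_features() -> list[Feature]:
    feats = [
        Feature("total_time", FLOW, "game duration"),
        Feature("images_selected", FLOW, "images selected"),
        Feature("images_outlined", FLOW, "images completely outlined"),
        Feature("images_fill_started", FLOW, "images with colour filling begun"),
    ]
    for kind in ("contour", "fill", "all"):
        feats += _stats_block(f"speed_{kind}", _FIVE, "mean drawing speed per path", TOUCH)
    feats += _stats_block("fill_len", _FIVE, "colour-filling path length", TOUCH)
    feats += _stats_block("fill_xrange", _FIVE, "horizontal extent of filling paths", TOUCH)
    feats += _stats_block("fill_yrange", _FIVE, "vertical extent of filling paths", TOUCH)
    feats.append(Feature("colour_changes_per_image", TOUCH, "colour changes / images selected"))
    feats += [
        Feature("x_sign_change_rate", INERTIAL, "X-acceleration sign flips per second, horizontal paths"),
        Feature("y_sign_change_rate", INERTIAL, "Y-acceleration sign flips per second, vertical paths"),
        Feature("z_sign_change_rate", INERTIAL, "Z-acceleration sign flips per second"),
        Feature("x_exceed_frac", INERTIAL, "fraction of time |ax| above threshold"),
        Feature("y_exceed_frac", INERTIAL, "fraction of time |ay| above threshold"),
        Feature("z_exceed_frac", INERTIAL, "fraction of time |az| above threshold"),
    ]
    return feats


def _catdog_features() -> list[Feature]:
    feats = [
        Feature("total_time", FLOW, "game duration"),
        Feature("correct_rate", FLOW, "correct touch answers per second"),
        Feature("incorrect_rate", FLOW, "incorrect touch answers per second"),
        Feature("unexpected_touch_rate", FLOW, "unexpected-region touches per second"),
        Feature("missed_rate", FLOW, "missed target stimuli per second"),
        Feature("touch_answer_frac", FLOW, "fraction of trials answered by touch"),
        Feature("restrain_frac", FLOW, "fraction of trials with withheld touch"),
    ]
    for kind in ("correct_image", "correct_sound", "incorrect_image", "incorrect_sound", "all"):
        feats += _stats_block(f"rt_{kind}", ("mean", "sd", "min", "max"), "reaction time statistics", TOUCH)
    return feats


#: Canonical ordered registry, one slice per game.
REGISTRY: dict[str, tuple[Feature, ...]] = {
    "boxes": tuple(_boxes_features()),
    "sharing": tuple(_sharing_features()),
    "pinwheel": tuple(_pinwheel_features()),
    "creativity": tuple(_creativity_features()),
    "catdog": tuple(_catdog_features()),
}

EXPECTED_COUNTS = {"boxes": 29, "sharing": 44, "pinwheel": 41, "creativity": 41, "catdog": 27}

for _g, _feats in REGISTRY.items():
    assert len(_feats) == EXPECTED_COUNTS[_g], (_g, len(_feats))
    assert len({f.name for f in _feats}) == len(_feats), _g


def registry_manifest() -> dict[str, tuple[Feature, ...]]:
    """The canonical feature registry (game -> ordered feature tuple)."""
    return dict(REGISTRY)


def feature_names(game_id: str) -> list[str]:
    return [f.name for f in REGISTRY[game_id]]


def feature_source(game_id: str, name: str) -> str:
    for f in REGISTRY[game_id]:
        if f.name == name:
            return f.source
    raise KeyError((game_id, name))


def write_manifest_tsv(path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["game", "name", "source", "definition_ref"])
        for game, feats in REGISTRY.items():
            for f in feats:
                w.writerow([game, f.name, f.source, f.definition_ref])


def read_manifest_tsv(path: str | Path) -> dict[str, tuple[Feature, ...]]:
    out: dict[str, list[Feature]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["game"], []).append(
                Feature(row["name"], row["source"], row["definition_ref"])
            )
    return {g: tuple(v) for g, v in out.items()}


# ---------------------------------------------------------------------------
# Shared extraction helpers

def touch_paths(recording: GameRecording) -> dict[int, PlanarPath]:
    """Group touch samples into drag paths keyed by path_id."""
    grouped: dict[int, list[tuple[float, float, float]]] = {}
    for s in recording.touches:
        grouped.setdefault(s.path_id, []).append((s.t, s.x, s.y))
    return {pid: PlanarPath.from_samples(samples) for pid, samples in grouped.items()}


def _stat(values: Sequence[float], which: str) -> float:
    vals = [v for v in values if not math.isnan(v)]
    if not vals:
        return NA
    stats = kin.SummaryStats.from_values(vals)
    return {
        "avg": stats.mean,
        "mean": stats.mean,
        "sd": stats.sd,
        "min": stats.min,
        "max": stats.max,
        "median": stats.median,
    }[which]


def _path_stat_block(paths: Sequence[PlanarPath], prefix: str, stats: Sequence[str], fn: Callable[[PlanarPath], float]) -> dict[str, float]:
    values = [fn(p) for p in paths]
    return {f"{prefix}_{s}": _stat(values, s) for s in stats}


def _finalize(game_id: str, values: dict[str, float], config: ExtractionConfig) -> FeatureVector:
    expected = feature_names(game_id)
    missing = set(expected) - set(values)
    extra = set(values) - set(expected)
    if missing or extra:  # pragma: no cover - extractor bug guard
        raise RuntimeError(f"{game_id}: registry mismatch missing={missing} extra={extra}")
    return FeatureVector(game_id=game_id, values={k: float(values[k]) for k in expected}, config=config)


def _check_game(recording: GameRecording, game_id: str) -> None:
    if recording.game_id != game_id:
        raise ValueError(f"expected a {game_id} recording, got {recording.game_id}")
    if recording.duration <= 0:
        raise ValueError("recording duration must be > 0")


# ---------------------------------------------------------------------------
# Boxes

def extract_boxes(recording: GameRecording, config: ExtractionConfig | None = None) -> FeatureVector:
    """Flow counts/rates per ball colour plus drag-path statistics, the
    latter over all box-ending moves and separately over short ones."""
    config = config or ExtractionConfig()
    _check_game(recording, "boxes")
    T = recording.duration
    paths = touch_paths(recording)
    drops = [e for e in recording.events if e.kind == "ball_drop"]

    values: dict[str, float] = {"total_time": T, "total_moves": float(len(paths))}
    n_success = n_fail = 0
    for c in BALL_COLOURS:
        succ = sum(1 for e in drops if e.payload.get("ball_colour") == c and e.payload.get("box_colour") == c)
        fail = sum(1 for e in drops if e.payload.get("ball_colour") == c and e.payload.get("box_colour") != c)
        values[f"success_count_{c}"] = float(succ)
        values[f"fail_count_{c}"] = float(fail)
        n_success += succ
        n_fail += fail
    values["success_move_rate"] = n_success / T
    values["fail_move_rate"] = n_fail / T
    values["total_move_rate"] = len(paths) / T

    box_paths = [paths[e.payload["path_id"]] for e in drops if e.payload.get("path_id") in paths]
    short = [p for p in box_paths if kin.path_length(p) < config.short_path_length]
    for scope, subset in (("all", box_paths), ("short", short)):
        values[f"{scope}_path_count"] = float(len(subset))
        values.update(_path_stat_block(subset, f"{scope}_efficiency", ("avg", "min", "max"), kin.path_efficiency))
        values.update(_path_stat_block(subset, f"{scope}_speed", ("avg", "min", "max"), kin.mean_path_speed))
    return _finalize("boxes", values, config)


# ---------------------------------------------------------------------------
# Sharing

def extract_sharing(recording: GameRecording, config: ExtractionConfig | None = None) -> FeatureVector:
    """Rule-following flow rates plus per-character food-drag statistics."""
    config = config or ExtractionConfig()
    _check_game(recording, "sharing")
    T = recording.duration
    paths = touch_paths(recording)
    food = [e for e in recording.events if e.kind == "food_drag"]
    objects = [e for e in recording.events if e.kind == "object_drag"]
    distractors = [e for e in recording.events if e.kind == "distractor_tap"]
    rounds = sorted(e.t for e in recording.events if e.kind == "round_start")

    food_table = [e for e in food if e.payload.get("source") == "table"]
    n_actions = len(food) + len(objects) + len(distractors)

    values: dict[str, float] = {
        "total_time": T,
        "action_rate": n_actions / T,
        "success_action_rate": len(food_table) / T,
        "food_to_plate_rate": len(food_table) / T,
        "object_table_rate": sum(1 for e in objects if e.payload.get("source") == "table") / T,
        "object_plate_rate": sum(1 for e in objects if e.payload.get("source") == "plate") / T,
    }
    if rounds:
        bounds = rounds + [T]
        values["avg_round_length"] = float(np.mean(np.diff(bounds)))
    else:
        values["avg_round_length"] = T
    for g in DISTRACTOR_GROUPS:
        values[f"distractor_rate_{g}"] = sum(1 for e in distractors if e.payload.get("group") == g) / T
    values["distractor_rate_all"] = len(distractors) / T

    for ch in SHARING_CHARACTERS:
        drag_paths = [
            paths[e.payload["path_id"]]
            for e in food_table
            if e.payload.get("target_character") == ch and e.payload.get("path_id") in paths
        ]
        values.update(_path_stat_block(drag_paths, f"char{ch}_efficiency", ("avg", "min", "max", "median"), kin.path_efficiency))
        values.update(_path_stat_block(drag_paths, f"char{ch}_speed", ("avg", "min", "max", "median"), kin.mean_path_speed))
    return _finalize("sharing", values, config)


# ---------------------------------------------------------------------------
# Pinwheel

def extract_pinwheel(recording: GameRecording, config: ExtractionConfig | None = None) -> FeatureVector:
    """Hit/fall flow rates, round-to-hit reaction times and the four-way
    directional tilt feature block from the inertial stream."""
    config = config or ExtractionConfig()
    _check_game(recording, "pinwheel")
    if not recording.motion:
        raise ValueError("pinwheel recording requires a motion stream")
    T = recording.duration
    hits = [e for e in recording.events if e.kind == "petal_hit"]
    successes = [e for e in hits if e.payload.get("success")]
    failures = [e for e in hits if not e.payload.get("success")]
    falls = [e for e in recording.events if e.kind == "ball_fall"]
    rounds = sorted(e.t for e in recording.events if e.kind == "round_start")

    values: dict[str, float] = {
        "total_time": T,
        "success_hit_rate": len(successes) / T,
        "fail_hit_rate": len(failures) / T,
        "ball_fall_rate": len(falls) / T,
        "round_rate": len(rounds) / T,
        "touch_rate": len(touch_paths(recording)) / T,
    }

    def hit_rts(events) -> list[float]:
        rts = []
        for e in events:
            prior = [r for r in rounds if r <= e.t]
            if prior:
                rts.append(e.t - prior[-1])
        return rts

    values["rt_success_mean"] = _stat(hit_rts(successes), "mean")
    values["rt_fail_mean"] = _stat(hit_rts(failures), "mean")
    values["rt_all_mean"] = _stat(hit_rts(hits), "mean")

    t = np.array([m.t for m in recording.motion])
    roll = np.array([m.roll for m in recording.motion])
    pitch = np.array([m.pitch for m in recording.motion])
    for d in TILT_DIRECTIONS:
        angles = kin.signed_angle(roll, pitch, d)
        episodes = kin.detect_tilt_episodes(t, angles, d, config.tilt_threshold)
        block = kin.tilt_features(episodes, T)
        for key, val in block.items():
            values[f"tilt_{d}_{key}"] = val
    return _finalize("pinwheel", values, config)


# ---------------------------------------------------------------------------
# Creativity

def _fill_intervals(recording: GameRecording) -> list[tuple[float, float]]:
    """Time spans from each fill_started to the next image_selected (or end)."""
    selections = sorted(e.t for e in recording.events if e.kind == "image_selected")
    spans = []
    for e in recording.events:
        if e.kind != "fill_started":
            continue
        nxt = [s for s in selections if s > e.t]
        spans.append((e.t, nxt[0] if nxt else recording.duration))
    return spans


def extract_creativity(recording: GameRecording, config: ExtractionConfig | None = None) -> FeatureVector:
    """Drawing-progress flow counts, contour/fill drawing statistics and
    accelerometer jerkiness/pressure features."""
    config = config or ExtractionConfig()
    _check_game(recording, "creativity")
    if not recording.motion:
        raise ValueError("creativity recording requires a motion stream")
    T = recording.duration
    paths = list(touch_paths(recording).values())
    n_selected = sum(1 for e in recording.events if e.kind == "image_selected")
    n_outlined = sum(1 for e in recording.events if e.kind == "outline_completed")
    n_fill = sum(1 for e in recording.events if e.kind == "fill_started")
    n_colour = sum(1 for e in recording.events if e.kind == "colour_change")

    fill_spans = _fill_intervals(recording)

    def is_fill(p: PlanarPath) -> bool:
        t0 = float(p.t[0])
        return any(a <= t0 < b for a, b in fill_spans)

    fill_paths = [p for p in paths if is_fill(p)]
    contour_paths = [p for p in paths if not is_fill(p)]

    values: dict[str, float] = {
        "total_time": T,
        "images_selected": float(n_selected),
        "images_outlined": float(n_outlined),
        "images_fill_started": float(n_fill),
        "colour_changes_per_image": (n_colour / n_selected) if n_selected else NA,
    }
    for kind, subset in (("contour", contour_paths), ("fill", fill_paths), ("all", paths)):
        values.update(_path_stat_block(subset, f"speed_{kind}", _FIVE, kin.mean_path_speed))
    values.update(_path_stat_block(fill_paths, "fill_len", _FIVE, kin.path_length))
    values.update(
        _path_stat_block(fill_paths, "fill_xrange", _FIVE, lambda p: float(np.max(p.x) - np.min(p.x)))
    )
    values.update(
        _path_stat_block(fill_paths, "fill_yrange", _FIVE, lambda p: float(np.max(p.y) - np.min(p.y)))
    )

    t = np.array([m.t for m in recording.motion])
    ax = np.array([m.ax for m in recording.motion])
    ay = np.array([m.ay for m in recording.motion])
    az = np.array([m.az for m in recording.motion])

    is_horizontal = [
        bool(np.max(p.x) - np.min(p.x) >= np.max(p.y) - np.min(p.y)) for p in paths
    ]
    horizontal = [p for p, h in zip(paths, is_horizontal) if h]
    vertical = [p for p, h in zip(paths, is_horizontal) if not h]

    def directional_rate(subset: list[PlanarPath], accel: np.ndarray) -> float:
        spans = [(float(p.t[0]), float(p.t[-1])) for p in subset if p.t[-1] > p.t[0]]
        total = sum(b - a for a, b in spans)
        if total <= 0:
            return NA
        mask = np.zeros(len(t), dtype=bool)
        for a, b in spans:
            mask |= (t >= a) & (t <= b)
        if not np.any(mask):
            return NA
        return kin.sign_change_rate(accel[mask], total)

    values["x_sign_change_rate"] = directional_rate(horizontal, ax)
    values["y_sign_change_rate"] = directional_rate(vertical, ay)
    values["z_sign_change_rate"] = kin.sign_change_rate(az, T)
    if len(t) >= 2:
        values["x_exceed_frac"] = kin.exceedance_fraction(t, ax, config.accel_threshold)
        values["y_exceed_frac"] = kin.exceedance_fraction(t, ay, config.accel_threshold)
        values["z_exceed_frac"] = kin.exceedance_fraction(t, az, config.accel_threshold)
    else:
        values["x_exceed_frac"] = values["y_exceed_frac"] = values["z_exceed_frac"] = NA
    return _finalize("creativity", values, config)


# ---------------------------------------------------------------------------
# Cat and Dog

def extract_catdog(recording: GameRecording, config: ExtractionConfig | None = None) -> FeatureVector:
    """Go/no-go flow rates, answer/restrain fractions and reaction-time
    statistics split by stimulus kind and answer correctness."""
    config = config or ExtractionConfig()
    _check_game(recording, "catdog")
    T = recording.duration
    stimuli = sorted(
        (e for e in recording.events if e.kind == "stimulus_onset"), key=lambda e: e.t
    )
    taps = sorted(e.t for e in recording.events if e.kind == "response_tap" and e.payload.get("region") == "expected")
    unexpected = [e for e in recording.events if e.kind == "response_tap" and e.payload.get("region") == "unexpected"]

    rts = kin.reaction_times([e.t for e in stimuli], taps, config.response_window)

    answered = [(s, rt) for s, rt in zip(stimuli, rts) if rt is not None]
    unanswered = [s for s, rt in zip(stimuli, rts) if rt is None]
    correct = [(s, rt) for s, rt in answered if s.payload.get("target")]
    incorrect = [(s, rt) for s, rt in answered if not s.payload.get("target")]
    missed = [s for s in unanswered if s.payload.get("target")]

    n_trials = len(stimuli)
    values: dict[str, float] = {
        "total_time": T,
        "correct_rate": len(correct) / T,
        "incorrect_rate": len(incorrect) / T,
        "unexpected_touch_rate": len(unexpected) / T,
        "missed_rate": len(missed) / T,
        "touch_answer_frac": (len(answered) / n_trials) if n_trials else NA,
        "restrain_frac": (len(unanswered) / n_trials) if n_trials else NA,
    }

    def subset_rts(pairs, modality: str | None) -> list[float]:
        return [rt for s, rt in pairs if modality is None or s.payload.get("modality") == modality]

    groups = {
        "correct_image": subset_rts(correct, "image"),
        "correct_sound": subset_rts(correct, "sound"),
        "incorrect_image": subset_rts(incorrect, "image"),
        "incorrect_sound": subset_rts(incorrect, "sound"),
        "all": subset_rts(answered, None),
    }
    for kind, rt_list in groups.items():
        for s in ("mean", "sd", "min", "max"):
            values[f"rt_{kind}_{s}"] = _stat(rt_list, s)
    return _finalize("catdog", values, config)


EXTRACTORS: dict[str, Callable[[GameRecording, ExtractionConfig | None], FeatureVector]] = {
    "boxes": extract_boxes,
    "sharing": extract_sharing,
    "pinwheel": extract_pinwheel,
    "creativity": extract_creativity,
    "catdog": extract_catdog,
}


def extract(recording: GameRecording, config: ExtractionConfig | None = None) -> FeatureVector:
    """Dispatch to the extractor for the recording's game."""
    try:
        fn = EXTRACTORS[recording.game_id]
    except KeyError:
        raise ValueError(f"unknown game_id {recording.game_id!r}") from None
    return fn(recording, config)
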