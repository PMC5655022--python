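"""Synthetic gameplay cohorts with known ground truth.

Simulates children whose latent per-area skills follow a drifting random
walk across monthly sessions. Each session produces five game recordings
whose kinematic and flow properties are monotone (logistic) functions of
the linked skills, plus a therapist questionnaire whose item ratings are
clipped, rounded, noisy monotone readouts of the same skills. Ground-truth
skill trajectories are returned so downstream stages can be tested for
recovery.

Acceleration samples are user (gravity-removed) acceleration in g units.
The simulator provides controllable statistical structure, not clinical
realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .assessment import (
    AREAS,
    Instrument,
    QuestionnaireResponse,
    default_instrument,
)
from .session import (
    GAME_IDS,
    GameEvent,
    GameRecording,
    MotionSample,
    SessionRecord,
    TouchSample,
)

EffectLink = tuple[str, str, int, float]  # (game_id, family, direction, strength)

#: Behaviour families each game exposes to the effect map.
GAME_FAMILIES: dict[str, tuple[str, ...]] = {
    "boxes": ("accuracy", "path", "speed"),
    "sharing": ("path", "speed", "distractor", "compliance"),
    "pinwheel": ("tilt", "hit", "reaction"),
    "creativity": ("path", "speed", "tremor", "persistence"),
    "catdog": ("attention", "inhibition", "reaction"),
}

DEFAULT_DURATIONS: dict[str, float] = {
    "boxes": 90.0,
    "sharing": 120.0,
    "pinwheel": 90.0,
    "creativity": 120.0,
    "catdog": 75.0,
}


def default_effect_map() -> dict[str, list[EffectLink]]:
    """Plausible skill-to-behaviour links; three areas deliberately have
    weak or no behavioural expression."""
    return {
        "fine_motor": [
            ("boxes", "path", 1, 1.2),
            ("boxes", "speed", 1, 0.8),
            ("sharing", "path", 1, 1.2),
            ("creativity", "path", 1, 1.2),
            ("creativity", "tremor", 1, 1.0),
        ],
        "gross_motor": [("pinwheel", "tilt", 1, 1.2), ("pinwheel", "hit", 1, 0.8)],
        "attention": [("catdog", "attention", 1, 1.2), ("sharing", "distractor", 1, 1.0)],
        "communication": [("boxes", "accuracy", 1, 1.0), ("sharing", "compliance", 1, 0.8)],
        "following_instructions": [
            ("sharing", "compliance", 1, 0.8),
            ("boxes", "accuracy", 1, 0.6),
        ],
        "stimulation_reaction": [
            ("catdog", "inhibition", 1, 1.0),
            ("creativity", "tremor", 1, 0.6),
        ],
        "social_emotional": [("sharing", "speed", 1, 0.5), ("catdog", "reaction", 1, 0.8)],
        "stereotypical": [("pinwheel", "reaction", 1, 0.6)],
        "self_reliance": [("creativity", "persistence", 1, 0.8)],
        "challenging": [],
    }


@dataclass(frozen=True)
class CohortConfig:
    n_children: int = 40
    sessions_range: tuple[int, int] = (2, 7)
    age_months_range: tuple[int, int] = (37, 83)
    drift: dict[str, float] = field(default_factory=lambda: {a: 0.15 for a in AREAS})
    latent_noise_sd: float = 0.3
    rating_noise_sd: float = 0.5
    effect_map: dict[str, list[EffectLink]] = field(default_factory=default_effect_map)
    durations: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DURATIONS))
    touch_hz: float = 60.0
    motion_hz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if self.latent_noise_sd < 0 or self.rating_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        lo, hi = self.sessions_range
        if not (1 <= lo <= hi <= 7):
            raise ValueError("sessions_range must satisfy 1 <= lo <= hi <= 7")


@dataclass
class Cohort:
    sessions: list[SessionRecord]
    skills: pd.DataFrame  # columns: child_id, session_index, area, skill
    config: CohortConfig


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def family_abilities(
    game_id: str,
    skills: dict[str, float],
    effect_map: dict[str, list[EffectLink]],
) -> dict[str, float]:
    """Logistic controls in (0, 1) per behaviour family; 0.5 when no skill
    drives a family."""
    controls = {fam: 0.0 for fam in GAME_FAMILIES[game_id]}
    for area, links in effect_map.items():
        for g, fam, direction, strength in links:
            if g == game_id and fam in controls:
                controls[fam] += direction * strength * skills.get(area, 0.0)
    return {fam: _sigmoid(v) for fam, v in controls.items()}


# ---------------------------------------------------------------------------
# Touch-path synthesis

def _drag_path(
    rng: np.random.Generator,
    path_id: int,
    t0: float,
    p0: tuple[float, float],
    p1: tuple[float, float],
    speed: float,
    jitter_sd: float,
    hz: float,
) -> tuple[list[TouchSample], float]:
    """A drag gesture from p0 to p1: straight line plus interior jitter."""
    dist = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    elapsed = max(dist / speed, 3.0 / hz)
    n = max(int(elapsed * hz) + 1, 3)
    ts = t0 + np.linspace(0.0, elapsed, n)
    xs = np.linspace(p0[0], p1[0], n)
    ys = np.linspace(p0[1], p1[1], n)
    if jitter_sd > 0 and n > 2:
        xs[1:-1] += rng.normal(0.0, jitter_sd, n - 2)
        ys[1:-1] += rng.normal(0.0, jitter_sd, n - 2)
    xs = np.clip(xs, 0.0, 1.0)
    ys = np.clip(ys, 0.0, 1.0)
    samples = [
        TouchSample(
            path_id=path_id,
            t=float(ts[i]),
            x=float(xs[i]),
            y=float(ys[i]),
            phase="began" if i == 0 else ("ended" if i == n - 1 else "moved"),
        )
        for i in range(n)
    ]
    return samples, float(ts[-1])


def _tap(path_id: int, t0: float, x: float, y: float) -> list[TouchSample]:
    return [
        TouchSample(path_id=path_id, t=t0, x=x, y=y, phase="began"),
        TouchSample(path_id=path_id, t=t0 + 0.05, x=x, y=y, phase="ended"),
    ]


def _baseline_motion(
    rng: np.random.Generator, duration: float, hz: float, accel_sd: float, angle_sd: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = max(int(duration * hz) + 1, 2)
    t = np.linspace(0.0, duration, n)
    acc = rng.normal(0.0, accel_sd, (3, n))
    ang = rng.normal(0.0, angle_sd, (2, n))
    return t, acc[0], acc[1], acc[2], ang[0], ang[1]


# ---------------------------------------------------------------------------
# Per-game simulators

def _simulate_boxes(
    rng: np.random.Generator,
    u: dict[str, float],
    duration: float,
    hz: float,
    scripted: bool,
) -> GameRecording:
    colours = ("red", "blue", "green", "yellow", "purple")
    ball_xy = {c: ((i + 0.5) / 5.0, 0.15) for i, c in enumerate(colours)}
    box_xy = {c: ((i + 0.5) / 5.0, 0.9) for i, c in enumerate(colours)}
    p_wrong = 0.0 if scripted else 0.35 * (1 - u["accuracy"])
    p_abort = 0.0 if scripted else 0.2 * (1 - u["accuracy"])
    jitter = 0.0 if scripted else 0.004 + 0.05 * (1 - 0.85 * u["path"])
    speed = 0.5 if scripted else 0.2 + 0.6 * u["speed"]

    touches: list[TouchSample] = []
    events: list[GameEvent] = []
    t = 0.5
    path_id = 0
    for _ in range(4):
        events.append(GameEvent(t=t, kind="round_start"))
        for c in colours:
            if not scripted and t > duration - 3.0:
                break
            if not scripted and rng.random() < p_abort:
                mid = (rng.uniform(0.2, 0.8), rng.uniform(0.3, 0.7))
                samples, t_end = _drag_path(rng, path_id, t, ball_xy[c], mid, speed, jitter, hz)
                touches.extend(samples)
                path_id += 1
                t = t_end + (0.3 if scripted else rng.uniform(0.3, 0.9))
            box = c
            if rng.random() < p_wrong:
                box = str(rng.choice([b for b in colours if b != c]))
            samples, t_end = _drag_path(rng, path_id, t, ball_xy[c], box_xy[box], speed, jitter, hz)
            touches.extend(samples)
            events.append(
                GameEvent(
                    t=t_end,
                    kind="ball_drop",
                    payload={"ball_colour": c, "box_colour": box, "path_id": path_id},
                )
            )
            path_id += 1
            t = t_end + (0.3 if scripted else rng.uniform(0.3, 0.9))
    total = max(duration, t + 0.5)
    return GameRecording(game_id="boxes", duration=total, touches=touches, events=events)


def _simulate_sharing(
    rng: np.random.Generator,
    u: dict[str, float],
    duration: float,
    hz: float,
    scripted: bool,
) -> GameRecording:
    table = (0.5, 0.8)
    plates = {1: (0.15, 0.25), 2: (0.38, 0.25), 3: (0.62, 0.25), 4: (0.85, 0.25)}
    jitter = 0.0 if scripted else 0.004 + 0.05 * (1 - 0.85 * u["path"])
    speed = 0.5 if scripted else 0.2 + 0.6 * u["speed"]
    distractor_lambda = 0.0 if scripted else 3.0 * (1 - u["distractor"])
    p_object = 0.0 if scripted else 0.3 * (1 - u["compliance"])

    touches: list[TouchSample] = []
    events: list[GameEvent] = []
    t = 0.5
    path_id = 0
    groups = ("lamps", "shelf", "bird", "pinwheel")
    for _ in range(4):
        if not scripted and t > duration - 5.0:
            break
        events.append(GameEvent(t=t, kind="round_start"))
        for ch in (1, 2, 3, 4):
            n_distract = rng.poisson(distractor_lambda / 4.0) if distractor_lambda else 0
            for _ in range(n_distract):
                x, y = rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95)
                touches.extend(_tap(path_id, t, x, y))
                events.append(
                    GameEvent(t=t, kind="distractor_tap", payload={"group": str(rng.choice(groups))})
                )
                path_id += 1
                t += rng.uniform(0.4, 1.0)
            if rng.random() < p_object:
                src = str(rng.choice(["table", "plate"]))
                p0 = table if src == "table" else plates[int(rng.integers(1, 5))]
                p1 = plates[int(rng.integers(1, 5))]
                samples, t_end = _drag_path(rng, path_id, t, p0, p1, speed, jitter, hz)
                touches.extend(samples)
                events.append(GameEvent(t=t_end, kind="object_drag", payload={"source": src, "path_id": path_id}))
                path_id += 1
                t = t_end + rng.uniform(0.3, 0.8)
            samples, t_end = _drag_path(rng, path_id, t, table, plates[ch], speed, jitter, hz)
            touches.extend(samples)
            events.append(
                GameEvent(
                    t=t_end,
                    kind="food_drag",
                    payload={"source": "table", "target_character": ch, "path_id": path_id},
                )
            )
            path_id += 1
            t = t_end + (0.3 if scripted else rng.uniform(0.3, 0.9))
    total = max(duration, t + 0.5)
    return GameRecording(game_id="sharing", duration=total, touches=touches, events=events)


def _simulate_pinwheel(
    rng: np.random.Generator,
    u: dict[str, float],
    duration: float,
    hz: float,
    motion_hz: float,
    scripted: bool,
    tilt_threshold: float = 0.175,
) -> GameRecording:
    t_arr, ax, ay, az, roll, pitch = _baseline_motion(
        rng, duration, motion_hz, accel_sd=0.03, angle_sd=0.0 if scripted else 0.02
    )
    p_hit = 1.0 if scripted else 0.25 + 0.7 * u["hit"]
    rt_base = 0.8 if scripted else 0.5 + 1.3 * (1 - u["reaction"])
    osc_sd = 0.0 if scripted else 0.09 * (1 - u["tilt"])

    events: list[GameEvent] = []
    touches: list[TouchSample] = []
    directions = ("forward", "forward", "backward", "left", "right")
    t = 1.0
    path_id = 0
    while t < duration - 3.0:
        events.append(GameEvent(t=t, kind="round_start"))
        rt = rt_base if scripted else rt_base + rng.exponential(0.3)
        rt = min(rt, 2.5)
        direction = directions[int(rng.integers(len(directions)))]
        amp = tilt_threshold + 0.08 + (0.0 if scripted else rng.uniform(0.0, 0.25))
        bump_start, bump_end = t + 0.1, t + rt
        idx = (t_arr >= bump_start) & (t_arr <= bump_end)
        if np.any(idx):
            tau = (t_arr[idx] - bump_start) / max(bump_end - bump_start, 1e-6)
            shape = amp * np.sin(np.pi * tau)
            if osc_sd > 0:
                shape = shape + rng.normal(0.0, osc_sd, idx.sum())
            if direction == "forward":
                pitch[idx] -= shape
            elif direction == "backward":
                pitch[idx] += shape
            elif direction == "left":
                roll[idx] += shape
            else:
                roll[idx] -= shape
        if rng.random() < p_hit:
            events.append(GameEvent(t=t + rt, kind="petal_hit", payload={"success": True}))
        elif rng.random() < 0.5:
            events.append(GameEvent(t=t + rt, kind="petal_hit", payload={"success": False}))
        else:
            events.append(GameEvent(t=t + rt, kind="ball_fall"))
        if not scripted and rng.random() < 0.2:
            touches.extend(_tap(path_id, t + rt * 0.5, rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8)))
            path_id += 1
        t += rt + (1.0 if scripted else rng.uniform(0.8, 1.6))
    motion = [
        MotionSample(t=float(t_arr[i]), ax=float(ax[i]), ay=float(ay[i]), az=float(az[i]),
                     roll=float(roll[i]), pitch=float(pitch[i]))
        for i in range(len(t_arr))
    ]
    return GameRecording(
        game_id="pinwheel", duration=duration, touches=touches, motion=motion, events=events
    )


def _simulate_creativity(
    rng: np.random.Generator,
    u: dict[str, float],
    duration: float,
    hz: float,
    motion_hz: float,
    scripted: bool,
) -> GameRecording:
    jitter = 0.0 if scripted else 0.003 + 0.04 * (1 - 0.85 * u["path"])
    speed = 0.4 if scripted else 0.15 + 0.5 * u["speed"]
    tremor_sd = 0.04 if scripted else 0.04 + 0.3 * (1 - u["tremor"])
    n_images = 3 if scripted else 1 + int(round(3 * u["persistence"]))

    t_arr, ax, ay, az, roll, pitch = _baseline_motion(
        rng, duration, motion_hz, accel_sd=tremor_sd, angle_sd=0.02
    )
    touches: list[TouchSample] = []
    events: list[GameEvent] = []
    t = 0.5
    path_id = 0
    for _ in range(n_images):
        if not scripted and t > duration - 10.0:
            break
        events.append(GameEvent(t=t, kind="image_selected"))
        t += 0.5
        # contour: a diamond of four strokes
        corners = [(0.5, 0.2), (0.8, 0.5), (0.5, 0.8), (0.2, 0.5), (0.5, 0.2)]
        complete = True
        for p0, p1 in zip(corners, corners[1:]):
            if not scripted and t > duration - 4.0:
                complete = False
                break
            samples, t_end = _drag_path(rng, path_id, t, p0, p1, speed, jitter, hz)
            touches.extend(samples)
            path_id += 1
            t = t_end + (0.2 if scripted else rng.uniform(0.2, 0.6))
        if complete:
            events.append(GameEvent(t=t, kind="outline_completed"))
        events.append(GameEvent(t=t, kind="fill_started"))
        n_fill = 5 if scripted else 3 + int(rng.integers(0, 4))
        for s in range(n_fill):
            if not scripted and t > duration - 2.0:
                break
            horizontal = s % 2 == 0
            x0, y0 = rng.uniform(0.3, 0.5), rng.uniform(0.35, 0.55)
            length = 0.25 if scripted else rng.uniform(0.1, 0.35)
            p1 = (x0 + length, y0) if horizontal else (x0, y0 + length)
            samples, t_end = _drag_path(rng, path_id, t, (x0, y0), p1, speed, jitter, hz)
            touches.extend(samples)
            path_id += 1
            t = t_end + (0.15 if scripted else rng.uniform(0.15, 0.5))
            if not scripted and rng.random() < 0.25:
                events.append(GameEvent(t=t, kind="colour_change"))
        t += 0.3 if scripted else rng.uniform(0.3, 1.0)
    total = max(duration, t + 0.5)
    if total > duration:
        # extend motion baseline to cover the overrun
        extra_t, eax, eay, eaz, eroll, epitch = _baseline_motion(
            rng, max(total - duration - 1.0 / motion_hz, 1.0 / motion_hz), motion_hz, tremor_sd, 0.02
        )
        t_arr = np.concatenate([t_arr, duration + 1.0 / motion_hz + extra_t])
        ax, ay, az = np.concatenate([ax, eax]), np.concatenate([ay, eay]), np.concatenate([az, eaz])
        roll, pitch = np.concatenate([roll, eroll]), np.concatenate([pitch, epitch])
        keep = t_arr <= total
        t_arr, ax, ay, az = t_arr[keep], ax[keep], ay[keep], az[keep]
        roll, pitch = roll[keep], pitch[keep]
    motion = [
        MotionSample(t=float(t_arr[i]), ax=float(ax[i]), ay=float(ay[i]), az=float(az[i]),
                     roll=float(roll[i]), pitch=float(pitch[i]))
        for i in range(len(t_arr))
    ]
    return GameRecording(
        game_id="creativity", duration=total, touches=touches, motion=motion, events=events
    )


def _simulate_catdog(
    rng: np.random.Generator,
    u: dict[str, float],
    duration: float,
    hz: float,
    scripted: bool,
) -> GameRecording:
    p_answer = 1.0 if scripted else 0.35 + 0.6 * u["attention"]
    p_false = 0.0 if scripted else 0.4 * (1 - u["inhibition"])
    rt_base = 0.4 if scripted else 0.35 + 0.9 * (1 - u["reaction"])

    touches: list[TouchSample] = []
    events: list[GameEvent] = []
    t = 1.0
    path_id = 0
    spacing = 2.5
    while t < duration - spacing:
        modality = "image" if (scripted or rng.random() < 0.5) else "sound"
        target = True if scripted else bool(rng.random() < 0.55)
        events.append(
            GameEvent(t=t, kind="stimulus_onset", payload={"modality": modality, "target": target})
        )
        answered = (target and rng.random() < p_answer) or (not target and rng.random() < p_false)
        if answered:
            rt = rt_base if scripted else min(rt_base + rng.exponential(0.25), 1.9)
            events.append(GameEvent(t=t + rt, kind="response_tap", payload={"region": "expected"}))
            touches.extend(_tap(path_id, t + rt, 0.5, 0.5))
            path_id += 1
        if not scripted and rng.random() < 0.1:
            tu = t + rng.uniform(0.1, spacing - 0.2)
            events.append(GameEvent(t=tu, kind="response_tap", payload={"region": "unexpected"}))
            touches.extend(_tap(path_id, tu, rng.uniform(0.0, 0.2), rng.uniform(0.8, 1.0)))
            path_id += 1
        t += spacing
    return GameRecording(game_id="catdog", duration=duration, touches=touches, events=events)


def simulate_game_recording(
    game_id: str,
    skills: dict[str, float],
    duration: float,
    seed: int,
    effect_map: dict[str, list[EffectLink]] | None = None,
    touch_hz: float = 60.0,
    motion_hz: float = 100.0,
    scripted: bool = False,
) -> GameRecording:
    """One game recording whose behaviour reflects the given skills.

    ``scripted`` forces deterministic perfect play (complete rounds,
    straight paths, fixed reaction times) regardless of skills.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    for v in skills.values():
        if not math.isfinite(v):
            raise ValueError("skills must be finite")
    if game_id not in GAME_IDS:
        raise ValueError(f"unknown game {game_id!r}")
    effect_map = default_effect_map() if effect_map is None else effect_map
    u = family_abilities(game_id, skills, effect_map)
    rng = np.random.default_rng(seed)
    if game_id == "boxes":
        return _simulate_boxes(rng, u, duration, touch_hz, scripted)
    if game_id == "sharing":
        return _simulate_sharing(rng, u, duration, touch_hz, scripted)
    if game_id == "pinwheel":
        return _simulate_pinwheel(rng, u, duration, touch_hz, motion_hz, scripted)
    if game_id == "creativity":
        return _simulate_creativity(rng, u, duration, touch_hz, motion_hz, scripted)
    return _simulate_catdog(rng, u, duration, touch_hz, scripted)


# ---------------------------------------------------------------------------
# Questionnaire simulation

def simulate_questionnaire(
    skills: dict[str, float],
    instrument: Instrument,
    noise_sd: float,
    seed: int,
    child_id: str = "",
    session_index: int = 1,
) -> QuestionnaireResponse:
    """Item ratings as clipped, rounded logistic readouts of area skills."""
    rng = np.random.default_rng(seed)
    ratings: dict[str, int] = {}
    for item in instrument.items:
        s = skills.get(item.area, 0.0) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        value = item.scale_min + (item.scale_max - item.scale_min) * _sigmoid(s)
        ratings[item.item_id] = int(np.clip(round(value), item.scale_min, item.scale_max))
    return QuestionnaireResponse(child_id=child_id, session_index=session_index, ratings=ratings)


# ---------------------------------------------------------------------------
# Cohort simulation

def simulate_cohort(config: CohortConfig, instrument: Instrument | None = None) -> Cohort:
    """A full cohort: drifting latent skills, monthly sessions (with
    absences), five recordings and a questionnaire per session, plus the
    ground-truth skill table."""
    instrument = instrument or default_instrument()
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss)
    sessions: list[SessionRecord] = []
    truth_rows: list[dict] = []
    lo, hi = config.sessions_range
    for i in range(config.n_children):
        child_id = f"c{i:03d}"
        child_rng = np.random.default_rng(ss.spawn(1)[0])
        n_sessions = int(master.integers(lo, hi + 1))
        months = sorted(master.choice(np.arange(1, 8), size=n_sessions, replace=False).tolist())
        skills = {a: float(child_rng.normal(0.0, 1.0)) for a in AREAS}
        trajectory: dict[int, dict[str, float]] = {}
        for month in range(1, 8):
            if month > 1:
                for a in AREAS:
                    skills[a] += config.drift.get(a, 0.0) + (
                        float(child_rng.normal(0.0, config.latent_noise_sd))
                        if config.latent_noise_sd > 0
                        else 0.0
                    )
            trajectory[month] = dict(skills)
        for month in months:
            sk = trajectory[month]
            record = SessionRecord(child_id=child_id, session_index=month)
            for game_id in GAME_IDS:
                game_seed = int(child_rng.integers(2**31))
                record.recordings[game_id] = simulate_game_recording(
                    game_id,
                    sk,
                    config.durations[game_id],
                    seed=game_seed,
                    effect_map=config.effect_map,
                    touch_hz=config.touch_hz,
                    motion_hz=config.motion_hz,
                )
            record.questionnaire = simulate_questionnaire(
                sk,
                instrument,
                config.rating_noise_sd,
                seed=int(child_rng.integers(2**31)),
                child_id=child_id,
                session_index=month,
            )
            sessions.append(record)
            for a in AREAS:
                truth_rows.append(
                    {"child_id": child_id, "session_index": month, "area": a, "skill": sk[a]}
                )
    return Cohort(sessions=sessions, skills=pd.DataFrame(truth_rows), config=config)


def separated_design_matrix(
    n_samples: int = 60,
    n_features: int = 20,
    n_informative: int = 5,
    separation: float = 1.5,
    seed: int = 0,
):
    """Gaussian two-class matrix with a known class-mean separation.

    The first ``n_informative`` features differ between classes by
    ``separation`` pooled standard deviations; the rest are pure noise.
    With separation 0 the labels are independent of every feature.
    Returns a :class:`playmetrics.dataset.DesignMatrix`.
    """
    from .dataset import DesignMatrix  # local import to avoid cycle

    rng = np.random.default_rng(seed)
    y = np.zeros(n_samples, dtype=int)
    y[: n_samples // 2] = 1
    rng.shuffle(y)
    X = rng.normal(0.0, 1.0, (n_samples, n_features))
    X[y == 1, :n_informative] += separation
    cols = [f"f{i}" for i in range(n_features)]
    return DesignMatrix(
        X=pd.DataFrame(X, columns=cols),
        y=y,
        child_ids=[f"c{i:03d}" for i in range(n_samples)],
        game_id="boxes",
        area="fine_motor",
    )


def null_config(**overrides) -> CohortConfig:
    """Zero-drift, no-behavioural-link configuration for calibration tests."""
    base = CohortConfig(
        drift={a: 0.0 for a in AREAS},
        effect_map={a: [] for a in AREAS},
    )
    return replace(base, **overrides)
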