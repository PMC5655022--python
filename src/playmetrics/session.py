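"""Data model and on-disk format for recorded gameplay sessions.

A session groups up to one recording per game for one child at one visit.
Each recording carries three streams: touch samples, inertial-motion
samples and game-flow events. On disk a session is a JSON Lines file: one
header object followed by one object per sample/event, discriminated by a
``stream`` field — appendable, streamable and diff-friendly.

Conventions fixed here (device-independent):

* screen coordinates are normalized to [0, 1], origin top-left, x
  rightward, y downward;
* time is seconds from game start (floating point); rates are per-second;
* positive pitch = top edge lifted (tilt backward), negative pitch =
  tilt forward; positive roll = right edge lifted (tilt left), negative
  roll = tilt right.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

from .assessment import QuestionnaireResponse

GAME_IDS: tuple[str, ...] = ("boxes", "sharing", "pinwheel", "creativity", "catdog")

#: Games whose recordings must include an inertial-motion stream.
MOTION_GAMES: frozenset[str] = frozenset({"pinwheel", "creativity"})

TOUCH_PHASES: tuple[str, ...] = ("began", "moved", "ended")

#: Game-flow event vocabulary per game.
EVENT_VOCAB: dict[str, frozenset[str]] = {
    "boxes": frozenset({"round_start", "ball_drop"}),
    "sharing": frozenset({"round_start", "food_drag", "object_drag", "distractor_tap"}),
    "pinwheel": frozenset({"round_start", "petal_hit", "ball_fall"}),
    "creativity": frozenset(
        {"image_selected", "outline_completed", "fill_started", "colour_change"}
    ),
    "catdog": frozenset({"stimulus_onset", "response_tap"}),
}


class SessionSchemaError(ValueError):
    """Raised when an on-disk session file violates the schema."""


@dataclass(frozen=True)
class TouchSample:
    path_id: int
    t: float
    x: float
    y: float
    phase: str


@dataclass(frozen=True)
class MotionSample:
    t: float
    ax: float
    ay: float
    az: float
    roll: float
    pitch: float


@dataclass(frozen=True)
class GameEvent:
    t: float
    kind: str
    payload: dict[str, Any] = field(default_factory=dict)

    def __hash__(self) -> int:  # payload is a dict; hash on stable parts
        return hash((self.t, self.kind, tuple(sorted(self.payload.items()))))


@dataclass
class GameRecording:
    game_id: str
    duration: float
    touches: list[TouchSample] = field(default_factory=list)
    motion: list[MotionSample] = field(default_factory=list)
    events: list[GameEvent] = field(default_factory=list)


@dataclass
class SessionRecord:
    child_id: str
    session_index: int
    recordings: dict[str, GameRecording] = field(default_factory=dict)
    questionnaire: QuestionnaireResponse | None = None


@dataclass(frozen=True)
class ExtractionConfig:
    """Thresholds used by the feature extractors.

    ``short_path_threshold`` is a fraction of the screen diagonal (√2 in
    normalized units); the remaining thresholds are absolute.
    """

    tilt_threshold: float = 0.175   # radians, ≈ 10°
    accel_threshold: float = 0.15   # g
    short_path_threshold: float = 0.25  # fraction of screen diagonal
    response_window: float = 2.0    # seconds

    def __post_init__(self) -> None:
        for name in ("tilt_threshold", "accel_threshold", "short_path_threshold", "response_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def short_path_length(self) -> float:
        """Short-path cut-off in normalized screen units."""
        return self.short_path_threshold * math.sqrt(2.0)


# ---------------------------------------------------------------------------
# Validation

def validate_session(record: SessionRecord) -> list[str]:
    """Check all type invariants; returns human-readable violations.

    Violations are data, not exceptions: an empty list means the record is
    valid.
    """
    out: list[str] = []
    if record.session_index < 1:
        out.append(f"session_index {record.session_index} < 1")
    for game_id, rec in record.recordings.items():
        prefix = f"{record.child_id}/s{record.session_index}/{game_id}"
        if game_id != rec.game_id:
            out.append(f"{prefix}: key {game_id!r} != recording game_id {rec.game_id!r}")
        if rec.game_id not in GAME_IDS:
            out.append(f"{prefix}: unknown game_id {rec.game_id!r}")
            continue
        if rec.duration <= 0:
            out.append(f"{prefix}: duration {rec.duration} must be > 0")
        if rec.game_id in MOTION_GAMES and not rec.motion:
            out.append(f"{prefix}: motion stream required for {rec.game_id}")
        out.extend(_validate_touches(prefix, rec))
        out.extend(_validate_motion(prefix, rec))
        out.extend(_validate_events(prefix, rec))
    return out


def _validate_touches(prefix: str, rec: GameRecording) -> list[str]:
    out = []
    by_path: dict[int, list[TouchSample]] = {}
    for s in rec.touches:
        if s.phase not in TOUCH_PHASES:
            out.append(f"{prefix}: touch phase {s.phase!r} invalid")
        if s.t < 0:
            out.append(f"{prefix}: touch t {s.t} < 0")
        if s.t > rec.duration:
            out.append(f"{prefix}: touch t {s.t} exceeds duration {rec.duration}")
        by_path.setdefault(s.path_id, []).append(s)
    for pid, samples in by_path.items():
        ts = [s.t for s in samples]
        if any(b < a for a, b in zip(ts, ts[1:])):
            out.append(f"{prefix}: path {pid} has decreasing timestamps")
        if samples[0].phase != "began":
            out.append(f"{prefix}: path {pid} does not start with 'began'")
        if samples[-1].phase != "ended":
            out.append(f"{prefix}: path {pid} does not end with 'ended'")
    return out


def _validate_motion(prefix: str, rec: GameRecording) -> list[str]:
    out = []
    ts = [s.t for s in rec.motion]
    if any(b < a for a, b in zip(ts, ts[1:])):
        out.append(f"{prefix}: motion timestamps decrease")
    if ts and (ts[0] < 0 or ts[-1] > rec.duration):
        out.append(f"{prefix}: motion timestamps outside [0, duration]")
    return out


def _validate_events(prefix: str, rec: GameRecording) -> list[str]:
    out = []
    vocab = EVENT_VOCAB.get(rec.game_id, frozenset())
    for e in rec.events:
        if e.kind not in vocab:
            out.append(f"{prefix}: event kind {e.kind!r} not in {rec.game_id} vocabulary")
        if e.t < 0 or e.t > rec.duration:
            out.append(f"{prefix}: event t {e.t} outside [0, duration]")
    return out


def validate_cohort_sessions(records: Iterable[SessionRecord]) -> list[str]:
    """Cross-record checks: session_index unique per child."""
    out = []
    seen: set[tuple[str, int]] = set()
    for r in records:
        key = (r.child_id, r.session_index)
        if key in seen:
            out.append(f"duplicate session_index {r.session_index} for child {r.child_id}")
        seen.add(key)
    return out


# ---------------------------------------------------------------------------
# JSON Lines I/O

def write_session(record: SessionRecord, path: str | Path) -> None:
    """Serialize a session to JSON Lines; deterministic byte-for-byte."""
    games = [
        {"game_id": g, "duration": record.recordings[g].duration}
        for g in GAME_IDS
        if g in record.recordings
    ]
    lines = [
        json.dumps(
            {
                "stream": "header",
                "child_id": record.child_id,
                "session_index": record.session_index,
                "games": games,
            },
            sort_keys=True,
        )
    ]
    for g in GAME_IDS:
        if g not in record.recordings:
            continue
        rec = record.recordings[g]
        for s in rec.touches:
            lines.append(
                json.dumps(
                    {
                        "stream": "touch",
                        "game": g,
                        "path_id": s.path_id,
                        "t": s.t,
                        "x": s.x,
                        "y": s.y,
                        "phase": s.phase,
                    },
                    sort_keys=True,
                )
            )
        for m in rec.motion:
            lines.append(
                json.dumps(
                    {
                        "stream": "motion",
                        "game": g,
                        "t": m.t,
                        "ax": m.ax,
                        "ay": m.ay,
                        "az": m.az,
                        "roll": m.roll,
                        "pitch": m.pitch,
                    },
                    sort_keys=True,
                )
            )
        for e in rec.events:
            lines.append(
                json.dumps(
                    {"stream": "event", "game": g, "t": e.t, "kind": e.kind, "payload": e.payload},
                    sort_keys=True,
                )
            )
    if record.questionnaire is not None:
        for item_id in sorted(record.questionnaire.ratings):
            lines.append(
                json.dumps(
                    {
                        "stream": "rating",
                        "item_id": item_id,
                        "rating": record.questionnaire.ratings[item_id],
                    },
                    sort_keys=True,
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_session(path: str | Path) -> SessionRecord:
    """Parse and validate a JSON Lines session file.

    Raises :class:`SessionSchemaError` naming the offending line for any
    malformed record, unknown game or invariant violation.
    """
    path = Path(path)
    record: SessionRecord | None = None
    ratings: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                obj = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise SessionSchemaError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            stream = obj.get("stream")
            if record is None:
                if stream != "header":
                    raise SessionSchemaError(f"{path}:{lineno}: no session header")
                record = _parse_header(obj, path, lineno)
                continue
            try:
                if stream == "touch":
                    rec = _recording_for(record, obj, path, lineno)
                    rec.touches.append(
                        TouchSample(
                            path_id=int(obj["path_id"]),
                            t=float(obj["t"]),
                            x=float(obj["x"]),
                            y=float(obj["y"]),
                            phase=str(obj["phase"]),
                        )
                    )
                elif stream == "motion":
                    rec = _recording_for(record, obj, path, lineno)
                    rec.motion.append(
                        MotionSample(
                            t=float(obj["t"]),
                            ax=float(obj["ax"]),
                            ay=float(obj["ay"]),
                            az=float(obj["az"]),
                            roll=float(obj["roll"]),
                            pitch=float(obj["pitch"]),
                        )
                    )
                elif stream == "event":
                    rec = _recording_for(record, obj, path, lineno)
                    rec.events.append(
                        GameEvent(t=float(obj["t"]), kind=str(obj["kind"]), payload=dict(obj.get("payload", {})))
                    )
                elif stream == "rating":
                    ratings[str(obj["item_id"])] = int(obj["rating"])
                else:
                    raise SessionSchemaError(f"{path}:{lineno}: unknown stream {stream!r}")
            except (KeyError, TypeError, ValueError) as exc:
                if isinstance(exc, SessionSchemaError):
                    raise
                raise SessionSchemaError(f"{path}:{lineno}: malformed {stream} record: {exc}") from exc
    if record is None:
        raise SessionSchemaError(f"{path}: no session header")
    if ratings:
        record.questionnaire = QuestionnaireResponse(
            child_id=record.child_id, session_index=record.session_index, ratings=ratings
        )
    violations = validate_session(record)
    if violations:
        raise SessionSchemaError(f"{path}: invalid session: " + "; ".join(violations))
    return record


def _parse_header(obj: dict, path: Path, lineno: int) -> SessionRecord:
    try:
        record = SessionRecord(
            child_id=str(obj["child_id"]), session_index=int(obj["session_index"])
        )
        for g in obj["games"]:
            gid = str(g["game_id"])
            if gid not in GAME_IDS:
                raise SessionSchemaError(f"{path}:{lineno}: unknown game_id {gid!r}")
            record.recordings[gid] = GameRecording(game_id=gid, duration=float(g["duration"]))
    except (KeyError, TypeError) as exc:
        raise SessionSchemaError(f"{path}:{lineno}: malformed header: {exc}") from exc
    return record


def _recording_for(record: SessionRecord, obj: dict, path: Path, lineno: int) -> GameRecording:
    gid = obj.get("game")
    if gid not in record.recordings:
        raise SessionSchemaError(f"{path}:{lineno}: game {gid!r} not declared in header")
    return record.recordings[gid]


# ---------------------------------------------------------------------------
# Cohort manifest

def write_manifest(rows: list[tuple[str, int, str]], path: str | Path) -> None:
    """Write a cohort manifest CSV (child_id, session_index, file)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["child_id", "session_index", "file"])
        for child_id, session_index, file in rows:
            w.writerow([child_id, session_index, file])


def read_manifest(path: str | Path) -> list[tuple[str, int, str]]:
    with open(path, newline="") as fh:
        return [
            (row["child_id"], int(row["session_index"]), row["file"])
            for row in csv.DictReader(fh)
        ]
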