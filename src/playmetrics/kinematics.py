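"""Signal operators shared by all game feature extractors.

Operators over drag-gesture paths (length, straightness, speed), tilt-angle
series (episode detection, oscillation counting) and acceleration series
(sign-flip rates, threshold exceedance), plus stimulus/tap reaction-time
matching. Everything works at sample resolution — no sub-sample
interpolation — so results are directly checkable against brute-force
scans.

Direction-signed tilt angles follow the package sign convention (see
:mod:`playmetrics.session`): ``forward`` reads −pitch, ``backward`` +pitch,
``left`` +roll, ``right`` −roll.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

TILT_DIRECTIONS: tuple[str, ...] = ("forward", "backward", "left", "right")

#: Maps a tilt direction to (angle source, sign) applied to (roll, pitch).
_DIRECTION_SIGNS: dict[str, tuple[str, float]] = {
    "forward": ("pitch", -1.0),
    "backward": ("pitch", +1.0),
    "left": ("roll", +1.0),
    "right": ("roll", -1.0),
}


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    min: float
    max: float
    median: float

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SummaryStats":
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError("cannot summarize an empty collection")
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        return cls(
            mean=float(np.mean(arr)),
            sd=sd,
            min=float(np.min(arr)),
            max=float(np.max(arr)),
            median=float(np.median(arr)),
        )


@dataclass(frozen=True)
class PlanarPath:
    """One drag gesture: ordered (t, x, y) samples of a single path_id."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t) == 0:
            raise ValueError("path must contain at least one sample")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal lengths")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("path timestamps must be non-decreasing")

    @classmethod
    def from_samples(cls, samples: Sequence[tuple[float, float, float]]) -> "PlanarPath":
        arr = np.asarray(samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("samples must be (t, x, y) triples")
        return cls(t=arr[:, 0], x=arr[:, 1], y=arr[:, 2])

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class TiltEpisode:
    """A maximal run of samples tilted past threshold in one direction.

    Boundaries are sample times; a single-sample run yields a zero-length
    episode (t_end == t_start) that contributes no tilted time.
    """

    direction: str
    t_start: float
    t_end: float
    peak: float
    oscillations: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


# ---------------------------------------------------------------------------
# Path operators

def path_length(path: PlanarPath) -> float:
    """Total Euclidean arc length; 0 for a single sample."""
    if len(path) < 2:
        return 0.0
    return float(np.sum(np.hypot(np.diff(path.x), np.diff(path.y))))


def path_efficiency(path: PlanarPath) -> float:
    """Straight-line endpoint distance over traversed length, in [0, 1].

    A zero-length path (single sample or no motion) is perfectly direct by
    convention and scores 1.0.
    """
    total = path_length(path)
    if total == 0.0:
        return 1.0
    direct = math.hypot(path.x[-1] - path.x[0], path.y[-1] - path.y[0])
    return min(direct / total, 1.0)


def segment_speeds(path: PlanarPath) -> np.ndarray:
    """Per-segment speeds (length / Δt); zero-Δt segments are skipped."""
    if len(path) < 2:
        raise ValueError("need at least 2 samples for speeds")
    dt = np.diff(path.t)
    dist = np.hypot(np.diff(path.x), np.diff(path.y))
    keep = dt > 0
    return dist[keep] / dt[keep]


def segment_speed_stats(path: PlanarPath) -> SummaryStats:
    speeds = segment_speeds(path)
    if speeds.size == 0:
        raise ValueError("no segments with positive duration")
    return SummaryStats.from_values(speeds)


def mean_path_speed(path: PlanarPath) -> float:
    """Arc length divided by elapsed time; NaN when the path has no extent
    in time."""
    elapsed = float(path.t[-1] - path.t[0])
    if elapsed <= 0:
        return math.nan
    return path_length(path) / elapsed


# ---------------------------------------------------------------------------
# Tilt operators

def signed_angle(roll: np.ndarray, pitch: np.ndarray, direction: str) -> np.ndarray:
    """Direction-signed tilt angle series per the package sign convention."""
    source, sign = _DIRECTION_SIGNS[direction]
    series = pitch if source == "pitch" else roll
    return sign * np.asarray(series, dtype=float)


def detect_tilt_episodes(
    t: Sequence[float],
    angles: Sequence[float],
    direction: str,
    threshold: float,
) -> list[TiltEpisode]:
    """Maximal contiguous runs with direction-signed angle > threshold.

    ``angles`` must already be direction-signed (see :func:`signed_angle`).
    Episode peak is the maximum signed angle within the run; oscillations
    count the interior local extrema of the run's angle values.
    """
    t = np.asarray(t, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if t.size == 0:
        raise ValueError("empty angle series")
    if direction not in TILT_DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    above = angles > threshold
    episodes: list[TiltEpisode] = []
    i = 0
    n = len(t)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        run = angles[i : j + 1]
        episodes.append(
            TiltEpisode(
                direction=direction,
                t_start=float(t[i]),
                t_end=float(t[j]),
                peak=float(np.max(run)),
                oscillations=oscillation_count(run),
            )
        )
        i = j + 1
    return episodes


def tilt_features(episodes: Sequence[TiltEpisode], duration: float) -> dict[str, float]:
    """Aggregate one direction's episodes into the tilt feature block.

    Returns fraction of time tilted, tilt rate, and (mean, sd, median) of
    per-episode peaks and oscillation counts; all zeros when there are no
    episodes.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not episodes:
        return {
            "fraction": 0.0,
            "rate": 0.0,
            "peak_mean": 0.0,
            "peak_sd": 0.0,
            "peak_median": 0.0,
            "osc_mean": 0.0,
            "osc_sd": 0.0,
            "osc_median": 0.0,
        }
    peaks = SummaryStats.from_values([e.peak for e in episodes])
    oscs = SummaryStats.from_values([float(e.oscillations) for e in episodes])
    return {
        "fraction": min(sum(e.duration for e in episodes) / duration, 1.0),
        "rate": len(episodes) / duration,
        "peak_mean": peaks.mean,
        "peak_sd": peaks.sd,
        "peak_median": peaks.median,
        "osc_mean": oscs.mean,
        "osc_sd": oscs.sd,
        "osc_median": oscs.median,
    }


def oscillation_count(values: Sequence[float]) -> int:
    """Interior strict local extrema after collapsing equal-value plateaus."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    # collapse consecutive duplicates to single points
    keep = np.ones(arr.size, dtype=bool)
    keep[1:] = arr[1:] != arr[:-1]
    collapsed = arr[keep]
    if collapsed.size < 3:
        return 0
    d = np.diff(collapsed)
    return int(np.sum(d[:-1] * d[1:] < 0))


# ---------------------------------------------------------------------------
# Acceleration operators

def sign_change_rate(values: Sequence[float], duration: float) -> float:
    """Strict sign flips per second; zeros neither flip nor reset the sign."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    flips = 0
    last = 0
    for v in np.asarray(values, dtype=float):
        s = 0 if v == 0 else (1 if v > 0 else -1)
        if s == 0:
            continue
        if last != 0 and s != last:
            flips += 1
        last = s
    return flips / duration


def exceedance_fraction(
    t: Sequence[float], values: Sequence[float], threshold: float
) -> float:
    """Fraction of total time with |value| > threshold.

    Each inter-sample interval [t_i, t_{i+1}) is attributed to sample i's
    state; the final sample carries no interval.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    total = float(t[-1] - t[0])
    if total <= 0:
        raise ValueError("series must span positive time")
    dt = np.diff(t)
    above = np.abs(values[:-1]) > threshold
    return float(np.sum(dt[above]) / total)


# ---------------------------------------------------------------------------
# Reaction-time matching

def reaction_times(
    stimuli: Sequence[float], taps: Sequence[float], window: float
) -> list[float | None]:
    """Greedy first-tap-in-window matching; taps are consumed.

    Each stimulus onset is matched to the earliest unconsumed tap in
    (onset, onset + window]; the reaction time is tap − onset, or ``None``
    for a missed stimulus. Both inputs must be time-sorted.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    out: list[float | None] = []
    tap_iter = list(taps)
    next_tap = 0
    for onset in stimuli:
        # discard taps at or before the onset
        while next_tap < len(tap_iter) and tap_iter[next_tap] <= onset:
            next_tap += 1
        if next_tap < len(tap_iter) and tap_iter[next_tap] <= onset + window:
            out.append(tap_iter[next_tap] - onset)
            next_tap += 1
        else:
            out.append(None)
    return out
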