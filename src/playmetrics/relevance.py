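"""Feature-relevance ranking for progress indication.

Two complementary criteria rank feature deltas between consecutive
sessions: correlation (Pearson and Spearman) of the feature delta with the
therapist-evaluation delta for an area, and information gain of the
discretized feature delta against the binary progress label. Per area the
report takes the union of the top-k features under each criterion, tagged
by source (F flow / T touch / I inertial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .assessment import AREAS, PROGRESS
from .dataset import SessionFeatures, build_diff_samples
from .game_features import REGISTRY, feature_source
from .models import discretize, equal_frequency_bins
from .session import GAME_IDS

NA = math.nan

SOURCE_TAGS = {"flow": "F", "touch": "T", "inertial": "I"}


@dataclass(frozen=True)
class RelevanceRecord:
    game_id: str
    feature_name: str
    area: str
    pearson_r: float
    spearman_rho: float
    info_gain_bits: float
    n_pairs: int

    @property
    def source_tag(self) -> str:
        return SOURCE_TAGS[feature_source(self.game_id, self.feature_name)]


@dataclass
class IndicatorReport:
    """Per area, a ranked list of relevance records."""

    top_k: int
    ranked: dict[str, list[RelevanceRecord]]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; NaN when either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        return NA
    return float(sps.pearsonr(x, y).statistic)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with mid-rank ties; NaN on zero rank
    variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of at least 3 values")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return NA
    return float(sps.spearmanr(x, y).statistic)


def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def information_gain(
    values: Sequence[float], labels: Sequence, n_bins: int = 5
) -> float:
    """H(label) − Σ_b p(b)·H(label | b) over equal-frequency bins (base 2).

    Duplicate quantile edges collapse, so tied data may occupy fewer bins.
    A single-class label vector yields 0 by convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) != len(labels) or len(values) < 2:
        raise ValueError("need equal-length inputs of at least 2 values")
    if len(np.unique(labels)) < 2:
        return 0.0
    h = _entropy_bits(labels)
    edges = equal_frequency_bins(values, n_bins)
    bins = discretize(values, edges)
    cond = 0.0
    n = len(labels)
    for b in np.unique(bins):
        mask = bins == b
        cond += (mask.sum() / n) * _entropy_bits(labels[mask])
    return max(h - cond, 0.0)


# ---------------------------------------------------------------------------
# Cohort-level relevance

def relevance_records(
    cohort: Sequence[SessionFeatures],
    games: Sequence[str] = GAME_IDS,
    areas: Sequence[str] = AREAS,
    n_bins: int = 5,
) -> list[RelevanceRecord]:
    """Compute all (game, feature, area) relevance records from consecutive
    session deltas. Features with fewer than 3 finite pairs get NaN
    correlations and zero gain."""
    out: list[RelevanceRecord] = []
    for game in games:
        for area in areas:
            samples = build_diff_samples(cohort, game, area, mode="consecutive")
            if not samples:
                continue
            labels = np.array([s.label == PROGRESS for s in samples])
            score_deltas = _score_deltas(cohort, game, area)
            for feat in REGISTRY[game]:
                deltas = np.array([s.x[feat.name] for s in samples])
                finite = np.isfinite(deltas) & np.isfinite(score_deltas)
                n_pairs = int(finite.sum())
                if n_pairs >= 3:
                    r = pearson_r(deltas[finite], score_deltas[finite])
                    rho = spearman_rho(deltas[finite], score_deltas[finite])
                else:
                    r = rho = NA
                lab_finite = np.isfinite(deltas)
                if lab_finite.sum() >= 2 and len(np.unique(labels[lab_finite])) == 2:
                    ig = information_gain(deltas[lab_finite], labels[lab_finite], n_bins)
                else:
                    ig = 0.0
                out.append(
                    RelevanceRecord(
                        game_id=game, feature_name=feat.name, area=area,
                        pearson_r=r, spearman_rho=rho, info_gain_bits=ig,
                        n_pairs=n_pairs,
                    )
                )
    return out


def _score_deltas(cohort: Sequence[SessionFeatures], game: str, area: str) -> np.ndarray:
    """Area-score deltas aligned with build_diff_samples(consecutive)."""
    by_child: dict[str, list[SessionFeatures]] = {}
    for sf in cohort:
        if game in sf.vectors and sf.scores is not None:
            by_child.setdefault(sf.child_id, []).append(sf)
    deltas = []
    for child_id in by_child:
        sessions = sorted(by_child[child_id], key=lambda s: s.session_index)
        for a, b in zip(sessions, sessions[1:]):
            deltas.append(b.scores[area] - a.scores[area])
    return np.array(deltas)


def rank_indicators(
    records: Sequence[RelevanceRecord], top_k: int = 5
) -> IndicatorReport:
    """Per area: union of top-k by |r|, |rho| and info gain, ordered by each
    record's best (lowest) rank across the three criteria."""
    ranked: dict[str, list[RelevanceRecord]] = {}
    by_area: dict[str, list[RelevanceRecord]] = {}
    for rec in records:
        by_area.setdefault(rec.area, []).append(rec)
    for area, recs in by_area.items():

        def criterion_ranks(key) -> dict[int, int]:
            vals = [(i, key(r)) for i, r in enumerate(recs)]
            vals = [(i, v) for i, v in vals if not math.isnan(v)]
            vals.sort(key=lambda iv: -iv[1])
            return {i: rank for rank, (i, _) in enumerate(vals)}

        ranks = [
            criterion_ranks(lambda r: abs(r.pearson_r)),
            criterion_ranks(lambda r: abs(r.spearman_rho)),
            criterion_ranks(lambda r: r.info_gain_bits),
        ]
        selected: set[int] = set()
        for rk in ranks:
            top = sorted(rk, key=rk.get)[:top_k]
            selected.update(top)

        def best_rank(i: int) -> int:
            return min(rk.get(i, len(recs)) for rk in ranks)

        ordered = sorted(selected, key=best_rank)
        ranked[area] = [recs[i] for i in ordered]
    return IndicatorReport(top_k=top_k, ranked=ranked)


def write_report_tsv(report: IndicatorReport, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["area", "feature", "source", "game", "pearson_r", "spearman_rho", "info_gain_bits", "n_pairs"])
        for area in AREAS:
            for rec in report.ranked.get(area, []):
                w.writerow(
                    [
                        area, rec.feature_name, rec.source_tag, rec.game_id,
                        f"{rec.pearson_r:.4f}", f"{rec.spearman_rho:.4f}",
                        f"{rec.info_gain_bits:.4f}", rec.n_pairs,
                    ]
                )
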