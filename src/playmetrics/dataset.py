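"""Labelled difference-vector datasets per (game, area).

The classification input is never a raw feature vector: it is the
per-feature difference between two sessions of the same child, labelled by
whether the therapist evaluation of one developmental area strictly
increased over the same pair. Two pairing modes exist: ``first_last`` (one
sample per child) and ``consecutive`` (one per adjacent session pair).
Children with fewer than two usable sessions are excluded.

Preprocessing variants mirror the four study conditions: raw, raw + PCA,
min-max normalized, normalized + PCA.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .assessment import AreaScores, NO_PROGRESS, PROGRESS, progress_label
from .game_features import FeatureVector, feature_names

log = logging.getLogger(__name__)

PairingMode = Literal["first_last", "consecutive"]
VARIANTS = ("raw", "raw_pca", "norm", "norm_pca")


@dataclass
class SessionFeatures:
    """Extracted features plus area scores for one (child, session)."""

    child_id: str
    session_index: int
    vectors: dict[str, FeatureVector] = field(default_factory=dict)
    scores: AreaScores | None = None


@dataclass
class DiffSample:
    child_id: str
    game_id: str
    area: str
    x: dict[str, float]
    label: str
    from_session: int = 0
    to_session: int = 0


@dataclass
class DesignMatrix:
    """Feature matrix in registry column order plus labels and provenance."""

    X: pd.DataFrame
    y: np.ndarray  # 1 = progress, 0 = no_progress
    child_ids: list[str]
    game_id: str
    area: str
    preprocessing: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.X)


@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray  # (k, p), orthonormal rows
    explained_variance_ratio: np.ndarray
    variance_threshold: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T


def build_diff_samples(
    cohort: Sequence[SessionFeatures],
    game_id: str,
    area: str,
    mode: PairingMode = "first_last",
) -> list[DiffSample]:
    """Pair sessions per child and difference their feature vectors.

    A session is usable for (game, area) when it carries both a
    FeatureVector for the game and area scores. Labels come from the strict
    increase of the area score over the same session pair.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if mode not in ("first_last", "consecutive"):
        raise ValueError(f"unknown pairing mode {mode!r}")
    by_child: dict[str, list[SessionFeatures]] = {}
    for sf in cohort:
        if game_id in sf.vectors and sf.scores is not None:
            by_child.setdefault(sf.child_id, []).append(sf)

    samples: list[DiffSample] = []
    for child_id, sessions in by_child.items():
        sessions = sorted(sessions, key=lambda s: s.session_index)
        if len(sessions) < 2:
            continue
        if mode == "first_last":
            pairs = [(sessions[0], sessions[-1])]
        else:
            pairs = list(zip(sessions, sessions[1:]))
        for a, b in pairs:
            va, vb = a.vectors[game_id].values, b.vectors[game_id].values
            diff = {k: vb[k] - va[k] for k in feature_names(game_id)}
            lbl = progress_label(
                a.scores[area], b.scores[area], area, a.session_index, b.session_index
            )
            samples.append(
                DiffSample(
                    child_id=child_id,
                    game_id=game_id,
                    area=area,
                    x=diff,
                    label=lbl.label,
                    from_session=a.session_index,
                    to_session=b.session_index,
                )
            )
    return samples


def samples_to_matrix(samples: Sequence[DiffSample]) -> DesignMatrix:
    if not samples:
        raise ValueError("no samples")
    game_id, area = samples[0].game_id, samples[0].area
    cols = feature_names(game_id)
    X = pd.DataFrame([[s.x[c] for c in cols] for s in samples], columns=cols)
    y = np.array([1 if s.label == PROGRESS else 0 for s in samples])
    return DesignMatrix(
        X=X, y=y, child_ids=[s.child_id for s in samples], game_id=game_id, area=area
    )


# ---------------------------------------------------------------------------
# Preprocessing

def impute_missing(
    matrix: DesignMatrix, policy: Literal["median", "drop_feature"] = "median"
) -> DesignMatrix:
    """Remove not-available entries; explicit and logged, never silent.

    ``median`` fills each missing cell with that feature's column median;
    a feature missing in every row is dropped under either policy.
    """
    if policy not in ("median", "drop_feature"):
        raise ValueError(f"unknown policy {policy!r}")
    X = matrix.X.copy()
    all_missing = [c for c in X.columns if X[c].isna().all()]
    if all_missing:
        log.warning("dropping %d feature(s) missing in all rows: %s", len(all_missing), all_missing)
        X = X.drop(columns=all_missing)
    any_missing = [c for c in X.columns if X[c].isna().any()]
    if policy == "drop_feature":
        if any_missing:
            log.info("dropping %d feature(s) with missing values", len(any_missing))
            X = X.drop(columns=any_missing)
    else:
        n_cells = int(X.isna().sum().sum())
        if n_cells:
            log.info("imputing %d missing cell(s) with column medians", n_cells)
            X = X.fillna(X.median())
    pre = dict(matrix.preprocessing)
    pre["impute"] = {"policy": policy, "dropped": all_missing + (any_missing if policy == "drop_feature" else [])}
    return DesignMatrix(
        X=X, y=matrix.y, child_ids=matrix.child_ids, game_id=matrix.game_id,
        area=matrix.area, preprocessing=pre,
    )


def fit_minmax_bounds(X: pd.DataFrame) -> dict[str, tuple[float, float]]:
    return {c: (float(X[c].min()), float(X[c].max())) for c in X.columns}


def apply_minmax(X: pd.DataFrame, bounds: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Per-feature (v − min)/(max − min); constant features map to 0;
    out-of-bounds values (held-out rows) clip to [0, 1]."""
    out = {}
    for c in X.columns:
        lo, hi = bounds[c]
        if hi > lo:
            out[c] = np.clip((X[c] - lo) / (hi - lo), 0.0, 1.0)
        else:
            out[c] = np.zeros(len(X))
    return pd.DataFrame(out, index=X.index)


def minmax_normalize(matrix: DesignMatrix) -> DesignMatrix:
    bounds = fit_minmax_bounds(matrix.X)
    X = apply_minmax(matrix.X, bounds)
    pre = dict(matrix.preprocessing)
    pre["minmax"] = {c: list(b) for c, b in bounds.items()}
    return DesignMatrix(
        X=X, y=matrix.y, child_ids=matrix.child_ids, game_id=matrix.game_id,
        area=matrix.area, preprocessing=pre,
    )


def fit_pca(X: np.ndarray, variance_threshold: float = 0.95) -> PCAModel:
    """Smallest leading component set with cumulative explained variance
    ratio >= threshold (always at least one component)."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 rows")
    if float(np.var(X, axis=0).sum()) <= 1e-24:
        raise ValueError("rank-0 matrix: no variance to decompose")
    full = PCA(svd_solver="full").fit(X)
    ratios = full.explained_variance_ratio_
    if not np.any(full.explained_variance_ > 1e-12):
        raise ValueError("rank-0 matrix: no variance to decompose")
    nonzero = int(np.sum(full.explained_variance_ > 1e-12))
    cum = np.cumsum(ratios[:nonzero])
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, nonzero)
    return PCAModel(
        mean=full.mean_,
        components=full.components_[:k],
        explained_variance_ratio=ratios[:k],
        variance_threshold=variance_threshold,
    )


def pca_reduce(
    matrix: DesignMatrix, variance_threshold: float = 0.95
) -> tuple[PCAModel, DesignMatrix]:
    model = fit_pca(matrix.X.to_numpy(), variance_threshold)
    Z = model.transform(matrix.X.to_numpy())
    cols = [f"pc_{i + 1}" for i in range(Z.shape[1])]
    pre = dict(matrix.preprocessing)
    pre["pca"] = {
        "variance_threshold": variance_threshold,
        "n_components": Z.shape[1],
        "explained_variance_ratio": model.explained_variance_ratio.tolist(),
    }
    reduced = DesignMatrix(
        X=pd.DataFrame(Z, columns=cols, index=matrix.X.index),
        y=matrix.y, child_ids=matrix.child_ids, game_id=matrix.game_id,
        area=matrix.area, preprocessing=pre,
    )
    return model, reduced


def apply_variant(
    matrix: DesignMatrix, variant: str, variance_threshold: float = 0.95
) -> DesignMatrix:
    """Apply one of the four preprocessing conditions to a full matrix."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    out = impute_missing(matrix)
    if variant in ("norm", "norm_pca"):
        out = minmax_normalize(out)
    if variant in ("raw_pca", "norm_pca"):
        _, out = pca_reduce(out, variance_threshold)
    return out


# ---------------------------------------------------------------------------
# Interchange

def write_dataset(matrix: DesignMatrix, path: str | Path) -> None:
    df = matrix.X.copy()
    df.insert(0, "child_id", matrix.child_ids)
    df["label"] = [PROGRESS if v else NO_PROGRESS for v in matrix.y]
    df.to_csv(path, index=False)
    sidecar = Path(path).with_suffix(".meta.json")
    sidecar.write_text(
        json.dumps(
            {"game_id": matrix.game_id, "area": matrix.area, "preprocessing": matrix.preprocessing},
            indent=2, sort_keys=True,
        )
    )


def read_dataset(path: str | Path) -> DesignMatrix:
    df = pd.read_csv(path)
    meta = json.loads(Path(path).with_suffix(".meta.json").read_text())
    y = np.array([1 if v == PROGRESS else 0 for v in df.pop("label")])
    child_ids = list(df.pop("child_id"))
    return DesignMatrix(
        X=df, y=y, child_ids=child_ids, game_id=meta["game_id"], area=meta["area"],
        preprocessing=meta["preprocessing"],
    )
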