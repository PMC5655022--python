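"""End-to-end orchestration: cohort -> features -> labels -> CV -> reports.

Per (game, area, model) a repeated-stratified-CV result row is produced
under the selected preprocessing variant, alongside the feature-relevance
report and a provenance file sufficient to reproduce every output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .assessment import AREAS, Instrument, area_scores, default_instrument
from .dataset import (
    DesignMatrix,
    SessionFeatures,
    build_diff_samples,
    impute_missing,
    samples_to_matrix,
)
from .game_features import extract
from .models import CVResult, ModelSpec, repeated_stratified_cv
from .relevance import rank_indicators, relevance_records, write_report_tsv
from .session import ExtractionConfig, GAME_IDS, SessionRecord, read_manifest, read_session
from .simulate import Cohort, CohortConfig, simulate_cohort

log = logging.getLogger(__name__)

DEFAULT_MODELS = ("decision_tree", "naive_bayes", "random_forest")

#: variant -> (normalize, pca_threshold)
VARIANT_SETTINGS: dict[str, tuple[bool, float | None]] = {
    "raw": (False, None),
    "raw_pca": (False, 0.95),
    "norm": (True, None),
    "norm_pca": (True, 0.95),
}


@dataclass
class PipelineConfig:
    cohort: CohortConfig | str | Path = field(default_factory=CohortConfig)
    variant: str = "norm"
    games: Sequence[str] = GAME_IDS
    areas: Sequence[str] = AREAS
    mode: str = "first_last"
    models: Sequence[str] = DEFAULT_MODELS
    folds: int = 10
    repetitions: int = 10
    top_k: int = 5
    out_dir: str | Path = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_SETTINGS:
            raise ValueError(f"variant must be one of {tuple(VARIANT_SETTINGS)}")
        if self.mode not in ("first_last", "consecutive"):
            raise ValueError("mode must be first_last or consecutive")


def extract_cohort(
    sessions: Sequence[SessionRecord],
    config: ExtractionConfig | None = None,
    instrument: Instrument | None = None,
) -> list[SessionFeatures]:
    """Feature vectors and area scores for every session record."""
    config = config or ExtractionConfig()
    instrument = instrument or default_instrument()
    out: list[SessionFeatures] = []
    for record in sessions:
        sf = SessionFeatures(child_id=record.child_id, session_index=record.session_index)
        for game_id, rec in record.recordings.items():
            sf.vectors[game_id] = extract(rec, config)
        if record.questionnaire is not None:
            sf.scores = area_scores(record.questionnaire, instrument)
        out.append(sf)
    return out


def load_cohort_dir(path: str | Path) -> list[SessionRecord]:
    """Read a cohort directory written by the simulate CLI (manifest.csv
    pointing at per-session JSONL files)."""
    path = Path(path)
    manifest = read_manifest(path / "manifest.csv")
    return [read_session(path / file) for _, _, file in manifest]


def evaluate_matrix(
    matrix: DesignMatrix,
    models: Sequence[str],
    variant: str,
    folds: int,
    repetitions: int,
    seed: int,
) -> list[CVResult]:
    normalize, pca_threshold = VARIANT_SETTINGS[variant]
    results = []
    for name in models:
        spec = ModelSpec(name=name, seed=seed)
        results.append(
            repeated_stratified_cv(
                spec,
                matrix,
                folds=folds,
                repetitions=repetitions,
                seed=seed,
                normalize=normalize,
                pca_threshold=pca_threshold,
            )
        )
    return results


def results_table(results: Sequence[CVResult]) -> pd.DataFrame:
    """Mirror the published results layout: percentages, two decimals."""
    rows = []
    for r in results:
        game, area = r.dataset.split("/")
        m = r.metrics
        rows.append(
            {
                "game": game,
                "area": area,
                "method": r.spec.name,
                "accuracy_pct": round(100 * r.mean_accuracy, 2),
                "ci_pct": round(100 * r.ci_halfwidth, 2),
                "precision_p_pct": round(100 * m["progress"]["precision"], 2),
                "precision_n_pct": round(100 * m["no_progress"]["precision"], 2),
                "recall_p_pct": round(100 * m["progress"]["recall"], 2),
                "recall_n_pct": round(100 * m["no_progress"]["recall"], 2),
                "f_p_pct": round(100 * m["progress"]["f"], 2),
                "f_n_pct": round(100 * m["no_progress"]["f"], 2),
                "n_samples": r.confusion.total // r.repetitions,
                "folds": r.folds,
                "repetitions": r.repetitions,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if isinstance(config.cohort, (str, Path)):
        sessions = load_cohort_dir(config.cohort)
        cohort_desc: dict = {"source": str(config.cohort)}
    else:
        cohort = simulate_cohort(config.cohort)
        sessions = cohort.sessions
        cohort_desc = {"source": "simulated", "n_children": config.cohort.n_children,
                       "seed": config.cohort.seed}
    log.info("cohort ready: %d sessions (%.1fs)", len(sessions), time.perf_counter() - t0)

    features = extract_cohort(sessions)
    log.info("features extracted (%.1fs)", time.perf_counter() - t0)

    all_results: list[CVResult] = []
    for game_id in config.games:
        for area in config.areas:
            try:
                samples = build_diff_samples(features, game_id, area, mode=config.mode)
                if not samples:
                    continue
                matrix = impute_missing(samples_to_matrix(samples))
                all_results.extend(
                    evaluate_matrix(
                        matrix, config.models, config.variant,
                        config.folds, config.repetitions, config.seed,
                    )
                )
            except ValueError as exc:
                log.warning("skipping %s/%s: %s", game_id, area, exc)
    log.info("cross-validation done: %d results (%.1fs)", len(all_results), time.perf_counter() - t0)

    outputs: dict[str, Path] = {}
    results_path = out_dir / "results.csv"
    results_table(all_results).to_csv(results_path, index=False)
    outputs["results"] = results_path

    records = relevance_records(features, games=config.games, areas=config.areas)
    report = rank_indicators(records, top_k=config.top_k)
    relevance_path = out_dir / "relevance.tsv"
    write_report_tsv(report, relevance_path)
    outputs["relevance"] = relevance_path

    provenance_path = out_dir / "provenance.json"
    provenance_path.write_text(
        json.dumps(
            {
                "package_version": __version__,
                "seed": config.seed,
                "variant": config.variant,
                "mode": config.mode,
                "games": list(config.games),
                "areas": list(config.areas),
                "models": list(config.models),
                "folds": config.folds,
                "repetitions": config.repetitions,
                "cohort": cohort_desc,
            },
            indent=2,
            sort_keys=True,
        )
    )
    outputs["provenance"] = provenance_path
    log.info("pipeline complete (%.1fs)", time.perf_counter() - t0)
    return outputs
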