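"""End-to-end orchestration: trials + image metadata → results bundle.

``run_analysis`` chains ingest → mixed models → metamemory comparison →
consistency analysis and returns an :class:`AnalysisResults` bundle that
``write_results`` serializes as a directory of JSON/CSV files (no binary
formats).  Every results file embeds the config hash and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import consistency as cons
from . import ingest, metamemory
from .config import RunConfig, config_hash
from .errors import StructuralError
from .mixed import ModelFit, compare_models_aic, fit_rating_lmm, fit_recognition_glmm

logger = logging.getLogger("lepmem")


@dataclass
class AnalysisResults:
    config: RunConfig
    exclusion: ingest.ExclusionReport
    image_scores: pd.DataFrame
    rating_fit: Optional[ModelFit] = None
    recognition_fit: Optional[ModelFit] = None
    model_comparison: Optional[pd.DataFrame] = None
    spearman: list[metamemory.SpearmanResult] = field(default_factory=list)
    discrepancy: Optional[pd.DataFrame] = None
    reliability: Optional[dict[str, cons.ConsistencyResult]] = None
    delta_rho: Optional[float] = None
    delta_p: Optional[float] = None
    curves: Optional[cons.CurveSet] = None
    rank_table: Optional[pd.DataFrame] = None
    n_trials_read: int = 0


def run_analysis(
    trials: pd.DataFrame, images: pd.DataFrame, config: RunConfig
) -> AnalysisResults:
    """Run the configured analysis stages on validated input tables."""
    n_read = len(trials)
    retained, report = ingest.apply_vigilance_exclusion(trials)
    retained = ingest.normalize_ratings(retained)
    excluded = list(config.excluded_images)
    analysed = retained[~retained["image_id"].isin(excluded)].reset_index(drop=True)
    logger.info(
        "rows: %d read, %d after participant exclusion, %d after image exclusion",
        n_read, len(retained), len(analysed),
    )
    scores = ingest.compute_image_scores(analysed, images, excluded_images=excluded)
    results = AnalysisResults(
        config=config, exclusion=report, image_scores=scores, n_trials_read=n_read
    )

    if config.run_models:
        results.rating_fit = fit_rating_lmm(analysed, images)
        results.recognition_fit = fit_recognition_glmm(analysed, images)
        rating_null = fit_rating_lmm(analysed, images, random="intercepts")
        recog_null = fit_recognition_glmm(analysed, images, random="intercepts")
        tables = []
        for label, pair in (
            ("rating", [results.rating_fit, rating_null]),
            ("recognition", [results.recognition_fit, recog_null]),
        ):
            t = compare_models_aic(pair)
            t.insert(0, "response", label)
            tables.append(t)
        results.model_comparison = pd.concat(tables, ignore_index=True)

    if config.run_comparison:
        results.spearman = [
            metamemory.correlate_rating_hit(scores, scope)
            for scope in metamemory.SCOPES
        ]
        results.discrepancy = metamemory.build_discrepancy_table(scores)

    if config.run_consistency:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        matrix, pids, iids = cons.make_matrix(analysed)
        class_map = images.set_index("image_id")["lepidoptera_class"]
        classes = class_map.reindex(iids).to_numpy()
        if pd.isna(classes).any():
            raise StructuralError("trial images missing from image metadata")
        its, rel = cons.split_half_reliability(
            matrix,
            classes,
            iids,
            pids,
            n_iterations=config.n_iterations,
            n_bootstrap=config.n_bootstrap,
            rng=rng,
        )
        delta, p = cons.permutation_test_delta_rho(
            matrix,
            classes,
            n_permutations=config.n_permutations,
            rng=rng,
            iterations=its,
        )
        rel["AP"].delta_rho = delta
        rel["AP"].delta_p = p
        curves = cons.cumulative_curves(
            its, classes, rng=rng, n_bootstrap=config.n_bootstrap
        )
        rank_table = cons.rank_tests(
            curves,
            n_permutations=config.n_permutations,
            n_bootstrap=config.n_bootstrap,
            rng=rng,
        )
        results.reliability = rel
        results.delta_rho = delta
        results.delta_p = p
        results.curves = curves
        results.rank_table = rank_table

    return results


def write_results(results: AnalysisResults, out_dir: str | Path) -> None:
    """Serialize the bundle to ``out_dir`` as JSON + CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config_hash(results.config), "seed": results.config.seed}

    def dump(name: str, payload: dict) -> None:
        with open(out / name, "w", encoding="utf-8") as fh:
            json.dump({**stamp, **payload}, fh, indent=1, sort_keys=True, default=float)

    dump("run_meta.json", {
        "config": results.config.to_dict(),
        "n_trials_read": results.n_trials_read,
    })
    dump("exclusion_report.json", results.exclusion.to_dict())
    results.image_scores.to_csv(out / "image_scores.csv", index=False)

    if results.rating_fit is not None:
        dump("model_rating.json", results.rating_fit.to_dict())
    if results.recognition_fit is not None:
        dump("model_recognition.json", results.recognition_fit.to_dict())
    if results.model_comparison is not None:
        results.model_comparison.to_csv(out / "model_comparison.csv", index=False)
    if results.spearman:
        dump("spearman.json", {"correlations": [s.to_dict() for s in results.spearman]})
    if results.discrepancy is not None:
        results.discrepancy.to_csv(out / "discrepancy.csv", index=False)
    if results.reliability is not None:
        dump("consistency.json", {
            "reliability": {k: v.to_dict() for k, v in results.reliability.items()},
            "delta_rho": results.delta_rho,
            "delta_p": results.delta_p,
        })
        results.curves.to_frame().to_csv(out / "curves.csv", index=False)
        results.rank_table.to_csv(out / "rank_tests.csv", index=False)
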