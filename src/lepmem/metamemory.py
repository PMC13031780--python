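"""Metamemory–recognition comparison: rank correlations and the
"think memorable / is memorable" discrepancy analysis.

Across images, the mean normalized metamemory rating is compared with the
recognition hit rate.  Spearman rank correlations (average ranks for ties)
are computed overall and per class.  The discrepancy analysis ranks images by
``mean_rating − hit_rate``: the largest positive differences are labelled
"thought memorable but actually forgettable", the largest negative ones
"thought forgettable but actually memorable".  Among the images where the two
measures agree best (lowest quintile of |difference|), those with both
measures above their own 60th percentile are "memorable-expected" and those
with both below their 40th percentile are "forgettable-expected"; percentiles
use the linear-interpolation convention.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

__all__ = [
    "SpearmanResult",
    "correlate_rating_hit",
    "build_discrepancy_table",
    "QUADRANT_LABELS",
]

QUADRANT_LABELS = (
    "memorable-expected",
    "forgettable-expected",
    "thought-memorable-but-forgettable",
    "thought-forgettable-but-memorable",
    "unclassified",
)

SCOPES = ("all", "AP", "nonAP")


@dataclass
class SpearmanResult:
    scope: str
    rho: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _scope_scores(scores: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "all":
        return scores
    if scope not in ("AP", "nonAP"):
        raise ValueError(f"unknown scope {scope!r}")
    return scores[scores["lepidoptera_class"] == scope]


def correlate_rating_hit(scores: pd.DataFrame, scope: str = "all") -> SpearmanResult:
    """Spearman correlation between per-image mean rating and hit rate."""
    sub = _scope_scores(scores, scope)
    if len(sub) < 3:
        raise DegenerateDataError(f"scope {scope!r} has fewer than 3 images")
    x = sub["mean_rating"].to_numpy(dtype=float)
    y = sub["hit_rate"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError(
            f"scope {scope!r}: constant vector, rank correlation undefined"
        )
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(scope=scope, rho=float(rho), p_value=float(p), n=len(sub))


def build_discrepancy_table(
    scores: pd.DataFrame,
    upper_pct: float = 60.0,
    lower_pct: float = 40.0,
    n_exemplars: int = 6,
) -> pd.DataFrame:
    """Label each image by how its metamemory rating matched its hit rate.

    Returns the scores table augmented with ``difference`` (mean_rating −
    hit_rate), ``rank`` (1 = largest positive difference; ties broken by
    image id), and ``quadrant``.  The ``n_exemplars`` images with the largest
    positive/negative differences receive the two "unexpected" labels; the
    expected labels are assigned within the lowest quintile of |difference|
    by comparing both measures against their own percentile thresholds, with
    the ``n_exemplars`` most extreme exemplars kept per category.  Category
    mean rating/hit rate are attached as a DataFrame ``attrs['category_means']``.
    """
    if len(scores) < 2 * n_exemplars:
        raise DegenerateDataError(
            f"need at least {2 * n_exemplars} images, got {len(scores)}"
        )
    table = scores.copy().reset_index(drop=True)
    table["difference"] = table["mean_rating"] - table["hit_rate"]
    order = table.sort_values(
        ["difference", "image_id"], ascending=[False, True], kind="stable"
    ).index
    rank = pd.Series(np.arange(1, len(table) + 1), index=order)
    table["rank"] = rank.sort_index()

    labels = np.full(len(table), "unclassified", dtype=object)
    diff = table["difference"].to_numpy()

    # unexpected: strongest mismatches in either direction (strict sign)
    pos_order = [i for i in order if diff[i] > 0][:n_exemplars]
    neg_order = [i for i in reversed(order.tolist()) if diff[i] < 0][:n_exemplars]
    labels[pos_order] = "thought-memorable-but-forgettable"
    labels[neg_order] = "thought-forgettable-but-memorable"

    # expected: best-matching pool = lowest quintile of |difference|
    absdiff = np.abs(diff)
    pool_cut = np.percentile(absdiff, 20.0, method="linear")
    rating_hi = np.percentile(table["mean_rating"], upper_pct, method="linear")
    rating_lo = np.percentile(table["mean_rating"], lower_pct, method="linear")
    hit_hi = np.percentile(table["hit_rate"], upper_pct, method="linear")
    hit_lo = np.percentile(table["hit_rate"], lower_pct, method="linear")

    pool = [
        i
        for i in np.lexsort((table["image_id"].to_numpy(), absdiff))
        if absdiff[i] <= pool_cut and labels[i] == "unclassified"
    ]
    mem = [
        i
        for i in pool
        if table.at[i, "mean_rating"] > rating_hi and table.at[i, "hit_rate"] > hit_hi
    ]
    forg = [
        i
        for i in pool
        if table.at[i, "mean_rating"] < rating_lo and table.at[i, "hit_rate"] < hit_lo
    ]
    # "most extreme" exemplars within each expected set: highest (resp. lowest)
    # combined level of the two measures
    level = (table["mean_rating"] + table["hit_rate"]).to_numpy()
    mem = sorted(mem, key=lambda i: (-level[i], table.at[i, "image_id"]))[:n_exemplars]
    forg = sorted(forg, key=lambda i: (level[i], table.at[i, "image_id"]))[:n_exemplars]
    labels[mem] = "memorable-expected"
    labels[forg] = "forgettable-expected"

    table["quadrant"] = labels
    means = (
        table[table["quadrant"] != "unclassified"]
        .groupby("quadrant")[["mean_rating", "hit_rate"]]
        .mean()
    )
    table.attrs["category_means"] = means
    return table
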