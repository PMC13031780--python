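"""Cross-observer memorability consistency analysis.

The participant pool is repeatedly split into two random halves (groups *j*
and *k*); per-image hit rates are computed within each half and compared:

* **Split-half reliability** — Spearman correlation of the two half-pool
  hit-rate vectors, corrected with the Spearman-Brown formula ``2r/(1+r)``,
  averaged over splits, with bootstrap 95% CIs; computed overall and per
  class on the *same* splits.
* **Δρ permutation test** — the AP − nonAP reliability difference compared
  against a null built by permuting class labels across images (splits held
  fixed); one-sided by default (shuffled Δρ ≥ observed), p reported with a
  resolution floor of 1/n_permutations.
* **Cumulative hit-rate curves** — images sorted by group-j hit rate
  (descending, ties by image id); cumulative means of the top-n images traced
  for group j, group k under j's ordering, and a shuffled baseline in which
  the image ↔ hit-rate association of group k is randomly permuted within the
  scope.  Ranks run from top-2 to top-M.
* **Per-rank inference** — per-iteration cumulative differences (j−k,
  k−shuffled, and the between-class k−shuffled excess) tested with sign-flip
  permutation tests, Bonferroni-corrected within each rank family, plus
  bootstrap CIs.

Everything is driven by a single :class:`numpy.random.Generator`, so a fixed
seed reproduces the analysis bit for bit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateDataError, StructuralError

__all__ = [
    "SplitIterations",
    "ConsistencyResult",
    "CurveSet",
    "make_matrix",
    "spearman_brown",
    "rowwise_spearman",
    "split_half_reliability",
    "permutation_test_delta_rho",
    "cumulative_curves",
    "rank_tests",
]

logger = logging.getLogger("lepmem")

SCOPES = ("all", "AP", "nonAP")


@dataclass
class SplitIterations:
    """Per-iteration half-pool hit-rate vectors from random participant splits."""

    image_ids: np.ndarray             # (M,) column order of the matrix
    participant_ids: np.ndarray       # (P,)
    group_j: np.ndarray               # (n_iter, floor(P/2)) participant indices
    group_k: np.ndarray               # (n_iter, ceil(P/2))
    hj: np.ndarray                    # (n_iter, M) group-j hit rates per image
    hk: np.ndarray                    # (n_iter, M)

    @property
    def n_iterations(self) -> int:
        return self.hj.shape[0]


@dataclass
class ConsistencyResult:
    """Split-half reliability for one scope, averaged over iterations."""

    scope: str
    rho_mean: float
    ci95: tuple[float, float]
    n_iterations: int                 # iterations contributing (non-missing)
    n_missing: int
    values: np.ndarray = field(repr=False)   # per-iteration corrected rho (nan = missing)
    delta_rho: Optional[float] = None        # attached on the AP result by the Δρ test
    delta_p: Optional[float] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("values")
        d["ci95"] = [float(self.ci95[0]), float(self.ci95[1])]
        return d


@dataclass
class CurveSet:
    """Cumulative hit-rate curves per scope with per-iteration difference series."""

    ranks: dict[str, np.ndarray]              # scope -> rank vector (2..M)
    mean_j: dict[str, np.ndarray]
    mean_k: dict[str, np.ndarray]
    mean_shuffled: dict[str, np.ndarray]
    ci_j: dict[str, np.ndarray]               # (2, R) bootstrap 95% bands
    ci_k: dict[str, np.ndarray]
    ci_shuffled: dict[str, np.ndarray]
    diffs_jk: dict[str, np.ndarray] = field(repr=False)    # (n_iter, R)
    diffs_ks: dict[str, np.ndarray] = field(repr=False)    # (n_iter, R)
    grand_mean: dict[str, float] = field(default_factory=dict)
    curves_j: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    curves_k: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    curves_shuffled: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scope, ranks in self.ranks.items():
            for i, r in enumerate(ranks):
                rows.append(
                    {
                        "scope": scope,
                        "rank": int(r),
                        "mean_j": self.mean_j[scope][i],
                        "mean_k": self.mean_k[scope][i],
                        "mean_shuffled": self.mean_shuffled[scope][i],
                        "ci_j_lo": self.ci_j[scope][0, i],
                        "ci_j_hi": self.ci_j[scope][1, i],
                        "ci_k_lo": self.ci_k[scope][0, i],
                        "ci_k_hi": self.ci_k[scope][1, i],
                        "ci_shuffled_lo": self.ci_shuffled[scope][0, i],
                        "ci_shuffled_hi": self.ci_shuffled[scope][1, i],
                    }
                )
        return pd.DataFrame(rows)


def make_matrix(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Participant × image binary outcome matrix from target recognition rows.

    Returns ``(matrix, participant_ids, image_ids)`` with rows/columns sorted
    by id.  Every participant must have exactly one trial per image.
    """
    rec = trials[(trials["block"] == "recognition") & (trials["role"] == "target")]
    if rec.empty:
        raise StructuralError("no target recognition trials")
    dup = rec.duplicated(subset=["participant_id", "image_id"])
    if dup.any():
        pair = rec[dup].iloc[0]
        raise StructuralError(
            f"duplicated trial for participant {pair['participant_id']!r}, "
            f"image {pair['image_id']!r}"
        )
    pivot = rec.pivot(index="participant_id", columns="image_id", values="response")
    pivot = pivot.sort_index(axis=0).sort_index(axis=1)
    if pivot.isna().any().any():
        missing = np.argwhere(pivot.isna().to_numpy())[0]
        raise StructuralError(
            f"missing participant×image cell: participant "
            f"{pivot.index[missing[0]]!r}, image {pivot.columns[missing[1]]!r}"
        )
    matrix = (pivot == "old").to_numpy(dtype=float)
    return matrix, pivot.index.to_numpy(), pivot.columns.to_numpy()


def spearman_brown(r: float) -> float:
    """Spearman-Brown step-up correction ``2r/(1+r)`` for a split-half
    correlation; undefined at r = −1."""
    r = float(r)
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    if r == -1.0:
        raise DegenerateDataError("Spearman-Brown correction undefined at r = -1")
    return 2.0 * r / (1.0 + r)


def rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row of ``a`` with the same row of ``b``
    (average ranks for ties); rows with a constant vector give NaN."""
    ra = rankdata(a, axis=1)
    rb = rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    va = np.einsum("ij,ij->i", ra, ra)
    vb = np.einsum("ij,ij->i", rb, rb)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.einsum("ij,ij->i", ra, rb) / np.sqrt(va * vb)
    out[(va == 0) | (vb == 0)] = np.nan
    return out


def _generate_splits(
    n_participants: int, n_iterations: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint halves; with odd pools the extra participant joins k."""
    if n_participants < 4:
        raise DegenerateDataError("need at least 4 participants to split")
    half = n_participants // 2
    perms = np.empty((n_iterations, n_participants), dtype=np.intp)
    for i in range(n_iterations):
        perms[i] = rng.permutation(n_participants)
    return perms[:, :half], perms[:, half:]


def compute_split_iterations(
    matrix: np.ndarray,
    image_ids: Sequence[str],
    participant_ids: Sequence[str],
    n_iterations: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> SplitIterations:
    """Draw ``n_iterations`` random half-splits and their hit-rate vectors."""
    rng = np.random.default_rng() if rng is None else rng
    matrix = np.asarray(matrix, dtype=float)
    gj, gk = _generate_splits(matrix.shape[0], n_iterations, rng)
    hj = matrix[gj].mean(axis=1)      # (n_iter, half, M) -> (n_iter, M)
    hk = matrix[gk].mean(axis=1)
    return SplitIterations(
        image_ids=np.asarray(image_ids),
        participant_ids=np.asarray(participant_ids),
        group_j=gj,
        group_k=gk,
        hj=hj,
        hk=hk,
    )


def _scope_columns(classes: np.ndarray, scope: str) -> np.ndarray:
    if scope == "all":
        return np.arange(len(classes))
    return np.flatnonzero(classes == scope)


def _corrected_rhos(it: SplitIterations, cols: np.ndarray) -> np.ndarray:
    r = rowwise_spearman(it.hj[:, cols], it.hk[:, cols])
    with np.errstate(invalid="ignore", divide="ignore"):
        corrected = 2.0 * r / (1.0 + r)
    corrected[r == -1.0] = np.nan
    return corrected


def bootstrap_mean_ci(
    values: np.ndarray,
    n_bootstrap: int,
    rng: np.random.Generator,
    q: tuple[float, float] = (2.5, 97.5),
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of ``values`` (NaNs dropped)."""
    vals = values[~np.isnan(values)]
    if len(vals) == 0:
        return (np.nan, np.nan)
    idx = rng.integers(0, len(vals), size=(n_bootstrap, len(vals)))
    means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(means, q)
    return (float(lo), float(hi))


def split_half_reliability(
    matrix: np.ndarray,
    classes: np.ndarray,
    image_ids: Optional[Sequence[str]] = None,
    participant_ids: Optional[Sequence[str]] = None,
    n_iterations: int = 1000,
    n_bootstrap: int = 1000,
    rng: Optional[np.random.Generator] = None,
    iterations: Optional[SplitIterations] = None,
) -> tuple[SplitIterations, dict[str, ConsistencyResult]]:
    """Spearman-Brown corrected split-half reliability per scope.

    The per-class reliabilities reuse the same participant splits as the
    overall value.  Iterations whose half-pool hit-rate vector is constant in
    a scope are recorded as missing there and excluded from the mean and CI.
    """
    rng = np.random.default_rng() if rng is None else rng
    matrix = np.asarray(matrix, dtype=float)
    classes = np.asarray(classes)
    if matrix.shape[1] != len(classes):
        raise StructuralError("class vector length does not match matrix columns")
    if image_ids is None:
        image_ids = np.arange(matrix.shape[1]).astype(str)
    if participant_ids is None:
        participant_ids = np.arange(matrix.shape[0]).astype(str)
    if iterations is None:
        iterations = compute_split_iterations(
            matrix, image_ids, participant_ids, n_iterations, rng
        )

    results: dict[str, ConsistencyResult] = {}
    for scope in SCOPES:
        cols = _scope_columns(classes, scope)
        if len(cols) < 3:
            raise DegenerateDataError(f"scope {scope!r} has fewer than 3 images")
        vals = _corrected_rhos(iterations, cols)
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            logger.warning(
                "scope %s: %d of %d split iterations degenerate (constant vector)",
                scope, n_missing, len(vals),
            )
        results[scope] = ConsistencyResult(
            scope=scope,
            rho_mean=float(np.nanmean(vals)),
            ci95=bootstrap_mean_ci(vals, n_bootstrap, rng),
            n_iterations=len(vals) - n_missing,
            n_missing=n_missing,
            values=vals,
        )
    return iterations, results


def permutation_test_delta_rho(
    matrix: np.ndarray,
    classes: np.ndarray,
    n_permutations: int = 1000,
    rng: Optional[np.random.Generator] = None,
    n_iterations: int = 1000,
    iterations: Optional[SplitIterations] = None,
    two_sided: bool = False,
) -> tuple[float, float]:
    """Permutation test of Δρ = reliability(AP) − reliability(nonAP).

    Class labels are permuted across images (class sizes preserved) with the
    participant splits held fixed; the one-sided p-value is the proportion of
    shuffled Δρ ≥ observed Δρ, floored at 1/n_permutations.
    """
    rng = np.random.default_rng() if rng is None else rng
    matrix = np.asarray(matrix, dtype=float)
    classes = np.asarray(classes)
    for cls in ("AP", "nonAP"):
        if (classes == cls).sum() < 3:
            raise DegenerateDataError(f"class {cls!r} has fewer than 3 images")
    if iterations is None:
        iterations = compute_split_iterations(
            matrix,
            np.arange(matrix.shape[1]).astype(str),
            np.arange(matrix.shape[0]).astype(str),
            n_iterations,
            rng,
        )

    def delta(labels: np.ndarray) -> float:
        ap = np.nanmean(_corrected_rhos(iterations, np.flatnonzero(labels == "AP")))
        non = np.nanmean(_corrected_rhos(iterations, np.flatnonzero(labels == "nonAP")))
        return ap - non

    observed = delta(classes)
    count = 0
    for _ in range(n_permutations):
        shuffled = classes[rng.permutation(len(classes))]
        d = delta(shuffled)
        if two_sided:
            count += abs(d) >= abs(observed)
        else:
            count += d >= observed
    p = max(count / n_permutations, 1.0 / n_permutations)
    return float(observed), float(p)


def cumulative_curves(
    iterations: SplitIterations,
    classes: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    n_bootstrap: int = 1000,
    scopes: Sequence[str] = SCOPES,
) -> CurveSet:
    """Cumulative mean hit-rate curves (group j, group k, shuffled baseline).

    Within each scope, images are sorted by group-j hit rate (descending,
    ties broken by image id) per iteration; the shuffled baseline permutes the
    image ↔ hit-rate association within group k, within the scope.
    """
    rng = np.random.default_rng() if rng is None else rng
    classes = np.asarray(classes)
    cs = CurveSet({}, {}, {}, {}, {}, {}, {}, {}, {})
    for scope in scopes:
        cols = _scope_columns(classes, scope)
        m = len(cols)
        if m < 4:
            raise DegenerateDataError(f"scope {scope!r} has fewer than 4 images")
        hj = iterations.hj[:, cols]
        hk = iterations.hk[:, cols]
        # stable argsort on negated values: ties fall back to column (image id) order
        order = np.argsort(-hj, axis=1, kind="stable")
        denom = np.arange(1, m + 1, dtype=float)
        cum_j = np.cumsum(np.take_along_axis(hj, order, axis=1), axis=1) / denom
        cum_k = np.cumsum(np.take_along_axis(hk, order, axis=1), axis=1) / denom
        cum_s = np.cumsum(rng.permuted(hk, axis=1), axis=1) / denom
        sl = slice(1, m)  # ranks 2..M
        ranks = np.arange(2, m + 1)
        idx = rng.integers(0, cum_j.shape[0], size=(n_bootstrap, cum_j.shape[0]))

        def band(curves: np.ndarray) -> np.ndarray:
            boot = curves[idx].mean(axis=1)
            return np.percentile(boot, [2.5, 97.5], axis=0)

        cs.ranks[scope] = ranks
        cs.mean_j[scope] = cum_j[:, sl].mean(axis=0)
        cs.mean_k[scope] = cum_k[:, sl].mean(axis=0)
        cs.mean_shuffled[scope] = cum_s[:, sl].mean(axis=0)
        cs.ci_j[scope] = band(cum_j[:, sl])
        cs.ci_k[scope] = band(cum_k[:, sl])
        cs.ci_shuffled[scope] = band(cum_s[:, sl])
        cs.diffs_jk[scope] = cum_j[:, sl] - cum_k[:, sl]
        cs.diffs_ks[scope] = cum_k[:, sl] - cum_s[:, sl]
        cs.grand_mean[scope] = float(iterations.hk[:, cols].mean())
        cs.curves_j[scope] = cum_j[:, sl]
        cs.curves_k[scope] = cum_k[:, sl]
        cs.curves_shuffled[scope] = cum_s[:, sl]
    return cs


def _sign_flip_p(
    diffs: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Sign-flip permutation p per column of the (n_iter, R) difference array.

    One flip matrix is shared across the ranks of a family (common random
    numbers); p is the proportion of flipped mean magnitudes ≥ the observed
    magnitude, floored at 1/n_permutations.
    """
    n_iter = diffs.shape[0]
    obs = np.abs(diffs.mean(axis=0))
    signs = rng.integers(0, 2, size=(n_permutations, n_iter)) * 2.0 - 1.0
    flipped = np.abs(signs @ diffs) / n_iter          # (n_perm, R)
    count = (flipped >= obs[None, :] - 1e-15).sum(axis=0)
    return np.maximum(count / n_permutations, 1.0 / n_permutations)


def rank_tests(
    curve_set: CurveSet,
    n_permutations: int = 1000,
    n_bootstrap: int = 1000,
    rng: Optional[np.random.Generator] = None,
    scopes: Sequence[str] = ("AP", "nonAP"),
) -> pd.DataFrame:
    """Per-rank inference on the cumulative-curve differences.

    Families tested (each Bonferroni-corrected over its own ranks):
    per scope, group j vs group k and group k vs shuffled; between classes,
    the k-minus-shuffled excess of AP vs nonAP (the surplus nonAP rank is
    dropped so the rank grids align).
    """
    rng = np.random.default_rng() if rng is None else rng
    n_iters = {
        d.shape[0]
        for store in (curve_set.diffs_jk, curve_set.diffs_ks)
        for d in store.values()
    }
    if len(n_iters) > 1:
        raise StructuralError("difference series have mismatched iteration counts")
    families: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    for scope in scopes:
        families.append((scope, "j_vs_k", curve_set.ranks[scope], curve_set.diffs_jk[scope]))
        families.append(
            (scope, "k_vs_shuffled", curve_set.ranks[scope], curve_set.diffs_ks[scope])
        )
    if "AP" in curve_set.diffs_ks and "nonAP" in curve_set.diffs_ks:
        d_ap = curve_set.diffs_ks["AP"]
        d_non = curve_set.diffs_ks["nonAP"]
        n_common = min(d_ap.shape[1], d_non.shape[1])
        families.append(
            (
                "between",
                "excess_AP_vs_nonAP",
                curve_set.ranks["AP"][:n_common],
                d_ap[:, :n_common] - d_non[:, :n_common],
            )
        )

    rows = []
    for scope, comparison, ranks, diffs in families:
        p_raw = _sign_flip_p(diffs, n_permutations, rng)
        p_adj = np.minimum(p_raw * len(ranks), 1.0)
        idx = rng.integers(0, diffs.shape[0], size=(n_bootstrap, diffs.shape[0]))
        boot = diffs[idx].mean(axis=1)
        ci = np.percentile(boot, [2.5, 97.5], axis=0)
        mean_diff = diffs.mean(axis=0)
        for i, r in enumerate(ranks):
            rows.append(
                {
                    "scope": scope,
                    "comparison": comparison,
                    "rank": int(r),
                    "mean_diff": mean_diff[i],
                    "ci_lo": ci[0, i],
                    "ci_hi": ci[1, i],
                    "p_raw": p_raw[i],
                    "p_bonferroni": p_adj[i],
                }
            )
    return pd.DataFrame(rows)
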