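"""Mixed-effects models for trial-level ratings and recognition outcomes.

Two models mirror the study's analysis:

* ``rating ~ class + (class | participant)`` — Gaussian linear mixed model on
  the normalized metamemory ratings, fitted by REML (statsmodels ``MixedLM``);
* ``recognition ~ class + (class | participant)`` — binomial-logit GLMM on
  hit/miss outcomes, fitted by Laplace-approximated maximum likelihood
  (:mod:`lepmem.glmm`).

Class is treatment-coded with nonAP as the reference, so the reported fixed
effect is the AP − nonAP difference.  Non-convergent or singular fits trigger
an automatic fallback chain (drop the intercept–slope correlation, then drop
the slope), each step logged on the returned :class:`ModelFit`.

Variance explained is summarized with Nakagawa's marginal/conditional R²:
``R²_m = var_f / (var_f + var_r + var_e)`` and
``R²_c = (var_f + var_r) / (var_f + var_r + var_e)`` where ``var_f`` is the
variance of the fixed-effect predictions, ``var_r`` the mean random-effect
variance ``z_i' Σ z_i`` across rows, and ``var_e`` the residual variance
(the theoretical latent-scale value ``π²/3`` for the logit family).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from . import glmm as _glmm
from .errors import DegenerateDataError, NotConvergedError
from .ingest import normalize_ratings

__all__ = [
    "ModelFit",
    "prepare_model_frame",
    "fit_rating_lmm",
    "fit_recognition_glmm",
    "nakagawa_r2",
    "compare_models_aic",
]

logger = logging.getLogger("lepmem")

LOGIT_RESIDUAL_VAR = np.pi**2 / 3.0


@dataclass
class ModelFit:
    """Summary of a fitted mixed model.

    ``beta``/``se``/``stat``/``p_value`` describe the class fixed effect
    (AP − nonAP); ``beta_all`` holds the full fixed-effect vector in design
    order (intercept, class, extras) and ``cov_re`` the random-effect
    covariance matrix, both needed to recompute R².
    """

    formula_label: str
    family: str                      # "gaussian" | "binomial-logit"
    beta: float
    se: float
    stat: float
    p_value: float
    intercept: float
    re_intercept_sd: float
    re_slope_sd: float
    re_correlation: float
    aic: float
    r2_marginal: float
    r2_conditional: float
    converged: bool
    n_obs: int
    n_groups: int
    beta_all: list[float]
    fixed_names: list[str]
    cov_re: list[list[float]]
    resid_var: float
    fallback: Optional[str] = None
    response_checksum: Optional[int] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=float)

    def summary(self) -> str:
        lines = [
            self.formula_label,
            f"  family: {self.family}   n_obs: {self.n_obs}   groups: {self.n_groups}",
            f"  class effect (AP - nonAP): beta = {self.beta:.4f}, SE = {self.se:.4f}, "
            f"{'z' if self.family.startswith('binomial') else 't'} = {self.stat:.2f}, "
            f"p = {self.p_value:.4g}",
            f"  random effects: intercept SD = {self.re_intercept_sd:.4f}, "
            f"slope SD = {self.re_slope_sd:.4f}, corr = {self.re_correlation:.3f}",
            f"  AIC = {self.aic:.1f}   R2_marginal = {self.r2_marginal:.4f}   "
            f"R2_conditional = {self.r2_conditional:.4f}",
        ]
        if self.fallback:
            lines.append(f"  note: {self.fallback}")
        return "\n".join(lines)


def prepare_model_frame(
    trials: pd.DataFrame,
    image_meta: Optional[pd.DataFrame] = None,
    block: str = "metamemory",
) -> pd.DataFrame:
    """Target rows of one block with a 0/1 ``class_AP`` column attached."""
    rows = trials[(trials["block"] == block) & (trials["role"] == "target")].copy()
    if "lepidoptera_class" not in rows.columns:
        if image_meta is None:
            raise DegenerateDataError(
                "trials lack a lepidoptera_class column and no image metadata given"
            )
        rows = rows.merge(
            image_meta[["image_id", "lepidoptera_class"]], on="image_id", how="left"
        )
    if rows["lepidoptera_class"].isna().any():
        raise DegenerateDataError("some target trials have no class label")
    rows["class_AP"] = (rows["lepidoptera_class"] == "AP").astype(float)
    return rows


def _checksum(frame: pd.DataFrame, response: str) -> int:
    key = frame[["participant_id", "image_id", response]].sort_values(
        ["participant_id", "image_id"], ignore_index=True
    )
    return int(pd.util.hash_pandas_object(key, index=False).sum() % (2**63))


def _variance_partition(
    X: np.ndarray, beta: np.ndarray, Z: np.ndarray, cov_re: np.ndarray, resid_var: float
) -> tuple[float, float, float]:
    var_f = float(np.var(X @ beta))
    d = cov_re.shape[0]
    Zd = Z[:, :d]
    var_r = float(np.mean(np.einsum("nd,de,ne->n", Zd, cov_re, Zd)))
    return var_f, var_r, resid_var


def _r2(var_f: float, var_r: float, var_e: float) -> tuple[float, float]:
    total = var_f + var_r + var_e
    if total <= 0:
        return 0.0, 0.0
    return var_f / total, (var_f + var_r) / total


def _fit_mixedlm(y, X, groups, exog_re, free, reml: bool = True):
    """MixedLM fit with a BFGS → Powell optimizer retry; None on failure."""
    model = MixedLM(y, X, groups=groups, exog_re=exog_re)
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "powell"):
            try:
                candidate = model.fit(reml=reml, free=free, maxiter=500, method=method)
            except Exception:
                continue
            if best is None:
                best = candidate
            if candidate.converged:
                return candidate
    return best


def fit_rating_lmm(
    trials: pd.DataFrame,
    image_meta: Optional[pd.DataFrame] = None,
    extra_fixed: Sequence[str] = (),
    random: str = "slopes",
    compute_aic: bool = True,
) -> ModelFit:
    """REML fit of ``rating ~ class + (class | participant)``.

    ``random``: "slopes" (correlated intercept + slope, the default),
    "slopes_nocorr", or "intercepts".  ``extra_fixed`` names additional
    numeric columns entered as fixed effects.  ``compute_aic=False`` skips
    the ML refit used for model comparison (AIC reported as NaN).
    """
    if "rating" not in trials.columns:
        trials = normalize_ratings(trials)
    frame = prepare_model_frame(trials, image_meta, block="metamemory")
    if len(frame["participant_id"].unique()) < 2:
        raise DegenerateDataError("need at least 2 participants")
    if frame["class_AP"].nunique() < 2:
        raise DegenerateDataError("both classes must be present")

    y = frame["rating"].astype(float).to_numpy()
    fixed_names = ["intercept", "class_AP", *extra_fixed]
    X = np.column_stack(
        [np.ones(len(frame)), frame["class_AP"].to_numpy()]
        + [frame[c].astype(float).to_numpy() for c in extra_fixed]
    )
    groups = frame["participant_id"].to_numpy()
    label = _label("rating", extra_fixed, random)

    if np.ptp(y) == 0.0:
        # constant response: the degenerate fit is reported, not hidden
        d = 2 if random.startswith("slopes") else 1
        fit = ModelFit(
            formula_label=label,
            family="gaussian",
            beta=0.0, se=0.0, stat=0.0, p_value=1.0,
            intercept=float(y[0]),
            re_intercept_sd=0.0, re_slope_sd=0.0, re_correlation=np.nan,
            aic=np.nan, r2_marginal=0.0, r2_conditional=0.0,
            converged=True,
            n_obs=len(y), n_groups=len(np.unique(groups)),
            beta_all=[float(y[0])] + [0.0] * (X.shape[1] - 1),
            fixed_names=fixed_names,
            cov_re=np.zeros((d, d)).tolist(),
            resid_var=0.0,
            fallback="degenerate fit: constant response",
        )
        return fit

    attempts = _lmm_attempts(random)
    result = None
    used = None
    fallback_note = None
    usable = None  # (structure, fit, note) — boundary/singular but valid estimates
    for structure in attempts:
        exog_re = X[:, :2] if structure != "intercepts" else X[:, :1]
        free = None
        if structure == "slopes_nocorr":
            free = MixedLMParams.from_components(
                fe_params=np.ones(X.shape[1]), cov_re=np.eye(2)
            )
        candidate = _fit_mixedlm(y, X, groups, exog_re, free)
        if candidate is None:
            logger.warning("LMM structure %s failed; falling back", structure)
            continue
        finite = (
            np.isfinite(candidate.fe_params).all()
            and np.isfinite(np.asarray(candidate.bse_fe)).all()
            and np.isfinite(candidate.scale)
        )
        if candidate.converged and finite:
            result = candidate
            used = structure
            if structure != attempts[0]:
                fallback_note = (
                    f"refit with random structure '{structure}' after non-convergence"
                )
                logger.warning("LMM %s", fallback_note)
            break
        if finite and usable is None:
            # boundary (singular) fit: estimates valid, optimizer flagged it
            usable = (
                structure,
                candidate,
                f"singular random-effect fit (structure '{structure}'); "
                "variance estimate at the boundary",
            )
        logger.warning("LMM structure %s did not converge; falling back", structure)
    if result is None and usable is not None:
        used, result, fallback_note = usable
        logger.warning("LMM %s", fallback_note)
    if result is None:
        raise NotConvergedError("linear mixed model did not converge under any structure")

    # ML refit of the selected structure for a comparable AIC
    n_vc = 3 if used == "slopes" else (2 if used == "slopes_nocorr" else 1)
    aic = np.nan
    if compute_aic:
        exog_re = X[:, :2] if used != "intercepts" else X[:, :1]
        free = None
        if used == "slopes_nocorr":
            free = MixedLMParams.from_components(
                fe_params=np.ones(X.shape[1]), cov_re=np.eye(2)
            )
        ml = _fit_mixedlm(y, X, groups, exog_re, free, reml=False)
        if ml is not None:
            aic = float(-2 * ml.llf + 2 * (X.shape[1] + n_vc + 1))

    cov_re = np.atleast_2d(np.asarray(result.cov_re))
    re_int_sd = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    re_slope_sd = float(np.sqrt(max(cov_re[1, 1], 0.0))) if cov_re.shape[0] > 1 else 0.0
    if cov_re.shape[0] > 1 and re_int_sd > 0 and re_slope_sd > 0:
        re_corr = float(cov_re[0, 1] / (re_int_sd * re_slope_sd))
    else:
        re_corr = np.nan

    beta_all = np.asarray(result.fe_params, dtype=float)
    resid_var = float(result.scale)
    var_f, var_r, var_e = _variance_partition(X, beta_all, X[:, :2], cov_re, resid_var)
    r2m, r2c = _r2(var_f, var_r, var_e)

    return ModelFit(
        formula_label=label,
        family="gaussian",
        beta=float(beta_all[1]),
        se=float(result.bse_fe[1]),
        stat=float(result.tvalues[1]),
        p_value=float(result.pvalues[1]),
        intercept=float(beta_all[0]),
        re_intercept_sd=re_int_sd,
        re_slope_sd=re_slope_sd,
        re_correlation=re_corr,
        aic=aic,
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=bool(result.converged),
        n_obs=len(y),
        n_groups=len(np.unique(groups)),
        beta_all=beta_all.tolist(),
        fixed_names=fixed_names,
        cov_re=cov_re.tolist(),
        resid_var=resid_var,
        fallback=fallback_note,
        response_checksum=_checksum(frame.assign(_y=y), "_y"),
    )


def fit_recognition_glmm(
    trials: pd.DataFrame,
    image_meta: Optional[pd.DataFrame] = None,
    extra_fixed: Sequence[str] = (),
    random: str = "slopes",
) -> ModelFit:
    """Laplace ML fit of ``recognition ~ class + (class | participant)``."""
    frame = prepare_model_frame(trials, image_meta, block="recognition")
    if len(frame["participant_id"].unique()) < 2:
        raise DegenerateDataError("need at least 2 participants")
    if frame["class_AP"].nunique() < 2:
        raise DegenerateDataError("both classes must be present")
    y = (frame["response"] == "old").astype(float).to_numpy()
    fixed_names = ["intercept", "class_AP", *extra_fixed]
    X = np.column_stack(
        [np.ones(len(frame)), frame["class_AP"].to_numpy()]
        + [frame[c].astype(float).to_numpy() for c in extra_fixed]
    )
    groups = frame["participant_id"].to_numpy()
    Z = X[:, :2]
    label = _label("recognition", extra_fixed, random)

    attempts = {"slopes": ["full", "diag", "intercept"],
                "slopes_nocorr": ["diag", "intercept"],
                "intercepts": ["intercept"]}[random]
    result = None
    fallback_note = None
    for structure in attempts:
        candidate = _glmm.fit_logistic_glmm(y, X, Z, groups, structure=structure)
        if candidate.converged:
            result = candidate
            if structure != attempts[0]:
                fallback_note = (
                    f"refit with random structure '{structure}' after non-convergence"
                )
                logger.warning("GLMM %s", fallback_note)
            break
        logger.warning("GLMM structure %s did not converge; falling back", structure)
    if result is None:
        raise NotConvergedError("logistic mixed model did not converge under any structure")

    cov_re = result.cov_re
    if cov_re.shape[0] == 1:
        cov_re = np.array([[cov_re[0, 0], 0.0], [0.0, 0.0]])
    re_int_sd = float(np.sqrt(max(cov_re[0, 0], 0.0)))
    re_slope_sd = float(np.sqrt(max(cov_re[1, 1], 0.0)))
    re_corr = (
        float(cov_re[0, 1] / (re_int_sd * re_slope_sd))
        if re_int_sd > 0 and re_slope_sd > 0
        else np.nan
    )

    z = result.beta[1] / result.se[1] if result.se[1] > 0 else np.nan
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    var_f, var_r, var_e = _variance_partition(
        X, result.beta, Z, cov_re, LOGIT_RESIDUAL_VAR
    )
    r2m, r2c = _r2(var_f, var_r, var_e)

    return ModelFit(
        formula_label=label,
        family="binomial-logit",
        beta=float(result.beta[1]),
        se=float(result.se[1]),
        stat=float(z),
        p_value=float(p),
        intercept=float(result.beta[0]),
        re_intercept_sd=re_int_sd,
        re_slope_sd=re_slope_sd,
        re_correlation=re_corr,
        aic=float(result.aic),
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=result.converged,
        n_obs=result.n_obs,
        n_groups=result.n_groups,
        beta_all=result.beta.tolist(),
        fixed_names=fixed_names,
        cov_re=cov_re.tolist(),
        resid_var=LOGIT_RESIDUAL_VAR,
        fallback=fallback_note,
        response_checksum=_checksum(frame.assign(_y=y), "_y"),
    )


def nakagawa_r2(
    fit: ModelFit,
    trials: pd.DataFrame,
    image_meta: Optional[pd.DataFrame] = None,
) -> tuple[float, float]:
    """Recompute (marginal, conditional) R² for a converged fit from the data.

    Gaussian fits use the estimated residual variance; binomial-logit fits use
    the theoretical latent-scale residual variance π²/3.
    """
    if not fit.converged:
        raise NotConvergedError("cannot compute R2 for a non-converged fit")
    block = "metamemory" if fit.family == "gaussian" else "recognition"
    if fit.family == "gaussian" and "rating" not in trials.columns:
        trials = normalize_ratings(trials)
    frame = prepare_model_frame(trials, image_meta, block=block)
    cols = {"intercept": np.ones(len(frame)), "class_AP": frame["class_AP"].to_numpy()}
    X = np.column_stack(
        [cols.get(name, frame[name].astype(float).to_numpy() if name in frame else None)
         for name in fit.fixed_names]
    )
    var_f, var_r, var_e = _variance_partition(
        X,
        np.asarray(fit.beta_all),
        X[:, :2],
        np.asarray(fit.cov_re),
        fit.resid_var,
    )
    return _r2(var_f, var_r, var_e)


def compare_models_aic(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """AIC selection table; refuses fits on different data."""
    if len(fits) < 2:
        raise DegenerateDataError("need at least two fits to compare")
    checks = {(f.n_obs, f.response_checksum) for f in fits}
    if len(checks) > 1:
        raise DegenerateDataError("fits were computed on different row sets")
    aics = np.array([f.aic for f in fits], dtype=float)
    order = np.argsort(aics, kind="stable")
    table = pd.DataFrame(
        {
            "formula_label": [fits[i].formula_label for i in order],
            "aic": aics[order],
            "delta_aic": aics[order] - aics[order[0]],
            "selected": [i == 0 for i in range(len(fits))],
        }
    )
    return table


def _label(response: str, extra_fixed: Sequence[str], random: str) -> str:
    fixed = " + ".join(["class", *extra_fixed])
    re_part = {
        "slopes": "(class | participant)",
        "slopes_nocorr": "(class || participant)",
        "intercepts": "(1 | participant)",
    }[random]
    return f"{response} ~ {fixed} + {re_part}"


def _lmm_attempts(random: str) -> list[str]:
    return {
        "slopes": ["slopes", "slopes_nocorr", "intercepts"],
        "slopes_nocorr": ["slopes_nocorr", "intercepts"],
        "intercepts": ["intercepts"],
    }[random]
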