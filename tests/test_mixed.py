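"""Linear mixed model wrapper, Nakagawa R² and AIC comparison."""

import numpy as np
import pandas as pd
import pytest

from lepmem import (
    DegenerateDataError,
    compare_models_aic,
    fit_rating_lmm,
    nakagawa_r2,
    normalize_ratings,
)
from lepmem.errors import NotConvergedError

from conftest import make_meta


def rating_frame(participants, images, classes, values):
    """Long metamemory frame with a precomputed ``rating`` column."""
    rows = []
    idx = 0
    for p in participants:
        for img, cls in zip(images, classes):
            rows.append(
                {
                    "participant_id": p,
                    "image_id": img,
                    "block": "metamemory",
                    "role": "target",
                    "rating_raw": pd.NA,
                    "response": pd.NA,
                    "confidence": pd.NA,
                    "rating": values[idx],
                    "lepidoptera_class": cls,
                }
            )
            idx += 1
    df = pd.DataFrame(rows)
    df["rating_raw"] = df["rating_raw"].astype("Int64")
    return df


def test_lmm_reduces_to_ols_without_random_variance():
    """Participants with identical response patterns force the random-effect
    variance to zero; beta and SE must match ordinary least squares."""
    rng = np.random.default_rng(0)
    n_img = 10
    images = [f"I{i:02d}" for i in range(n_img)]
    classes = ["AP"] * 5 + ["nonAP"] * 5
    per_image = 0.3 + 0.2 * (np.array(classes) == "AP") + 0.05 * rng.standard_normal(n_img)
    participants = [f"P{i}" for i in range(6)]
    values = np.tile(per_image, len(participants))
    frame = rating_frame(participants, images, classes, values)
    fit = fit_rating_lmm(frame, compute_aic=False)

    X = np.column_stack(
        [np.ones(len(values)), np.tile((np.array(classes) == "AP").astype(float), 6)]
    )
    beta_ols, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta_ols
    sigma2 = resid @ resid / (len(values) - 2)
    se_ols = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    assert fit.beta == pytest.approx(beta_ols[1], abs=1e-6)
    assert fit.se == pytest.approx(se_ols[1], abs=1e-6)


def test_constant_response_yields_flagged_degenerate_fit():
    frame = rating_frame(
        ["P1", "P2"], ["I1", "I2"], ["AP", "nonAP"], [0.5, 0.5, 0.5, 0.5]
    )
    fit = fit_rating_lmm(frame)
    assert fit.beta == 0.0
    assert fit.re_intercept_sd == 0.0 and fit.re_slope_sd == 0.0
    assert "degenerate" in fit.fallback


def test_matches_lme4_reml_fit(default_dataset, default_retained):
    """Frozen lme4::lmer oracle (REML, correlated intercept+slope) on the
    seed-1 default dataset."""
    trials, _ = default_retained
    fit = fit_rating_lmm(trials, default_dataset.images)
    assert fit.beta == pytest.approx(0.1595402, abs=5e-5)
    assert fit.se == pytest.approx(0.0175076, abs=5e-5)
    assert fit.re_intercept_sd == pytest.approx(0.1140448, abs=2e-3)
    assert fit.re_slope_sd == pytest.approx(0.1153068, abs=2e-3)
    assert fit.re_correlation == pytest.approx(0.2607185, abs=0.02)
    assert fit.aic == pytest.approx(-1718.4262, abs=0.05)
    assert fit.p_value < 0.001 and fit.converged


def test_nakagawa_r2_recovers_known_variance_components():
    """Fixed var 1, random-intercept var 2, residual var 1 -> (0.25, 0.75)."""
    rng = np.random.default_rng(42)
    n_p, n_i = 100, 50
    images = [f"I{i:02d}" for i in range(n_i)]
    classes = ["AP"] * (n_i // 2) + ["nonAP"] * (n_i // 2)
    x = (np.array(classes) == "AP").astype(float)
    values = []
    for p in range(n_p):
        b = rng.normal(0, np.sqrt(2.0))
        values.extend(2.0 * x + b + rng.standard_normal(n_i))
    frame = rating_frame([f"P{i:03d}" for i in range(n_p)], images, classes, values)
    fit = fit_rating_lmm(frame, random="intercepts", compute_aic=False)
    assert fit.r2_marginal == pytest.approx(0.25, abs=0.03)
    assert fit.r2_conditional == pytest.approx(0.75, abs=0.03)
    # the standalone operation reproduces the values stored on the fit
    r2m, r2c = nakagawa_r2(fit, frame)
    assert (r2m, r2c) == pytest.approx((fit.r2_marginal, fit.r2_conditional), abs=1e-12)


def test_r2_collapse_cases():
    # zero random-effect variance: marginal == conditional
    rng = np.random.default_rng(1)
    n_img = 10
    images = [f"I{i:02d}" for i in range(n_img)]
    classes = ["AP"] * 5 + ["nonAP"] * 5
    per_image = 0.4 + 0.3 * (np.array(classes) == "AP") + 0.02 * rng.standard_normal(n_img)
    frame = rating_frame(
        [f"P{i}" for i in range(6)], images, classes, np.tile(per_image, 6)
    )
    fit = fit_rating_lmm(frame, compute_aic=False)
    assert fit.r2_marginal == pytest.approx(fit.r2_conditional, abs=1e-6)

    # zero fixed effect with real participant variance: marginal ~ 0 < conditional
    values = []
    for p in range(30):
        b = rng.normal(0, 0.5)
        values.extend(b + 0.1 * rng.standard_normal(n_img))
    frame = rating_frame([f"P{i:02d}" for i in range(30)], images, classes, values)
    fit = fit_rating_lmm(frame, random="intercepts", compute_aic=False)
    assert fit.r2_marginal < 0.02
    assert fit.r2_conditional > 0.5


def test_nakagawa_refuses_nonconverged_fit(default_dataset, default_retained):
    trials, _ = default_retained
    fit = fit_rating_lmm(trials, default_dataset.images, compute_aic=False)
    fit.converged = False
    with pytest.raises(NotConvergedError):
        nakagawa_r2(fit, trials, default_dataset.images)


def test_aic_tie_selects_first_in_stable_order(default_dataset, default_retained):
    trials, _ = default_retained
    fit = fit_rating_lmm(trials, default_dataset.images)
    table = compare_models_aic([fit, fit])
    assert table["delta_aic"].iloc[1] == 0.0
    assert table["selected"].tolist() == [True, False]


def test_aic_refuses_fits_on_different_rows(default_dataset, default_retained):
    trials, _ = default_retained
    fit_all = fit_rating_lmm(trials, default_dataset.images)
    subset = trials[trials["image_id"] != "AP_02"]
    fit_sub = fit_rating_lmm(subset, default_dataset.images)
    with pytest.raises(DegenerateDataError, match="different row sets"):
        compare_models_aic([fit_all, fit_sub])


def test_aic_penalty_for_useless_fixed_effect():
    """Adding a pure-noise covariate costs ~2 AIC (median over 200 seeds in
    [1, 3], the chi-square(1) null penalty)."""
    n_p, n_i = 12, 10
    images = [f"I{i:02d}" for i in range(n_i)]
    classes = ["AP"] * 5 + ["nonAP"] * 5
    x = (np.array(classes) == "AP").astype(float)
    deltas = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        values = []
        for p in range(n_p):
            values.extend(0.5 + 0.1 * x + rng.normal(0, 0.3) + 0.2 * rng.standard_normal(n_i))
        frame = rating_frame([f"P{i:02d}" for i in range(n_p)], images, classes, values)
        frame["junk"] = rng.standard_normal(len(frame))
        base = fit_rating_lmm(frame, random="intercepts")
        bigger = fit_rating_lmm(frame, random="intercepts", extra_fixed=["junk"])
        deltas.append(bigger.aic - base.aic)
    assert 1.0 <= np.median(deltas) <= 3.0


def test_aic_prefers_random_slopes_when_slope_variance_is_real():
    """With substantial participant-slope variance the slope model wins the
    AIC comparison in >= 90% of seeds."""
    n_p, n_i = 20, 20
    images = [f"I{i:02d}" for i in range(n_i)]
    classes = ["AP"] * 10 + ["nonAP"] * 10
    x = (np.array(classes) == "AP").astype(float)
    wins = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        values = []
        for p in range(n_p):
            b0 = rng.normal(0, 0.1)
            b1 = rng.normal(0, 0.3)
            values.extend(0.5 + 0.15 * x + b0 + b1 * x + 0.1 * rng.standard_normal(n_i))
        frame = rating_frame([f"P{i:02d}" for i in range(n_p)], images, classes, values)
        slopes = fit_rating_lmm(frame)
        intercepts = fit_rating_lmm(frame, random="intercepts")
        table = compare_models_aic([slopes, intercepts])
        wins += table[table["selected"]]["formula_label"].iloc[0] == slopes.formula_label
    assert wins / n_seeds >= 0.90


def test_fit_invariant_to_row_order(default_dataset, default_retained):
    trials, _ = default_retained
    fit = fit_rating_lmm(trials, default_dataset.images, compute_aic=False)
    shuffled = trials.sample(frac=1.0, random_state=3).reset_index(drop=True)
    fit2 = fit_rating_lmm(shuffled, default_dataset.images, compute_aic=False)
    assert fit2.beta == pytest.approx(fit.beta, abs=1e-8)
    assert fit2.se == pytest.approx(fit.se, abs=1e-8)


def test_marginal_r2_invariant_to_reference_class(default_dataset, default_retained):
    trials, _ = default_retained
    fit = fit_rating_lmm(trials, default_dataset.images, compute_aic=False)
    flipped_meta = default_dataset.images.copy()
    flipped_meta["lepidoptera_class"] = flipped_meta["lepidoptera_class"].map(
        {"AP": "nonAP", "nonAP": "AP", "": ""}
    )
    fit_flipped = fit_rating_lmm(trials, flipped_meta, compute_aic=False)
    assert fit_flipped.beta == pytest.approx(-fit.beta, abs=1e-6)
    # identical up to optimizer noise in the refitted variance components
    assert fit_flipped.r2_marginal == pytest.approx(fit.r2_marginal, abs=1e-4)
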