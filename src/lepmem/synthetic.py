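"""Synthetic trial generator for the two-class image-memory design.

The generator emulates the statistical structure of a metamemory-rating +
old/new recognition experiment on aposematic (AP) and non-aposematic (nonAP)
Lepidoptera images:

* each target image carries a true recognition probability ``p_i`` whose
  log-odds are Normal within class, with a *larger* between-image SD for AP
  than for nonAP images (this is what produces the cross-observer consistency
  difference downstream);
* each image also carries a latent apparent-memorability ``m_i`` on the 0–1
  rating scale, class-shifted for AP but only weakly correlated with
  ``logit(p_i)`` (this produces the metamemory–recognition dissociation);
* participants carry Gaussian intercept and slope offsets on the log-odds
  scale (recognition) and on the rating scale (metamemory);
* the recognition block mixes targets, AP-only lures, and repeats of a single
  task-irrelevant vigilance image; participants flagged as vigilance failures
  answer "new" to at least one vigilance repeat.

Randomness: one global seed; sub-streams for images, participants and trials
are spawned from it in that fixed order, so any stage can be regenerated
deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SimulationConfig
from .errors import ConfigError, StructuralError

__all__ = [
    "GroundTruth",
    "SimulatedDataset",
    "generate_images",
    "generate_participants",
    "generate_trials",
    "simulate_dataset",
]

VIGILANCE_IMAGE_ID = "VIG_01"


@dataclass
class GroundTruth:
    """Latent quantities behind a simulated dataset, kept for recovery tests."""

    image_ids: list[str]
    classes: list[str]                    # "AP" / "nonAP" per target image
    logit_p: np.ndarray                   # per-image true recognition log-odds
    p: np.ndarray                         # per-image true recognition probability
    m: np.ndarray                         # per-image latent apparent-memorability (0–1 scale)
    class_logit_sd: dict = field(default_factory=dict)  # realized sample SD of logit_p per class
    participant_ids: list[str] = field(default_factory=list)
    intercepts: Optional[np.ndarray] = None       # recognition log-odds offsets
    slopes: Optional[np.ndarray] = None           # recognition class-effect offsets
    rating_intercepts: Optional[np.ndarray] = None
    rating_slopes: Optional[np.ndarray] = None
    vigilance_fail: Optional[np.ndarray] = None   # boolean per participant

    def to_json(self, path: str | Path) -> None:
        def as_list(x):
            return None if x is None else np.asarray(x).tolist()

        payload = {
            "image_ids": list(self.image_ids),
            "classes": list(self.classes),
            "logit_p": as_list(self.logit_p),
            "p": as_list(self.p),
            "m": as_list(self.m),
            "class_logit_sd": {k: float(v) for k, v in self.class_logit_sd.items()},
            "participant_ids": list(self.participant_ids),
            "intercepts": as_list(self.intercepts),
            "slopes": as_list(self.slopes),
            "rating_intercepts": as_list(self.rating_intercepts),
            "rating_slopes": as_list(self.rating_slopes),
            "vigilance_fail": as_list(self.vigilance_fail),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    trials: pd.DataFrame
    images: pd.DataFrame
    participants: pd.DataFrame
    ground_truth: GroundTruth
    config: SimulationConfig


def _corr_pair(rng: np.random.Generator, n: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Two standard-normal vectors with correlation ``rho`` (in population)."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2


def _expected_norm_rating(mu: float, sd: float) -> float:
    """E[(clip(round(1 + 9u), 1, 10) − 1)/9] for u ~ N(mu, sd)."""
    from scipy.stats import norm

    ks = np.arange(1, 11)
    upper = np.where(ks == 10, np.inf, (ks + 0.5 - 1.0) / 9.0)
    lower = np.where(ks == 1, -np.inf, (ks - 0.5 - 1.0) / 9.0)
    pk = norm.cdf(upper, mu, sd) - norm.cdf(lower, mu, sd)
    return float(np.sum((ks - 1) / 9.0 * pk))


def _calibrated_latent_mean(target: float, sd: float) -> float:
    """Latent mean whose discretized, clipped 1–10 rating has normalized
    expectation ``target``; identity when the scale noise is (near) zero.

    The bounded scale compresses means toward its interior, so the latent
    Gaussian mean is shifted to compensate — this keeps the configured class
    means/shift exact on the *observed* 0–1 rating scale.
    """
    from scipy.optimize import brentq

    if sd < 0.02:
        return target
    lo, hi = target - 1.0, target + 1.0
    f = lambda mu: _expected_norm_rating(mu, sd) - target  # noqa: E731
    if f(lo) > 0 or f(hi) < 0:
        return target
    return float(brentq(f, lo, hi, xtol=1e-10))


def generate_images(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw target, lure and vigilance image metadata plus latent truth.

    Targets: ``n_images_per_class`` per class, with
    ``logit(p_i) ~ N(class_mean_logit[c], class_image_sd[c])`` and a latent
    memorability ``m_i`` correlated with ``logit(p_i)`` at
    ``rating_memory_coupling`` within class, shifted by ``rating_class_shift``
    for AP. Lures are AP-only, mirroring the study's stimulus constraint.
    """
    config.validate()
    n = config.n_images_per_class
    image_ids: list[str] = []
    classes: list[str] = []
    logit_p_parts = []
    m_parts = []
    class_logit_sd: dict[str, float] = {}

    for cls, mean, sd in (
        ("AP", config.class_mean_logit[0], config.class_image_sd[0]),
        ("nonAP", config.class_mean_logit[1], config.class_image_sd[1]),
    ):
        z_mem, z_rat = _corr_pair(rng, n, config.rating_memory_coupling)
        lp = mean + sd * z_mem
        shift = config.rating_class_shift if cls == "AP" else 0.0
        # total rating-scale dispersion around the class mean; the latent mean
        # is calibrated so the clipped/rounded scale reproduces base + shift
        rating_sd = float(
            np.sqrt(
                config.rating_image_sd**2
                + config.rating_participant_intercept_sd**2
                + (config.rating_participant_slope_sd**2 if cls == "AP" else 0.0)
                + config.rating_noise_sd**2
            )
        )
        latent_mean = _calibrated_latent_mean(config.rating_base + shift, rating_sd)
        m = latent_mean + config.rating_image_sd * z_rat
        prefix = "AP" if cls == "AP" else "NA"
        image_ids.extend(f"{prefix}_{i + 1:02d}" for i in range(n))
        classes.extend([cls] * n)
        logit_p_parts.append(lp)
        m_parts.append(m)
        class_logit_sd[cls] = float(np.std(lp, ddof=1)) if n > 1 else 0.0

    logit_p = np.concatenate(logit_p_parts)
    m = np.concatenate(m_parts)
    p = expit(logit_p)
    if not np.all((p > 0) & (p < 1)):
        raise ConfigError("class_mean_logit", "produced degenerate recognition probabilities")

    lure_ids = [f"LU_{i + 1:02d}" for i in range(config.n_lures)]
    lure_logit = config.lure_mean_logit + config.lure_image_sd * rng.standard_normal(
        config.n_lures
    )

    # natural relative specimen sizes, an optional covariate downstream
    sizes = np.exp(rng.normal(0.0, 0.3, size=len(image_ids) + len(lure_ids)))
    sizes = sizes / sizes.max()

    meta = pd.DataFrame(
        {
            "image_id": image_ids + lure_ids + [VIGILANCE_IMAGE_ID],
            "lepidoptera_class": classes + ["AP"] * len(lure_ids) + [""],
            "role": ["target"] * len(image_ids) + ["lure"] * len(lure_ids) + ["vigilance"],
            "specimen_size": np.round(np.append(sizes, np.nan), 6),
            "luminance_contrast": np.nan,
            "colour_contrast": np.nan,
            "odd": np.nan,
        }
    )
    # lure latent false-alarm log-odds ride along as an attribute (not a CSV column)
    meta.attrs["lure_logit"] = dict(zip(lure_ids, lure_logit))

    gt = GroundTruth(
        image_ids=image_ids,
        classes=classes,
        logit_p=logit_p,
        p=p,
        m=m,
        class_logit_sd=class_logit_sd,
    )
    return meta, gt


def generate_participants(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the participant roster with latent offsets and vigilance flags.

    Offsets are Normal(0, sd). The vigilance-failure flag is either exactly
    ``n_vigilance_failures`` participants chosen at random (the default,
    matching the study's realized 7/57) or, when that field is None,
    independent Bernoulli(``vigilance_fail_prob``) draws.
    """
    config.validate()
    n = config.n_participants
    if config.n_vigilance_failures is not None:
        fail = np.zeros(n, dtype=bool)
        fail[rng.choice(n, size=config.n_vigilance_failures, replace=False)] = True
    else:
        fail = rng.random(n) < config.vigilance_fail_prob
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "intercept": config.participant_intercept_sd * rng.standard_normal(n),
            "slope": config.participant_slope_sd * rng.standard_normal(n),
            "rating_intercept": config.rating_participant_intercept_sd
            * rng.standard_normal(n),
            "rating_slope": config.rating_participant_slope_sd * rng.standard_normal(n),
            "vigilance_fail": fail,
        }
    )


def generate_trials(
    images: pd.DataFrame,
    ground_truth: GroundTruth,
    participants: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Build the long-format trial table for both blocks.

    Metamemory block: one 10-point rating per participant×target, derived from
    the image's latent memorability plus participant offsets and trial noise,
    then discretized onto the 1–10 scale. Recognition block: one old/new
    response per participant×target (hit probability ``expit(logit(p_i) +
    intercept + slope·AP)``), per participant×lure (false alarms), and
    ``n_vigilance_repeats`` vigilance repeats with at least one "new" answer
    for flagged participants. Presentation order is randomized per participant.
    """
    targets = images[images["role"] == "target"]
    if list(targets["image_id"]) != list(ground_truth.image_ids):
        raise StructuralError("image metadata does not match ground truth roster")
    if targets["image_id"].duplicated().any():
        raise StructuralError("duplicated target image ids")

    lures = images[images["role"] == "lure"]
    lure_logit_map = images.attrs.get("lure_logit", {})
    lure_logit = np.array(
        [lure_logit_map.get(i, config.lure_mean_logit) for i in lures["image_id"]]
    )

    is_ap = np.array([c == "AP" for c in ground_truth.classes], dtype=float)
    n_img = len(ground_truth.image_ids)
    image_ids = np.asarray(ground_truth.image_ids)

    rows: list[pd.DataFrame] = []
    conf_levels = np.array(["low", "medium", "high"])

    for _, prow in participants.iterrows():
        pid = prow["participant_id"]

        # --- metamemory block: every target rated exactly once, random order
        order = rng.permutation(n_img)
        u = (
            ground_truth.m
            + prow["rating_intercept"]
            + prow["rating_slope"] * is_ap
            + config.rating_noise_sd * rng.standard_normal(n_img)
        )
        rating = np.clip(np.rint(1.0 + 9.0 * u), 1, 10).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "image_id": image_ids[order],
                    "block": "metamemory",
                    "role": "target",
                    "rating_raw": pd.array(rating[order], dtype="Int64"),
                    "response": pd.array([None] * n_img, dtype="string"),
                    "confidence": pd.array([None] * n_img, dtype="string"),
                }
            )
        )

        # --- recognition block: targets + lures + vigilance repeats, shuffled
        p_hit = expit(ground_truth.logit_p + prow["intercept"] + prow["slope"] * is_ap)
        target_resp = np.where(rng.random(n_img) < p_hit, "old", "new")

        p_fa = expit(lure_logit + prow["intercept"])
        lure_resp = np.where(rng.random(len(lures)) < p_fa, "old", "new")

        n_vig = config.n_vigilance_repeats
        vig_resp = np.full(n_vig, "old", dtype=object)
        if prow["vigilance_fail"]:
            n_new = 1 + rng.binomial(n_vig - 1, 0.25) if n_vig > 1 else 1
            vig_resp[rng.choice(n_vig, size=n_new, replace=False)] = "new"

        rec_ids = np.concatenate([image_ids, lures["image_id"].to_numpy(), [VIGILANCE_IMAGE_ID] * n_vig])
        rec_roles = np.concatenate(
            [["target"] * n_img, ["lure"] * len(lures), ["vigilance"] * n_vig]
        )
        rec_resp = np.concatenate([target_resp, lure_resp, vig_resp])
        shuffle = rng.permutation(len(rec_ids))
        confidence = conf_levels[rng.choice(3, size=len(rec_ids), p=[0.2, 0.3, 0.5])]
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "image_id": rec_ids[shuffle],
                    "block": "recognition",
                    "role": rec_roles[shuffle],
                    "rating_raw": pd.array([None] * len(rec_ids), dtype="Int64"),
                    "response": pd.array(rec_resp[shuffle], dtype="string"),
                    "confidence": pd.array(confidence[shuffle], dtype="string"),
                }
            )
        )

    return pd.concat(rows, ignore_index=True)


def simulate_dataset(config: SimulationConfig, seed: Optional[int] = None) -> SimulatedDataset:
    """Run the three generators with documented stream-splitting.

    The global seed (argument, falling back to ``config.seed``) is expanded
    into three independent sub-streams in the fixed order images →
    participants → trials.
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    ss = np.random.SeedSequence(seed)
    rng_images, rng_participants, rng_trials = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )
    images, gt = generate_images(config, rng_images)
    participants = generate_participants(config, rng_participants)
    trials = generate_trials(images, gt, participants, config, rng_trials)

    gt.participant_ids = list(participants["participant_id"])
    gt.intercepts = participants["intercept"].to_numpy()
    gt.slopes = participants["slope"].to_numpy()
    gt.rating_intercepts = participants["rating_intercept"].to_numpy()
    gt.rating_slopes = participants["rating_slope"].to_numpy()
    gt.vigilance_fail = participants["vigilance_fail"].to_numpy()
    return SimulatedDataset(trials, images, participants, gt, config)
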