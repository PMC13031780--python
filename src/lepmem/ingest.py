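"""Reading, validation and quality control of trial and image tables.

The long-format trial CSV has one row per behavioural event with columns
``participant_id, image_id, block, role, rating_raw, response, confidence``:

* ``block``: ``metamemory`` (study/rating block), ``recognition`` (old/new
  test block) or ``practice`` (accepted and ignored);
* ``role``: ``target``, ``lure`` or ``vigilance``;
* metamemory rows carry an integer ``rating_raw`` in 1–10 and no response;
  recognition rows carry a ``response`` in {old, new} and no rating;
* ``confidence`` (low/medium/high) is optional and not analysed here.

The image metadata CSV has one row per image: ``image_id,
lepidoptera_class (AP/nonAP, empty for vigilance images), role,
specimen_size, luminance_contrast, colour_contrast, odd`` — the last four are
optional covariates whose values come from outside this package.

Quality control implements the study's vigilance rule: any participant who
answers "new" to one or more repeats of the vigilance image is excluded with
all of their trials. Ratings are mapped to the unit interval by
``(rating_raw − 1) / 9`` so the scale's verbal anchors land on 0 and 1.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SchemaError

__all__ = [
    "ExclusionReport",
    "read_trials",
    "read_image_meta",
    "write_trials",
    "write_image_meta",
    "apply_vigilance_exclusion",
    "normalize_ratings",
    "compute_image_scores",
]

logger = logging.getLogger("lepmem")

TRIAL_COLUMNS = [
    "participant_id",
    "image_id",
    "block",
    "role",
    "rating_raw",
    "response",
    "confidence",
]
META_COLUMNS = [
    "image_id",
    "lepidoptera_class",
    "role",
    "specimen_size",
    "luminance_contrast",
    "colour_contrast",
    "odd",
]
BLOCKS = {"metamemory", "recognition", "practice"}
ROLES = {"target", "lure", "vigilance"}
RESPONSES = {"old", "new"}
CONFIDENCES = {"low", "medium", "high"}


@dataclass
class ExclusionReport:
    """Outcome of the vigilance-based participant exclusion."""

    n_recruited: int
    excluded_ids: list[str]
    n_retained: int
    reasons: dict[str, str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _first_bad_row(mask: pd.Series) -> int:
    return int(np.flatnonzero(mask.to_numpy())[0])


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table schema, raising :class:`SchemaError` on the first
    violation (naming row and column)."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns {missing}", column=missing[0])

    for col in ("participant_id", "image_id"):
        bad = trials[col].isna() | (trials[col].astype(str).str.len() == 0)
        if bad.any():
            raise SchemaError(f"empty {col}", row=_first_bad_row(bad), column=col)

    bad = ~trials["block"].isin(BLOCKS)
    if bad.any():
        raise SchemaError(
            f"unknown block value {trials['block'][bad].iloc[0]!r}",
            row=_first_bad_row(bad),
            column="block",
        )
    bad = ~trials["role"].isin(ROLES)
    if bad.any():
        raise SchemaError(
            f"unknown role value {trials['role'][bad].iloc[0]!r}",
            row=_first_bad_row(bad),
            column="role",
        )

    rating = trials["rating_raw"]
    has_rating = rating.notna()
    out_of_range = has_rating & ((rating < 1) | (rating > 10))
    if out_of_range.any():
        raise SchemaError(
            f"rating_raw {rating[out_of_range].iloc[0]} outside 1-10",
            row=_first_bad_row(out_of_range),
            column="rating_raw",
        )

    response = trials["response"]
    has_response = response.notna() & (response.astype(str).str.len() > 0)
    bad = has_response & ~response.isin(RESPONSES)
    if bad.any():
        raise SchemaError(
            f"unknown response value {response[bad].iloc[0]!r}",
            row=_first_bad_row(bad),
            column="response",
        )

    confidence = trials["confidence"]
    has_conf = confidence.notna() & (confidence.astype(str).str.len() > 0)
    bad = has_conf & ~confidence.isin(CONFIDENCES)
    if bad.any():
        raise SchemaError(
            f"unknown confidence value {confidence[bad].iloc[0]!r}",
            row=_first_bad_row(bad),
            column="confidence",
        )

    meta_rows = trials["block"] == "metamemory"
    rec_rows = trials["block"] == "recognition"
    bad = meta_rows & ~has_rating
    if bad.any():
        raise SchemaError(
            "metamemory row without rating_raw", row=_first_bad_row(bad), column="rating_raw"
        )
    bad = meta_rows & has_response
    if bad.any():
        raise SchemaError(
            "metamemory row with a recognition response",
            row=_first_bad_row(bad),
            column="response",
        )
    bad = rec_rows & ~has_response
    if bad.any():
        raise SchemaError(
            "recognition row without response", row=_first_bad_row(bad), column="response"
        )
    bad = rec_rows & has_rating
    if bad.any():
        raise SchemaError(
            "recognition row with rating_raw present",
            row=_first_bad_row(bad),
            column="rating_raw",
        )
    return trials


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV (UTF-8, comma-separated, header row)."""
    trials = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "image_id": str,
            "block": str,
            "role": str,
            "rating_raw": "Int64",
            "response": "string",
            "confidence": "string",
        },
        keep_default_na=True,
    )
    validate_trials(trials)
    logger.info("read %d trial rows from %s", len(trials), path)
    return trials


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_image_meta(path: str | Path) -> pd.DataFrame:
    """Read and validate the image metadata CSV."""
    meta = pd.read_csv(
        path,
        dtype={"image_id": str, "lepidoptera_class": str, "role": str},
        keep_default_na=True,
    )
    missing = [c for c in ("image_id", "lepidoptera_class", "role") if c not in meta.columns]
    if missing:
        raise SchemaError(f"image table missing columns {missing}", column=missing[0])
    meta["lepidoptera_class"] = meta["lepidoptera_class"].fillna("")
    bad = ~meta["role"].isin(ROLES)
    if bad.any():
        raise SchemaError(
            f"unknown role value {meta['role'][bad].iloc[0]!r}",
            row=_first_bad_row(bad),
            column="role",
        )
    bad = (meta["role"] == "target") & ~meta["lepidoptera_class"].isin({"AP", "nonAP"})
    if bad.any():
        raise SchemaError(
            "target image without AP/nonAP class",
            row=_first_bad_row(bad),
            column="lepidoptera_class",
        )
    if meta["image_id"].duplicated().any():
        dup = meta["image_id"][meta["image_id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicated image_id {dup!r}", column="image_id")
    logger.info("read %d image rows from %s", len(meta), path)
    return meta


def write_image_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def apply_vigilance_exclusion(
    trials: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop every trial of any participant who answered "new" to one or more
    vigilance checks; participants without vigilance rows are retained with a
    logged warning."""
    vig = trials[(trials["block"] == "recognition") & (trials["role"] == "vigilance")]
    participants = pd.unique(trials["participant_id"])

    counts = vig.groupby("participant_id")["response"].agg(
        n_new=lambda s: int((s == "new").sum()), n_total="size"
    )
    no_vigilance = [p for p in participants if p not in counts.index]
    for pid in no_vigilance:
        logger.warning("participant %s has no vigilance trials; retained", pid)

    flagged = counts[counts["n_new"] >= 1]
    excluded_ids = sorted(flagged.index)
    reasons = {
        pid: f"answered 'new' on {int(row.n_new)} of {int(row.n_total)} vigilance checks"
        for pid, row in flagged.iterrows()
    }
    retained = trials[~trials["participant_id"].isin(excluded_ids)].reset_index(drop=True)
    report = ExclusionReport(
        n_recruited=len(participants),
        excluded_ids=list(excluded_ids),
        n_retained=len(participants) - len(excluded_ids),
        reasons=reasons,
    )
    logger.info(
        "vigilance exclusion: %d recruited, %d excluded, %d retained",
        report.n_recruited,
        len(report.excluded_ids),
        report.n_retained,
    )
    return retained, report


def normalize_ratings(trials: pd.DataFrame) -> pd.DataFrame:
    """Add a ``rating`` column mapping the 1–10 scale onto [0, 1] via
    (rating_raw − 1)/9; affine, so rank order is preserved exactly."""
    meta_rows = trials["block"] == "metamemory"
    missing = meta_rows & trials["rating_raw"].isna()
    if missing.any():
        raise SchemaError(
            "metamemory row without rating_raw",
            row=_first_bad_row(missing),
            column="rating_raw",
        )
    out = trials.copy()
    out["rating"] = (out["rating_raw"].astype("Float64") - 1.0) / 9.0
    return out


def compute_image_scores(
    trials: pd.DataFrame,
    image_meta: pd.DataFrame,
    excluded_images: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-image aggregates over the retained pool.

    Returns one row per retained target image with hit count ``H``, number of
    recognition observations ``N``, ``hit_rate = H/N`` and the mean normalized
    metamemory rating. Lure, vigilance and practice rows are ignored; images
    in ``excluded_images`` are dropped (the study dropped one AP target due to
    a presentation error).
    """
    if "rating" not in trials.columns:
        trials = normalize_ratings(trials)
    excluded = set(excluded_images)
    targets = image_meta[
        (image_meta["role"] == "target") & ~image_meta["image_id"].isin(excluded)
    ]

    rec = trials[
        (trials["block"] == "recognition")
        & (trials["role"] == "target")
        & trials["image_id"].isin(targets["image_id"])
    ]
    hits = rec.groupby("image_id")["response"].agg(
        H=lambda s: int((s == "old").sum()), N="size"
    )
    rat = trials[
        (trials["block"] == "metamemory") & trials["image_id"].isin(targets["image_id"])
    ]
    mean_rating = rat.groupby("image_id")["rating"].mean()

    rows = []
    for _, img in targets.iterrows():
        iid = img["image_id"]
        if iid not in hits.index or hits.loc[iid, "N"] == 0:
            raise DegenerateDataError(
                f"target image {iid!r} has zero recognition observations"
            )
        H = int(hits.loc[iid, "H"])
        N = int(hits.loc[iid, "N"])
        rows.append(
            {
                "image_id": iid,
                "lepidoptera_class": img["lepidoptera_class"],
                "H": H,
                "N": N,
                "hit_rate": H / N,
                "mean_rating": float(mean_rating.get(iid, np.nan)),
            }
        )
    scores = pd.DataFrame(rows).sort_values("image_id", ignore_index=True)
    logger.info("image scores computed for %d target images", len(scores))
    return scores
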