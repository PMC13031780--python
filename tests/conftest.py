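import logging

import numpy as np
import pandas as pd
import pytest

from lepmem import (
    SimulationConfig,
    apply_vigilance_exclusion,
    compute_image_scores,
    normalize_ratings,
    simulate_dataset,
)

# fallback chatter from deliberately degenerate fits would swamp the test log
logging.getLogger("lepmem").setLevel(logging.ERROR)


def small_config(**overrides) -> SimulationConfig:
    """A reduced design for fast simulation-heavy tests."""
    base = dict(
        n_participants=16,
        n_images_per_class=8,
        n_lures=2,
        n_vigilance_repeats=3,
        n_vigilance_failures=2,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size synthetic dataset at the study's default design."""
    return simulate_dataset(SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def default_retained(default_dataset):
    retained, report = apply_vigilance_exclusion(default_dataset.trials)
    return normalize_ratings(retained), report


@pytest.fixture(scope="session")
def default_scores(default_dataset, default_retained):
    trials, _ = default_retained
    return compute_image_scores(trials, default_dataset.images, excluded_images=["AP_01"])


def trials_row(
    participant="P001",
    image="AP_01",
    block="metamemory",
    role="target",
    rating=None,
    response=None,
    confidence=None,
):
    return {
        "participant_id": participant,
        "image_id": image,
        "block": block,
        "role": role,
        "rating_raw": rating,
        "response": response,
        "confidence": confidence,
    }


def make_trials(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["rating_raw"] = df["rating_raw"].astype("Int64")
    df["response"] = df["response"].astype("string")
    df["confidence"] = df["confidence"].astype("string")
    return df


def make_meta(image_ids, classes, roles=None) -> pd.DataFrame:
    roles = ["target"] * len(image_ids) if roles is None else roles
    return pd.DataFrame(
        {
            "image_id": image_ids,
            "lepidoptera_class": classes,
            "role": roles,
            "specimen_size": np.nan,
            "luminance_contrast": np.nan,
            "colour_contrast": np.nan,
            "odd": np.nan,
        }
    )
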