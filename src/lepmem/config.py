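"""Configuration objects for simulation and analysis runs.

Two dataclasses are defined:

* :class:`SimulationConfig` — parameters of the synthetic trial generator.
  Defaults reproduce the design of the two-class Lepidoptera image-memory
  study the pipeline was built around: 57 recruited participants of whom 7
  fail a vigilance check, 29 aposematic (AP) and 29 non-aposematic (nonAP)
  target images, a 10-point metamemory rating scale, and an old/new
  recognition block with AP-only lures and 5 vigilance repeats.
* :class:`RunConfig` — the end-to-end analysis settings (resampling counts,
  seed, excluded images, stage toggles).

Both round-trip through YAML/JSON via ``to_dict``/``from_dict``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ConfigError

__all__ = ["SimulationConfig", "RunConfig", "config_hash"]


@dataclass
class SimulationConfig:
    """Generator parameters.

    Latent model: image *i* of class *c* has a true recognition probability
    ``p_i`` with ``logit(p_i) ~ Normal(class_mean_logit[c], class_image_sd[c])``
    and a latent apparent-memorability ``m_i`` on the 0–1 rating scale,
    correlated with ``logit(p_i)`` at ``rating_memory_coupling`` within class
    and shifted upward by ``rating_class_shift`` for AP images. Participants
    carry Gaussian intercept/slope offsets on the log-odds scale (recognition)
    and on the rating scale (metamemory).

    Class-valued pairs are ordered ``(AP, nonAP)``.
    """

    n_participants: int = 57
    n_images_per_class: int = 29
    class_mean_logit: tuple[float, float] = (0.62, 0.53)
    class_image_sd: tuple[float, float] = (1.2, 0.3)
    participant_intercept_sd: float = 0.6
    participant_slope_sd: float = 0.3
    rating_class_shift: float = 0.16
    rating_memory_coupling: float = 0.1
    rating_base: float = 0.45
    rating_image_sd: float = 0.10
    rating_participant_intercept_sd: float = 0.16
    rating_participant_slope_sd: float = 0.12
    rating_noise_sd: float = 0.145
    vigilance_fail_prob: float = 7.0 / 57.0
    n_vigilance_failures: Optional[int] = 7
    n_vigilance_repeats: int = 5
    n_lures: int = 67
    lure_mean_logit: float = -0.85
    lure_image_sd: float = 0.5
    seed: Optional[int] = None

    def __post_init__(self):
        self.class_mean_logit = tuple(float(v) for v in self.class_mean_logit)
        self.class_image_sd = tuple(float(v) for v in self.class_image_sd)
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_participants": self.n_participants,
            "n_images_per_class": self.n_images_per_class,
            "n_vigilance_repeats": self.n_vigilance_repeats,
        }
        for name, value in counts.items():
            if not isinstance(value, (int,)) or value < 1:
                raise ConfigError(name, f"must be an integer >= 1, got {value!r}")
        if not isinstance(self.n_lures, int) or self.n_lures < 0:
            raise ConfigError("n_lures", f"must be an integer >= 0, got {self.n_lures!r}")
        if len(self.class_mean_logit) != 2:
            raise ConfigError("class_mean_logit", "needs exactly two entries (AP, nonAP)")
        if len(self.class_image_sd) != 2:
            raise ConfigError("class_image_sd", "needs exactly two entries (AP, nonAP)")
        sds = {
            "class_image_sd[AP]": self.class_image_sd[0],
            "class_image_sd[nonAP]": self.class_image_sd[1],
            "participant_intercept_sd": self.participant_intercept_sd,
            "participant_slope_sd": self.participant_slope_sd,
            "rating_image_sd": self.rating_image_sd,
            "rating_participant_intercept_sd": self.rating_participant_intercept_sd,
            "rating_participant_slope_sd": self.rating_participant_slope_sd,
            "rating_noise_sd": self.rating_noise_sd,
            "lure_image_sd": self.lure_image_sd,
        }
        for name, value in sds.items():
            if value < 0:
                raise ConfigError(name, f"standard deviations must be >= 0, got {value!r}")
        if not 0.0 <= self.vigilance_fail_prob <= 1.0:
            raise ConfigError(
                "vigilance_fail_prob",
                f"must be a probability in [0, 1], got {self.vigilance_fail_prob!r}",
            )
        if not -1.0 <= self.rating_memory_coupling <= 1.0:
            raise ConfigError(
                "rating_memory_coupling",
                f"must lie in [-1, 1], got {self.rating_memory_coupling!r}",
            )
        if self.n_vigilance_failures is not None:
            if (
                not isinstance(self.n_vigilance_failures, int)
                or not 0 <= self.n_vigilance_failures <= self.n_participants
            ):
                raise ConfigError(
                    "n_vigilance_failures",
                    "must be None or an integer in [0, n_participants], "
                    f"got {self.n_vigilance_failures!r}",
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_mean_logit"] = list(self.class_mean_logit)
        d["class_image_sd"] = list(self.class_image_sd)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end analysis settings.

    ``n_iterations`` is the number of random participant splits for the
    consistency analysis, ``n_permutations`` the number of class-label
    permutations / sign flips, ``n_bootstrap`` the bootstrap resample count.
    """

    seed: int = 0
    n_iterations: int = 1000
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    alpha: float = 0.05
    excluded_images: list[str] = field(default_factory=list)
    run_models: bool = True
    run_comparison: bool = True
    run_consistency: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha", f"must lie in (0, 1), got {self.alpha!r}")
        for name in ("n_iterations", "n_permutations", "n_bootstrap"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 1:
                raise ConfigError(name, f"must be an integer >= 1, got {value!r}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed", f"must be an integer, got {self.seed!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration field")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("<root>", f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def config_hash(config: "RunConfig | SimulationConfig") -> str:
    """Short stable hash of a config, embedded in every results file."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:16]


def _as_override(config: RunConfig, **overrides) -> RunConfig:
    """Return a copy of ``config`` with non-None overrides applied."""
    d = config.to_dict()
    for key, value in overrides.items():
        if value is not None:
            d[key] = value
    return RunConfig.from_dict(d)
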