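"""Canonical factor levels and study configuration objects.

Every module reads factor levels from here so that no dialect drift can
occur between the simulator, the kinematics stage and the model catalogue.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

CULTURES = ("UK", "JP")
#: reference level first — all dummy codings downstream use index 0 as reference
GROUPS = ("non_aut", "aut")
CONDITIONS = ("mental", "non_mental")

MENTAL_WORDS = ("arguing", "surprising", "teasing")
NON_MENTAL_WORDS = ("following", "searching", "dancing")
DEFAULT_WORDS = MENTAL_WORDS + NON_MENTAL_WORDS


class ConfigurationError(ValueError):
    """Raised when a study configuration violates its invariants."""


@dataclass(frozen=True)
class DesignConfig:
    """Crossed 2 (culture) x 2 (group) generation/rating design.

    Parameters
    ----------
    n_per_cell : participants per culture x group cell.
    words : six word labels; the first three form the mental-state triad,
        the last three the non-mental (goal-directed) triad.
    animations_per_cell : animations each observer rates per
        word x generator-group x generator-culture cell (default 6, which
        yields 6 x 6 x 2 x 2 = 144 rated animations per observer).
    sampling_rate : trajectory sampling rate in Hz (default 60).
    seed : master seed; all phase RNG streams derive from it.
    """

    n_per_cell: int = 15
    words: tuple = DEFAULT_WORDS
    animations_per_cell: int = 6
    sampling_rate: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_cell < 1:
            raise ConfigurationError("n_per_cell must be a positive integer")
        if len(self.words) != 6 or len(set(self.words)) != 6:
            raise ConfigurationError("word list must contain exactly 6 distinct words")
        if self.animations_per_cell < 1:
            raise ConfigurationError("animations_per_cell must be positive")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")

    @property
    def mental_words(self) -> tuple:
        return tuple(self.words[:3])

    @property
    def non_mental_words(self) -> tuple:
        return tuple(self.words[3:])

    def word_condition(self, word: str) -> str:
        if word in self.mental_words:
            return "mental"
        if word in self.non_mental_words:
            return "non_mental"
        raise ConfigurationError(f"word {word!r} not in the design's word list")


@dataclass(frozen=True)
class TrajectoryParams:
    """Generative parameters for one two-triangle animation.

    The trajectory is a chain of minimum-jerk submovements per triangle;
    ``n_submovements`` and ``submovement_amplitude_sd`` jointly control the
    jerk level (jerk grows with submovement count at fixed duration), and
    ``noise_sd`` adds white positional noise on top of the smooth path.
    Units are normalised screen units (the screen is the unit square).
    """

    duration: float = 5.0
    n_submovements: int = 8
    submovement_amplitude_sd: float = 0.15
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.n_submovements < 1:
            raise ConfigurationError("n_submovements must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CellKinematics:
    """Kinematic profile of one culture x group generator cell.

    ``jerk_level_log_sd`` is the between-generator lognormal spread of the
    submovement amplitude multiplier; mean jerk scales linearly with
    amplitude, so this directly controls the inter-subject jerk CV of the
    cell. 0 makes every generator in the cell share the expected jerk level.
    """

    base: TrajectoryParams = field(default_factory=TrajectoryParams)
    jerk_level_log_sd: float = 0.25

    def __post_init__(self):
        if self.jerk_level_log_sd < 0:
            raise ConfigurationError("jerk_level_log_sd must be >= 0")


def default_cell_profiles() -> dict:
    """Default kinematic profiles: equal expected jerk in all cells, with
    elevated inter-subject jerk variability among UK autistic generators."""
    profiles = {}
    for culture in CULTURES:
        for group in GROUPS:
            spread = 0.5 if (culture == "UK" and group == "aut") else 0.25
            profiles[(culture, group)] = CellKinematics(jerk_level_log_sd=spread)
    return profiles


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth fixed and random effects for the rating simulator.

    All values are on the accuracy scale (score units, -100..100).
    ``beta_generator_group`` / ``beta_observer_group`` are effects of the
    autistic level relative to non-autistic; ``beta_mental_state`` is the
    effect of the mental-state condition relative to non-mental;
    ``beta_jerk_difference`` is per SD of observer-animation jerk difference.
    """

    baseline_accuracy: float = 15.0
    beta_generator_group: float = -8.0
    beta_observer_group: float = 0.0
    beta_interaction: float = 3.0
    beta_mental_state: float = 0.0
    beta_jerk_difference: float = -2.0
    sd_subject_intercept: float = 8.0
    sd_animation_intercept: float = 10.0
    sd_subject_slopes: float = 3.0
    sd_residual: float = 25.0

    def __post_init__(self):
        for name in ("sd_subject_intercept", "sd_animation_intercept",
                     "sd_subject_slopes", "sd_residual"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class McmcSettings:
    """Sampler run length. ``iterations`` counts total iterations per chain,
    of which the first ``warmup`` are discarded."""

    chains: int = 4
    iterations: int = 4000
    warmup: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.chains < 2:
            raise ConfigurationError("chains must be >= 2")
        if self.iterations <= self.warmup:
            raise ConfigurationError("iterations must exceed warmup")


# --- phase-separated RNG streams -------------------------------------------

_PHASES = {"design": 0, "trajectories": 1, "sessions": 2, "ratings": 3}


def phase_rng(seed: int, phase: str) -> np.random.Generator:
    """One independent RNG stream per pipeline phase, all derived from the
    study seed, so a phase can be re-run without disturbing the others."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _PHASES[phase]]))


# --- YAML round-trips --------------------------------------------------------

def design_to_dict(cfg: DesignConfig) -> dict:
    d = asdict(cfg)
    d["words"] = list(cfg.words)
    return d


def design_from_dict(d: Mapping) -> DesignConfig:
    d = dict(d)
    if "words" in d:
        d["words"] = tuple(d["words"])
    return DesignConfig(**d)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
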