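"""Synthetic animation-generation and rating studies.

Generates complete studies with the statistical structure the analysis
assumes: a crossed 2 (culture) x 2 (group) design, six words split into
mental-state and goal-directed triads, two-triangle trajectories built from
chains of minimum-jerk submovements, balanced pseudo-random rating sessions
(144 animations per observer under the defaults), and ratings whose latent
trial accuracy follows a linear model with subject- and animation-level
random effects.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import (
    CULTURES,
    GROUPS,
    CellKinematics,
    ConfigurationError,
    DesignConfig,
    EffectSpec,
    TrajectoryParams,
    default_cell_profiles,
    phase_rng,
)

__all__ = [
    "StudyDesign",
    "AnimationSet",
    "SyntheticStudy",
    "make_design",
    "simulate_trajectory",
    "simulate_generation_phase",
    "assemble_rating_sessions",
    "simulate_ratings",
    "simulate_study",
]


@dataclass(frozen=True)
class StudyDesign:
    """Participants and the word/condition table of one study."""

    participants: pd.DataFrame  # participant_id, culture, group
    words: pd.DataFrame  # word, condition
    config: DesignConfig


@dataclass(frozen=True)
class AnimationSet:
    """Animation metadata plus the long-format trajectory table."""

    animations: pd.DataFrame  # animation_id, generator_id, word, condition
    trajectories: pd.DataFrame  # animation_id, t, triangle_id, x, y


@dataclass(frozen=True)
class SyntheticStudy:
    design: StudyDesign
    animations: AnimationSet
    sessions: pd.DataFrame  # observer_id, animation_id
    ratings: pd.DataFrame  # observer_id, animation_id, <6 word columns>
    latent: pd.DataFrame  # observer_id, animation_id, latent_accuracy


def make_design(config: DesignConfig) -> StudyDesign:
    """Build the participant roster and word table for one study.

    Four culture x group cells with ``n_per_cell`` participants each;
    deterministic given the config (the roster involves no random draws).
    """
    rows = []
    for culture in CULTURES:
        for group in GROUPS:
            for i in range(config.n_per_cell):
                rows.append(
                    {
                        "participant_id": f"{culture}_{group}_{i + 1:03d}",
                        "culture": culture,
                        "group": group,
                    }
                )
    participants = pd.DataFrame(rows)
    words = pd.DataFrame(
        {
            "word": list(config.words),
            "condition": [config.word_condition(w) for w in config.words],
        }
    )
    return StudyDesign(participants=participants, words=words, config=config)


def _min_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile on tau in [0, 1]."""
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _one_triangle_path(
    t: np.ndarray, params: TrajectoryParams, amplitude_scale: float, rng
) -> np.ndarray:
    """Chain of minimum-jerk submovements for one triangle; (n, 2) array."""
    k = params.n_submovements
    seg = params.duration / k
    start = rng.uniform(0.3, 0.7, size=2)
    # displacement vector of each submovement
    disp = rng.normal(
        0.0, params.submovement_amplitude_sd * amplitude_scale, size=(k, 2)
    )
    pos = np.empty((t.size, 2))
    seg_idx = np.minimum((t / seg).astype(int), k - 1)
    tau = (t - seg_idx * seg) / seg
    s = _min_jerk_profile(np.clip(tau, 0.0, 1.0))
    cum = np.vstack([np.zeros(2), np.cumsum(disp, axis=0)])  # (k+1, 2)
    pos = start + cum[seg_idx] + disp[seg_idx] * s[:, None]
    if params.noise_sd > 0:
        pos = pos + rng.normal(0.0, params.noise_sd, size=pos.shape)
    return np.clip(pos, 0.0, 1.0)


def simulate_trajectory(
    params: TrajectoryParams,
    sampling_rate: float = 60.0,
    rng: Optional[np.random.Generator] = None,
    animation_id: str = "anim",
    amplitude_scale: float = 1.0,
) -> pd.DataFrame:
    """Simulate one two-triangle trajectory in long format.

    Each triangle follows its own chain of ``n_submovements`` minimum-jerk
    submovements with random directions and amplitudes, plus optional white
    positional noise, clipped to the unit square.

    Returns a DataFrame with columns ``animation_id, t, triangle_id, x, y``
    and ``round(duration * sampling_rate)`` samples per triangle.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(params.duration * sampling_rate))
    if n < 8:
        raise ConfigurationError(
            "trajectory too short to differentiate thrice: "
            f"duration*sampling_rate = {n} < 8 samples"
        )
    t = np.arange(n) / sampling_rate
    frames = []
    for tri in (1, 2):
        pos = _one_triangle_path(t, params, amplitude_scale, rng)
        frames.append(
            pd.DataFrame(
                {
                    "animation_id": animation_id,
                    "t": t,
                    "triangle_id": tri,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_generation_phase(
    design: StudyDesign,
    profiles: Optional[Mapping[tuple, CellKinematics]] = None,
) -> AnimationSet:
    """Generate one animation per participant x word.

    Each participant draws a lognormal jerk-level multiplier from their
    cell's profile, so inter-subject jerk dispersion is controllable per
    culture x group cell (a ``jerk_level_log_sd`` of 0 gives every generator
    in the cell the same expected jerk).
    """
    if profiles is None:
        profiles = default_cell_profiles()
    missing = [
        (c, g)
        for c in CULTURES
        for g in GROUPS
        if (c, g) not in profiles
    ]
    if missing:
        raise ConfigurationError(f"missing kinematic profiles for cells: {missing}")

    cfg = design.config
    rng = phase_rng(cfg.seed, "trajectories")
    meta_rows = []
    traj_frames = []
    for row in design.participants.itertuples(index=False):
        profile = profiles[(row.culture, row.group)]
        scale = float(
            np.exp(rng.normal(0.0, profile.jerk_level_log_sd))
        ) if profile.jerk_level_log_sd > 0 else 1.0
        for word in cfg.words:
            animation_id = f"{row.participant_id}__{word}"
            traj = simulate_trajectory(
                profile.base,
                sampling_rate=cfg.sampling_rate,
                rng=rng,
                animation_id=animation_id,
                amplitude_scale=scale,
            )
            traj_frames.append(traj)
            meta_rows.append(
                {
                    "animation_id": animation_id,
                    "generator_id": row.participant_id,
                    "word": word,
                    "condition": cfg.word_condition(word),
                }
            )
    return AnimationSet(
        animations=pd.DataFrame(meta_rows),
        trajectories=pd.concat(traj_frames, ignore_index=True),
    )


def assemble_rating_sessions(
    design: StudyDesign, animations: AnimationSet, seed: Optional[int] = None
) -> pd.DataFrame:
    """Pseudo-randomly assign each observer a balanced rating session.

    Every observer receives ``animations_per_cell`` animations for each of
    the word x generator-group x generator-culture cells (144 under the
    defaults) and never rates an animation they generated themselves.

    Returns a DataFrame with columns ``observer_id, animation_id``.
    """
    cfg = design.config
    rng = phase_rng(cfg.seed if seed is None else seed, "sessions")
    meta = animations.animations.merge(
        design.participants.rename(
            columns={
                "participant_id": "generator_id",
                "culture": "generator_culture",
                "group": "generator_group",
            }
        ),
        on="generator_id",
    )
    pools = {
        key: grp
        for key, grp in meta.groupby(["word", "generator_culture", "generator_group"])
    }
    rows = []
    for observer in design.participants["participant_id"]:
        for word in cfg.words:
            for culture in CULTURES:
                for group in GROUPS:
                    pool = pools.get((word, culture, group))
                    candidates = (
                        [] if pool is None
                        else pool.loc[pool["generator_id"] != observer, "animation_id"].tolist()
                    )
                    if len(candidates) < cfg.animations_per_cell:
                        raise ConfigurationError(
                            "animation pool exhausted for cell "
                            f"word={word!r}, culture={culture}, group={group} "
                            f"(need {cfg.animations_per_cell}, have {len(candidates)})"
                        )
                    chosen = rng.choice(
                        candidates, size=cfg.animations_per_cell, replace=False
                    )
                    rows.extend(
                        {"observer_id": observer, "animation_id": a} for a in chosen
                    )
    return pd.DataFrame(rows)


def _latent_accuracy(
    trials: pd.DataFrame,
    effects: EffectSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent accuracy per trial: fixed effects + crossed random effects."""
    gen_aut = (trials["generator_group"] == "aut").to_numpy(float)
    obs_aut = (trials["observer_group"] == "aut").to_numpy(float)
    mental = (trials["condition"] == "mental").to_numpy(float)

    mu = (
        effects.baseline_accuracy
        + effects.beta_generator_group * gen_aut
        + effects.beta_observer_group * obs_aut
        + effects.beta_interaction * gen_aut * obs_aut
        + effects.beta_mental_state * mental
    )
    if effects.beta_jerk_difference != 0.0:
        zj = trials["z_jerk_difference"].to_numpy(float)
        mu = mu + effects.beta_jerk_difference * zj

    observers = trials["observer_id"].to_numpy()
    anims = trials["animation_id"].to_numpy()
    obs_levels, obs_idx = np.unique(observers, return_inverse=True)
    anim_levels, anim_idx = np.unique(anims, return_inverse=True)
    u_obs = rng.normal(0.0, effects.sd_subject_intercept, size=obs_levels.size)
    v_anim = rng.normal(0.0, effects.sd_animation_intercept, size=anim_levels.size)
    s_obs = rng.normal(0.0, effects.sd_subject_slopes, size=obs_levels.size)
    eps = rng.normal(0.0, effects.sd_residual, size=len(trials)) if effects.sd_residual > 0 else 0.0
    return mu + u_obs[obs_idx] + v_anim[anim_idx] + s_obs[obs_idx] * gen_aut + eps


def simulate_ratings(
    sessions: pd.DataFrame,
    animations: AnimationSet,
    design: StudyDesign,
    effects: EffectSpec,
    kinematics_table: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
    rating_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the six visual-analogue ratings of every trial.

    The latent trial accuracy is a linear model (per ``effects``) of the
    observer/generator groups, the condition, and the z-scored
    observer-animation jerk difference, plus subject and animation random
    intercepts, a subject slope on generator group, and residual noise.
    Ratings are constructed symmetrically around the scale midpoint
    (target = 50 + A/2, each non-target = 50 - A/2) so the accuracy statistic
    recovers the latent value exactly before clipping to [0, 100].

    ``kinematics_table`` must carry ``animation_id, mean_jerk`` and is
    required whenever ``effects.beta_jerk_difference`` is nonzero.

    Returns ``(ratings, latent)``: the wide ratings table and the latent
    accuracy per trial (useful for exactness checks and recovery tests).
    """
    cfg = design.config
    rng = phase_rng(cfg.seed if seed is None else seed, "ratings")

    meta = animations.animations
    unknown = set(sessions["animation_id"]) - set(meta["animation_id"])
    if unknown:
        raise ConfigurationError(f"unknown animation ids in sessions: {sorted(unknown)[:5]}")

    trials = sessions.merge(meta, on="animation_id")
    parts = design.participants
    trials = trials.merge(
        parts.rename(
            columns={"participant_id": "observer_id", "culture": "observer_culture", "group": "observer_group"}
        ),
        on="observer_id",
    ).merge(
        parts.rename(
            columns={"participant_id": "generator_id", "culture": "generator_culture", "group": "generator_group"}
        ),
        on="generator_id",
    )

    if effects.beta_jerk_difference != 0.0:
        if kinematics_table is None:
            raise ConfigurationError(
                "kinematics_table is required when beta_jerk_difference != 0"
            )
        from .kinematics import jerk_difference_table, observer_word_jerk

        own = observer_word_jerk(kinematics_table, meta)
        jd = jerk_difference_table(own, kinematics_table, trials[["observer_id", "animation_id", "word"]])
        trials = trials.merge(
            jd[["observer_id", "animation_id", "z_jerk_difference"]],
            on=["observer_id", "animation_id"],
        )

    latent = _latent_accuracy(trials, effects, rng)

    words = list(cfg.words)
    target_mask = np.stack(
        [(trials["word"] == w).to_numpy() for w in words], axis=1
    )  # (n, 6)
    base = np.where(target_mask, 50.0 + latent[:, None] / 2.0, 50.0 - latent[:, None] / 2.0)
    if rating_noise_sd > 0:
        base = base + rng.normal(0.0, rating_noise_sd, size=base.shape)
    ratings = pd.DataFrame(np.clip(base, 0.0, 100.0), columns=words)
    ratings.insert(0, "animation_id", trials["animation_id"].to_numpy())
    ratings.insert(0, "observer_id", trials["observer_id"].to_numpy())
    latent_df = trials[["observer_id", "animation_id"]].copy()
    latent_df["latent_accuracy"] = latent
    return ratings, latent_df


def simulate_study(
    config: Optional[DesignConfig] = None,
    effects: Optional[EffectSpec] = None,
    profiles: Optional[Mapping[tuple, CellKinematics]] = None,
    rating_noise_sd: float = 0.0,
) -> SyntheticStudy:
    """End-to-end synthetic study: design, animations, sessions, ratings."""
    from .kinematics import kinematic_summaries

    config = config or DesignConfig()
    effects = effects or EffectSpec()
    design = make_design(config)
    animations = simulate_generation_phase(design, profiles)
    sessions = assemble_rating_sessions(design, animations)
    kin = (
        kinematic_summaries(animations.trajectories)
        if effects.beta_jerk_difference != 0.0
        else None
    )
    ratings, latent = simulate_ratings(
        sessions, animations, design, effects,
        kinematics_table=kin, rating_noise_sd=rating_noise_sd,
    )
    return SyntheticStudy(
        design=design,
        animations=animations,
        sessions=sessions,
        ratings=ratings,
        latent=latent,
    )
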