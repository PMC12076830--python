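"""Jerk and derived kinematic statistics.

Jerk is the third time-derivative of position, estimated by repeated central
finite differences on the raw (optionally low-pass filtered) positional
samples. The per-animation summary is the time-averaged Euclidean norm of
the 2-D jerk vector, averaged over the two triangles, so it is a
non-negative movement-smoothness intensity: translation-invariant and
linear under spatial scaling.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "KinematicsError",
    "differentiate",
    "mean_jerk",
    "kinematic_summaries",
    "observer_word_jerk",
    "jerk_difference_table",
    "jerk_cv",
]


class KinematicsError(ValueError):
    pass


def _uniform_dt(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.size == 0:
        raise KinematicsError("trajectory has a single sample")
    dt0 = float(np.median(dt))
    if dt0 <= 0 or np.any(np.abs(dt - dt0) > 1e-6 * max(dt0, 1.0)):
        raise KinematicsError("non-uniform time steps beyond tolerance")
    return dt0


def _central_diff(values: np.ndarray, dt: float, order: int) -> np.ndarray:
    out = values
    for _ in range(order):
        out = (out[2:] - out[:-2]) / (2.0 * dt)
    return out


def _lowpass(values: np.ndarray, dt: float, cutoff_hz: float) -> np.ndarray:
    nyq = 0.5 / dt
    if cutoff_hz >= nyq:
        return values
    b, a = signal.butter(2, cutoff_hz / nyq)
    return signal.filtfilt(b, a, values, axis=0)


def differentiate(
    trajectory: pd.DataFrame,
    order: int = 3,
    smooth_cutoff_hz: Optional[float] = None,
) -> dict:
    """Per-triangle derivative time series of the given order (1..3).

    Applies central finite differences ``order`` times per axis; each pass
    trims one sample at each end, so the series shrinks by ``2 * order``.
    With ``smooth_cutoff_hz`` set, a zero-phase 2nd-order Butterworth
    low-pass is applied to position before differentiating (third
    derivatives amplify high-frequency noise).

    Returns ``{triangle_id: (t_interior, deriv)}`` with ``deriv`` of shape
    ``(n - 2*order, 2)``.
    """
    if order not in (1, 2, 3):
        raise KinematicsError("order must be 1, 2 or 3")
    out = {}
    for tri, grp in trajectory.groupby("triangle_id"):
        grp = grp.sort_values("t")
        t = grp["t"].to_numpy(float)
        if t.size < order + 1 or t.size <= 2 * order:
            raise KinematicsError(
                f"triangle {tri}: {t.size} samples are too few for order {order}"
            )
        dt = _uniform_dt(t)
        xy = grp[["x", "y"]].to_numpy(float)
        if smooth_cutoff_hz is not None:
            xy = _lowpass(xy, dt, smooth_cutoff_hz)
        deriv = _central_diff(xy, dt, order)
        out[tri] = (t[order:-order], deriv)
    if not out:
        raise KinematicsError("empty trajectory")
    return out


def mean_jerk(
    trajectory: pd.DataFrame, smooth_cutoff_hz: Optional[float] = None
) -> float:
    """Mean jerk of one animation.

    Euclidean norm of the (x, y) jerk vector at each interior sample,
    averaged over time per triangle, then averaged over the two triangles.
    """
    per_triangle = []
    for _tri, (_t, jerk) in differentiate(
        trajectory, order=3, smooth_cutoff_hz=smooth_cutoff_hz
    ).items():
        per_triangle.append(float(np.mean(np.linalg.norm(jerk, axis=1))))
    return float(np.mean(per_triangle))


def kinematic_summaries(
    trajectories: pd.DataFrame, smooth_cutoff_hz: Optional[float] = None
) -> pd.DataFrame:
    """Per-animation mean jerk table: columns ``animation_id, mean_jerk``."""
    rows = [
        {"animation_id": aid, "mean_jerk": mean_jerk(grp, smooth_cutoff_hz)}
        for aid, grp in trajectories.groupby("animation_id", sort=True)
    ]
    return pd.DataFrame(rows)


def observer_word_jerk(
    animation_summaries: pd.DataFrame, animations: pd.DataFrame
) -> pd.DataFrame:
    """Each participant's own mean jerk per word, derived from the jerk of
    the animation they generated for that word.

    Returns columns ``participant_id, word, mean_jerk``.
    """
    merged = animations.merge(animation_summaries, on="animation_id")
    return merged.rename(columns={"generator_id": "participant_id"})[
        ["participant_id", "word", "mean_jerk"]
    ]


def jerk_difference_table(
    observer_summaries: pd.DataFrame,
    animation_summaries: pd.DataFrame,
    trials: pd.DataFrame,
) -> pd.DataFrame:
    """Observer-animation jerk difference per rating trial.

    For every trial, the observer's own mean jerk for the trial's word is
    subtracted from the rated animation's mean jerk and the absolute
    magnitude taken; lower values mean higher observer-agent kinematic
    similarity. ``z_jerk_difference`` standardises the column over the
    supplied trial set (the population entering the model).

    Parameters
    ----------
    observer_summaries : columns ``participant_id, word, mean_jerk``.
    animation_summaries : columns ``animation_id, mean_jerk``.
    trials : columns ``observer_id, animation_id, word``; one row per trial.
    """
    own = observer_summaries.rename(
        columns={"participant_id": "observer_id", "mean_jerk": "own_jerk"}
    )
    merged = trials.merge(own, on=["observer_id", "word"], how="left")
    missing = merged[merged["own_jerk"].isna()][["observer_id", "word"]].drop_duplicates()
    if len(missing):
        raise KinematicsError(
            "missing own-animation jerk for observer/word pairs: "
            + ", ".join(f"{r.observer_id}/{r.word}" for r in missing.itertuples())
        )
    merged = merged.merge(
        animation_summaries.rename(columns={"mean_jerk": "animation_jerk"}),
        on="animation_id",
        how="left",
    )
    if merged["animation_jerk"].isna().any():
        bad = merged.loc[merged["animation_jerk"].isna(), "animation_id"].unique()
        raise KinematicsError(f"missing animation jerk for: {list(bad)[:5]}")
    jd = np.abs(merged["own_jerk"].to_numpy() - merged["animation_jerk"].to_numpy())
    out = merged[["observer_id", "animation_id", "word"]].copy()
    out["jerk_difference"] = jd
    sd = jd.std(ddof=1)
    out["z_jerk_difference"] = (jd - jd.mean()) / sd if sd > 0 else 0.0
    return out


def jerk_cv(
    animation_summaries: pd.DataFrame,
    animations: pd.DataFrame,
    participants: pd.DataFrame,
) -> pd.DataFrame:
    """Inter-generator jerk variability per culture x group x word.

    CV = sample standard deviation / mean of the generators' mean-jerk
    values within the cell; six words yield six CV values per
    culture x group. Requires at least two generators per cell and a
    strictly positive cell mean.

    Returns columns ``culture, group, word, cv``.
    """
    merged = (
        animations.merge(animation_summaries, on="animation_id")
        .merge(
            participants.rename(columns={"participant_id": "generator_id"}),
            on="generator_id",
        )
    )
    rows = []
    for (culture, group, word), grp in merged.groupby(["culture", "group", "word"]):
        vals = grp["mean_jerk"].to_numpy(float)
        if vals.size < 2:
            raise KinematicsError(
                f"cell culture={culture}, group={group}, word={word!r} has "
                f"{vals.size} generator(s); need >= 2 for a CV"
            )
        m = vals.mean()
        if m <= 0:
            raise KinematicsError(
                f"non-positive mean jerk in cell {culture}/{group}/{word!r}"
            )
        rows.append(
            {"culture": culture, "group": group, "word": word, "cv": vals.std(ddof=1) / m}
        )
    return pd.DataFrame(rows)
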