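"""Trial-level accuracy and the modelling table.

Accuracy of one rating trial is the rating of the target word minus the
mean rating of the five non-target words, so it lives in [-100, 100]:
positive values mean the observer discriminated the intended word from the
alternatives, values near zero mean confusion between scales.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ScoringError", "accuracy", "accuracy_table", "build_model_table"]


class ScoringError(ValueError):
    pass


def accuracy(ratings: Mapping[str, float], target_word: str) -> float:
    """Target rating minus the mean of the five non-target ratings."""
    if len(ratings) != 6:
        raise ScoringError(f"expected 6 ratings, got {len(ratings)}")
    if target_word not in ratings:
        raise ScoringError(f"target word {target_word!r} missing from ratings")
    for word, value in ratings.items():
        if not (0.0 <= value <= 100.0):
            raise ScoringError(f"rating for {word!r} outside [0, 100]: {value}")
    target = ratings[target_word]
    others = [v for w, v in ratings.items() if w != target_word]
    return float(target - np.mean(others))


def accuracy_table(
    ratings: pd.DataFrame,
    animations: pd.DataFrame,
    participants: pd.DataFrame,
    words: Sequence[str],
) -> pd.DataFrame:
    """One accuracy record per rating trial, with all factor columns.

    Parameters
    ----------
    ratings : wide table ``observer_id, animation_id, <word columns>``.
    animations : ``animation_id, generator_id, word, condition``.
    participants : ``participant_id, culture, group``.
    words : the six word labels (column names in ``ratings``).
    """
    words = list(words)
    missing_cols = [w for w in words if w not in ratings.columns]
    if missing_cols:
        raise ScoringError(f"ratings table lacks word columns: {missing_cols}")
    vals = ratings[words].to_numpy(float)
    if np.isnan(vals).any() or (vals < 0).any() or (vals > 100).any():
        raise ScoringError("ratings contain missing or out-of-range values")

    merged = ratings.merge(animations, on="animation_id", how="left")
    if merged["word"].isna().any():
        bad = merged.loc[merged["word"].isna(), "animation_id"].unique()
        raise ScoringError(f"animations missing metadata: {list(bad)[:5]}")
    target_idx = merged["word"].map({w: i for i, w in enumerate(words)}).to_numpy()
    vals = merged[words].to_numpy(float)
    target = vals[np.arange(len(merged)), target_idx]
    non_target_mean = (vals.sum(axis=1) - target) / (len(words) - 1)

    out = merged[["observer_id", "animation_id", "word", "condition"]].copy()
    out["accuracy"] = target - non_target_mean
    out = out.merge(
        participants.rename(
            columns={"participant_id": "observer_id", "culture": "observer_culture", "group": "observer_group"}
        ),
        on="observer_id",
        how="left",
    ).merge(
        animations[["animation_id", "generator_id"]], on="animation_id"
    ).merge(
        participants.rename(
            columns={"participant_id": "generator_id", "culture": "generator_culture", "group": "generator_group"}
        ),
        on="generator_id",
        how="left",
    )
    for col in ("observer_group", "generator_group"):
        if out[col].isna().any():
            raise ScoringError(f"unmatched participants while building {col}")
    return out[
        [
            "observer_id",
            "animation_id",
            "word",
            "condition",
            "accuracy",
            "observer_culture",
            "observer_group",
            "generator_culture",
            "generator_group",
        ]
    ]


def build_model_table(
    accuracy_records: pd.DataFrame, jerk_difference_records: pd.DataFrame
) -> pd.DataFrame:
    """Join accuracy records with jerk-difference covariates, one row per
    rated trial. The join must be lossless: every accuracy record appears
    exactly once and orphans on either side are an error."""
    table = accuracy_records.merge(
        jerk_difference_records[
            ["observer_id", "animation_id", "jerk_difference", "z_jerk_difference"]
        ],
        on=["observer_id", "animation_id"],
        how="outer",
        indicator=True,
    )
    orphans = table[table["_merge"] != "both"]
    if len(orphans):
        sample = orphans[["observer_id", "animation_id", "_merge"]].head(5)
        raise ScoringError(f"unmatched keys in model-table join:\n{sample}")
    if len(table) != len(accuracy_records):
        raise ScoringError("model-table join is not one-to-one")
    return table.drop(columns="_merge")
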