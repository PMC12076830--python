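"""End-to-end orchestration: simulate -> kinematics -> score -> fit -> report.

Every stage consumes only documented artefacts of earlier stages and all
numeric output is fully determined by the run configuration and its seed.
Real deposited data enter through a mapping-driven ingestion path that
produces the same canonical model table as the synthetic route.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import contrast, fit as fit_model, summarise
from .catalogue import model_catalogue
from .config import (
    ConfigurationError,
    DesignConfig,
    EffectSpec,
    McmcSettings,
    design_from_dict,
    design_to_dict,
)
from .kinematics import jerk_cv, jerk_difference_table, kinematic_summaries, observer_word_jerk
from .scoring import accuracy_table, build_model_table
from .synthetic import SyntheticStudy, simulate_study

__all__ = [
    "RunConfig",
    "ReportBundle",
    "build_tables",
    "run_pipeline",
    "ingest_real_data",
    "recovery_experiment",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    design: DesignConfig = field(default_factory=DesignConfig)
    effects: EffectSpec = field(default_factory=EffectSpec)
    models: tuple = ("UK.1",)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    rating_noise_sd: float = 0.0
    outdir: Optional[str] = None
    write_trajectories: bool = False

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig(
            design=design_from_dict(raw.get("design", {})),
            effects=EffectSpec(**raw.get("effects", {})),
            models=tuple(raw.get("models", ("UK.1",))),
            mcmc=McmcSettings(**raw.get("mcmc", {})),
            rating_noise_sd=float(raw.get("rating_noise_sd", 0.0)),
            outdir=raw.get("outdir"),
            write_trajectories=bool(raw.get("write_trajectories", False)),
        )

    def to_dict(self) -> dict:
        return {
            "design": design_to_dict(self.design),
            "effects": asdict(self.effects),
            "models": list(self.models),
            "mcmc": asdict(self.mcmc),
            "rating_noise_sd": self.rating_noise_sd,
            "outdir": self.outdir,
            "write_trajectories": self.write_trajectories,
        }


@dataclass
class ReportBundle:
    """Per-model posterior tables, contrasts, diagnostics and provenance."""

    summaries: dict  # model name -> DataFrame
    contrasts: dict  # model name -> DataFrame
    diagnostics: dict  # model name -> dict
    tables: dict  # canonical tables used for fitting
    provenance: dict
    fits: dict  # model name -> ModelFit

    def payload(self) -> dict:
        """JSON-serialisable numeric payload (no timestamps)."""
        return {
            "provenance": self.provenance,
            "models": {
                name: {
                    "summary": self.summaries[name].to_dict(orient="records"),
                    "contrasts": self.contrasts[name].to_dict(orient="records"),
                    "diagnostics": self.diagnostics[name],
                }
                for name in self.summaries
            },
        }


def _config_hash(config: RunConfig) -> str:
    # hash covers everything that determines the numbers; output location
    # and artefact verbosity do not
    d = config.to_dict()
    d.pop("outdir", None)
    d.pop("write_trajectories", None)
    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    import arviz
    import scipy

    return {
        "package_version": __version__,
        "seed": config.design.seed,
        "mcmc_seed": config.mcmc.seed,
        "config_hash": _config_hash(config),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "arviz": arviz.__version__,
        },
    }


def build_tables(study: SyntheticStudy) -> dict:
    """Canonical analysis tables from a simulated (or ingested) study:

    - ``trials``: one row per rated trial (accuracy, factors, jerk difference)
    - ``animation_jerk``: per-animation mean jerk with generator factors
    - ``jerk_cv``: per culture x group x word jerk coefficient of variation
    """
    design = study.design
    kin = kinematic_summaries(study.animations.trajectories)
    acc = accuracy_table(
        study.ratings, study.animations.animations,
        design.participants, design.config.words,
    )
    own = observer_word_jerk(kin, study.animations.animations)
    jd = jerk_difference_table(
        own, kin, acc[["observer_id", "animation_id", "word"]]
    )
    trials = build_model_table(acc, jd)

    animation_jerk = (
        study.animations.animations.merge(kin, on="animation_id")
        .merge(
            design.participants.rename(columns={"participant_id": "generator_id"}),
            on="generator_id",
        )
    )
    cv = jerk_cv(kin, study.animations.animations, design.participants)
    return {"trials": trials, "animation_jerk": animation_jerk, "jerk_cv": cv}


def default_contrasts(name: str) -> list:
    """Reported post-hoc contrasts per model, as (label, cells) pairs."""
    g, o = "generator_group", "observer_group"
    if name.endswith(".1") and name.split(".")[0] in ("UK", "JP"):
        return [
            ("gen aut-vs-non_aut | obs non_aut",
             [(1, {g: "aut", o: "non_aut"}), (-1, {g: "non_aut", o: "non_aut"})]),
            ("gen aut-vs-non_aut | obs aut",
             [(1, {g: "aut", o: "aut"}), (-1, {g: "non_aut", o: "aut"})]),
            ("cell mean | obs aut, gen non_aut", [(1, {g: "non_aut", o: "aut"})]),
            ("cell mean | obs non_aut, gen aut", [(1, {g: "aut", o: "non_aut"})]),
        ]
    if name == "JPUK.7":
        return [
            ("group aut-vs-non_aut | culture UK",
             [(1, {"group": "aut", "culture": "UK"}),
              (-1, {"group": "non_aut", "culture": "UK"})]),
            ("group aut-vs-non_aut | culture JP",
             [(1, {"group": "aut", "culture": "JP"}),
              (-1, {"group": "non_aut", "culture": "JP"})]),
        ]
    return []


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages in order and return (and optionally write) the
    report bundle. Unknown model names fail before any computation."""
    catalogue = model_catalogue()
    unknown = [m for m in config.models if m not in catalogue]
    if unknown:
        raise ConfigurationError(
            f"unknown model(s) {unknown}; catalogue has {sorted(catalogue)}"
        )

    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "models").mkdir(exist_ok=True)

    study = simulate_study(
        config.design, config.effects, rating_noise_sd=config.rating_noise_sd
    )
    tables = build_tables(study)

    if outdir is not None:
        study.design.participants.to_csv(outdir / "participants.csv", index=False)
        study.animations.animations.to_csv(outdir / "animations.csv", index=False)
        study.sessions.to_csv(outdir / "sessions.csv", index=False)
        study.ratings.to_csv(outdir / "ratings.csv", index=False)
        if config.write_trajectories:
            study.animations.trajectories.to_csv(
                outdir / "trajectories.csv", index=False
            )
        tables["trials"].to_csv(outdir / "model_table.csv", index=False)
        tables["animation_jerk"].to_csv(outdir / "animation_jerk.csv", index=False)
        tables["jerk_cv"].to_csv(outdir / "jerk_cv.csv", index=False)

    summaries, contrasts_out, diagnostics, fits = {}, {}, {}, {}
    for name in config.models:
        spec = catalogue[name]
        fitted = fit_model(spec, tables[spec.table], config.mcmc)
        fits[name] = fitted
        summaries[name] = fitted.summary_table()
        rows = []
        for label, cells in default_contrasts(name):
            s = contrast(fitted, cells)
            d = s.as_dict()
            d["term"] = label
            rows.append(d)
        contrasts_out[name] = pd.DataFrame(
            rows, columns=["term", "e_mu", "cri_low", "cri_high", "p_negative", "p_positive"]
        )
        diagnostics[name] = {
            "max_rhat": fitted.diagnostics.max_rhat,
            "divergent_transitions": fitted.diagnostics.divergent_transition_count,
            "flagged": fitted.diagnostics.flagged,
        }
        if outdir is not None:
            summaries[name].to_csv(outdir / "models" / f"{name}_summary.csv", index=False)
            contrasts_out[name].to_csv(
                outdir / "models" / f"{name}_contrasts.csv", index=False
            )
            with open(outdir / "models" / f"{name}_diagnostics.json", "w") as fh:
                json.dump(diagnostics[name], fh, indent=2)

    bundle = ReportBundle(
        summaries=summaries,
        contrasts=contrasts_out,
        diagnostics=diagnostics,
        tables=tables,
        provenance=_provenance(config),
        fits=fits,
    )
    if outdir is not None:
        with open(outdir / "report.json", "w") as fh:
            json.dump(bundle.payload(), fh, indent=2)
    return bundle


# --------------------------------------------------------------------------
# real-data ingestion
# --------------------------------------------------------------------------

_REQUIRED_MAPPING = {
    "ratings": ("observer_id", "animation_id"),
    "participants": ("participant_id", "culture", "group"),
    "animations": ("animation_id", "generator_id", "word"),
}


def identity_mapping(words: Sequence[str]) -> dict:
    """Mapping for files already in the package's own CSV dialect."""
    return {
        "ratings": {"observer_id": "observer_id", "animation_id": "animation_id",
                    "words": {w: w for w in words}},
        "participants": {k: k for k in _REQUIRED_MAPPING["participants"]},
        "animations": {k: k for k in _REQUIRED_MAPPING["animations"]},
    }


def ingest_real_data(
    paths: Mapping[str, str],
    mapping: Mapping,
    words: Optional[Sequence[str]] = None,
) -> tuple:
    """Adapt arbitrarily-named deposited CSV files to the canonical tables.

    ``paths`` holds ``ratings``, ``participants`` and ``animations`` CSV
    paths (and optionally ``trajectories`` for the kinematic covariates);
    ``mapping`` maps semantic column names to the file's own columns.
    Returns ``(trials_table, report)`` where the report counts flagged
    (out-of-range) rating rows. Without trajectories the table carries no
    jerk columns.
    """
    words = list(words) if words is not None else list(DesignConfig().words)

    for section, required in _REQUIRED_MAPPING.items():
        sec = mapping.get(section, {})
        missing = [c for c in required if c not in sec]
        if missing:
            raise ConfigurationError(
                f"ingestion mapping for {section!r} lacks column(s): {missing}"
            )
    word_map = mapping["ratings"].get("words")
    if not word_map or set(word_map) != set(words):
        raise ConfigurationError(
            "ingestion mapping for 'ratings' must map all six word columns"
        )

    def _load(section):
        df = pd.read_csv(paths[section])
        sec = mapping[section]
        cols = {k: v for k, v in sec.items() if isinstance(v, str)}
        missing = [v for v in cols.values() if v not in df.columns]
        if missing:
            raise ConfigurationError(
                f"{section} file lacks mapped column(s): {missing}"
            )
        return df.rename(columns={v: k for k, v in cols.items()})

    ratings = _load("ratings")
    ratings = ratings.rename(columns={v: k for k, v in word_map.items()})
    missing_words = [w for w in words if w not in ratings.columns]
    if missing_words:
        raise ConfigurationError(f"ratings file lacks word column(s): {missing_words}")
    participants = _load("participants")[list(_REQUIRED_MAPPING["participants"])]
    animations = _load("animations")[list(_REQUIRED_MAPPING["animations"])]

    vals = ratings[words].to_numpy(float)
    bad = np.isnan(vals).any(axis=1) | (vals < 0).any(axis=1) | (vals > 100).any(axis=1)
    report = {
        "n_rating_rows": int(len(ratings)),
        "n_flagged_out_of_range": int(bad.sum()),
    }
    ratings = ratings.loc[~bad, ["observer_id", "animation_id"] + words].reset_index(drop=True)

    cfg = DesignConfig(words=tuple(words))
    animations = animations.copy()
    animations["condition"] = [cfg.word_condition(w) for w in animations["word"]]

    acc = accuracy_table(ratings, animations, participants, words)
    if "trajectories" in paths and paths["trajectories"]:
        traj = pd.read_csv(paths["trajectories"])
        kin = kinematic_summaries(traj)
        own = observer_word_jerk(kin, animations)
        jd = jerk_difference_table(own, kin, acc[["observer_id", "animation_id", "word"]])
        table = build_model_table(acc, jd)
    else:
        table = acc
    return table, report


# --------------------------------------------------------------------------
# parameter-recovery experiments
# --------------------------------------------------------------------------

def _recovery_spec() -> "ModelSpec":
    """Compact accuracy model matching the simulator's generative structure:
    group factors with interaction plus the jerk-difference covariate,
    crossed random intercepts and a subject slope on generator group,
    mental-state condition only."""
    from .bayes import Covariate, Factor, ModelSpec, PriorSet, RandomTerm
    from .config import GROUPS

    return ModelSpec(
        name="recovery",
        response="accuracy",
        terms=(
            "generator_group", "observer_group",
            "generator_group:observer_group", "jerk_difference",
        ),
        factors={
            "generator_group": Factor("generator_group", GROUPS),
            "observer_group": Factor("observer_group", GROUPS),
        },
        covariates={"jerk_difference": Covariate("jerk_difference")},
        random=(
            RandomTerm("observer_id", intercept=True, slopes=("generator_group",)),
            RandomTerm("animation_id", intercept=True),
        ),
        priors=PriorSet(),
        data_filter="condition == 'mental'",
        table="trials",
    )


def recovery_experiment(
    design: DesignConfig,
    effects: EffectSpec,
    n_replicates: int,
    seed: int = 0,
    settings: Optional[McmcSettings] = None,
    spec=None,
    term: str = "generator_group[aut]",
    true_value: Optional[float] = None,
) -> pd.DataFrame:
    """Simulate-and-refit replicates; record CrI coverage and bias of the
    injected generator-group effect (or any other term).

    Per replicate: simulate a study under ``effects`` with a fresh seed,
    build the model table, fit ``spec`` (default: a compact model matching
    the generative structure), and record the posterior summary of
    ``term``. Errors in a replicate are recorded, not fatal to the batch.
    """
    if n_replicates < 2:
        raise ConfigurationError("n_replicates must be >= 2")
    settings = settings or McmcSettings(chains=4, iterations=1000, warmup=500, seed=seed)
    spec = spec or _recovery_spec()
    if true_value is None:
        true_value = effects.beta_generator_group
    rows = []
    for r in range(n_replicates):
        rep_seed = (int(seed) + 1000003 * (r + 1)) % (2**31 - 1)
        try:
            cfg = DesignConfig(
                n_per_cell=design.n_per_cell,
                words=design.words,
                animations_per_cell=design.animations_per_cell,
                sampling_rate=design.sampling_rate,
                seed=rep_seed,
            )
            study = simulate_study(cfg, effects)
            tables = build_tables(study)
            rep_settings = McmcSettings(
                chains=settings.chains,
                iterations=settings.iterations,
                warmup=settings.warmup,
                seed=rep_seed,
            )
            fitted = fit_model(spec, tables[spec.table], rep_settings)
            s = summarise(fitted, term)
            rows.append(
                {
                    "replicate": r,
                    "seed": rep_seed,
                    "e_mu": s.e_mu,
                    "cri_low": s.cri_low,
                    "cri_high": s.cri_high,
                    "covered": bool(s.cri_low <= true_value <= s.cri_high),
                    "bias": s.e_mu - true_value,
                    "max_rhat": fitted.diagnostics.max_rhat,
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 — batch must survive a replicate
            rows.append(
                {
                    "replicate": r, "seed": rep_seed, "e_mu": np.nan,
                    "cri_low": np.nan, "cri_high": np.nan, "covered": False,
                    "bias": np.nan, "max_rhat": np.nan, "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
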