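# mentkin

Analysis pipeline for cross-cultural, cross-neurotype studies of
bi-directional mentalising with the animations task: participants first
*generate* short animations of two triangles depicting mental-state
(*arguing, surprising, teasing*) and goal-directed (*following, searching,
dancing*) interactions on a touch screen, then *rate* animations generated
by other participants on six 0–100 visual-analogue scales. The package is
aimed at researchers who want to re-run, probe, or power this style of
analysis end to end — including entirely on synthetic data with known
ground truth.

It provides:

- a **synthetic study generator** with the crossed 2 (culture: UK/JP) ×
  2 (group: autistic/non-autistic) design, 60 Hz minimum-jerk trajectories,
  balanced 144-animation rating sessions, and ratings driven by a latent
  linear model with known effects;
- **kinematics**: mean jerk per animation (time-averaged norm of the third
  derivative of position), observer–animation jerk differences matched by
  word, and per-cell jerk variability (coefficient of variation);
- **scoring**: per-trial accuracy `A = rating(target) − mean(ratings(non-targets))`
  and the assembled modelling table;
- **Bayesian crossed random-effects models**: a catalogue of 17 named
  models fit by an exact blocked Gibbs sampler
  (`y = Xβ + Σ_g Z_g u_g + ε` with normal coefficient priors and
  half-Cauchy sds), reporting Eμ, equal-tailed 95% CrIs, P(Eμ<0)/P(Eμ>0),
  Savage-Dickey Bayes factors, PSIS-LOO comparisons and emmeans-style
  contrasts;
- a **CLI** (`mentkin simulate|kinematics|score|fit|contrast|report|recover|ingest`)
  and a mapping-driven ingestion path for deposited real-data CSVs.

## Worked example

```python
import mentkin as mk
from mentkin.bayes import fit, summarise, contrast

# a synthetic study: 8 participants per culture x group cell, with a
# -8-point generator-group effect and a -2/SD jerk-difference effect
cfg = mk.DesignConfig(n_per_cell=8, seed=21)
study = mk.simulate_study(cfg, mk.EffectSpec())
tables = mk.build_tables(study)

spec = mk.model_catalogue()["UK.1"]   # accuracy ~ gen group * obs group,
                                      # UK mental-state trials, crossed REs
fitted = fit(spec, tables["trials"], mk.McmcSettings(seed=1))
print(summarise(fitted, "generator_group[aut]"))
```

```
PosteriorSummary(term='generator_group[aut]', e_mu=-0.634,
                 cri_low=-7.805, cri_high=6.397,
                 p_negative=0.574, p_positive=0.426)
```

`e_mu` is the posterior mean of the accuracy difference (score units)
between animations generated by autistic vs non-autistic participants, for
non-autistic observers (the reference level of the dummy-coded observer
factor); the interval is the equal-tailed 95% credible interval and
`p_negative` the posterior probability the effect is below zero. In this
particular simulated study the realized effect in the small UK mental-state
subset happens to be near zero even though −8 was injected — single small
studies are noisy, which is exactly what the package's recovery machinery
quantifies:

```python
rec = mk.recovery_experiment(cfg, mk.EffectSpec(), n_replicates=20, seed=0)
print(rec["covered"].mean(), rec["bias"].mean())   # 0.95, +1.15
```

i.e. across 20 simulated replicates the 95% CrI covers the injected −8 in
19, with a ~1-point attenuation from the weakly informative coefficient
prior.

The same machinery runs from the shell:

```bash
mentkin fit --config study.yaml --seed 1 --outdir out/
mentkin report --outdir out/
```

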