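# Methods

## The task and the quantities modelled

The package analyses a two-phase "animations" mentalising paradigm. In the
generation phase, each participant moves two triangles across a touch
screen to depict six words — three mental-state interactions (*arguing,
surprising, teasing*) and three goal-directed ones (*following, searching,
dancing*) — producing one animation per word, with the triangles' positions
recorded at 60 Hz. In the rating phase, each participant (now an observer)
views 144 animations made by the other participants — six per word ×
generator group (autistic / non-autistic) × generator culture (UK / JP) —
and rates on 0–100 visual-analogue scales how well each of the six words
describes what they saw.

Three derived quantities drive the analysis:

- **Accuracy** `A` of a trial: the rating of the target word minus the mean
  rating of the five non-target words (range −100…100). Adding a constant
  to all six ratings leaves `A` unchanged.
- **Mean jerk** `J` of an animation: the time-averaged Euclidean norm of
  the third time-derivative of each triangle's position, averaged over the
  two triangles. Jerk indexes movement smoothness; it is invariant to
  translation and scales linearly with spatial scale.
- **Jerk difference** `ΔJ` of a trial: |J of the observer's own animation
  of the trial's word − J of the rated animation| — an inverse index of
  observer–agent kinematic similarity. **Jerk variability** is the
  coefficient of variation (sample sd / mean) of generator-level mean jerk
  within each culture × group × word cell, six values per culture × group.

## The synthetic-data generator

The generator exists so that every downstream stage is testable without any
data download. Its defaults encode the study conditions: a crossed
2 (culture) × 2 (group) design, six words in two triads, 60 Hz trajectories,
144 rated animations per observer with observers never rating their own
animations, and group-dependent jerk distributions.

**Trajectories** are chains of minimum-jerk submovements: each triangle
executes `n_submovements` segments whose position profile follows the
minimum-jerk polynomial 10τ³ − 15τ⁴ + 6τ⁵ with random displacement vectors,
plus optional white positional noise, clipped to the unit square (screen
coordinates are normalised to [0,1]², pixel dimensions abstracted away).
At fixed duration, mean jerk grows with submovement count (each segment's
jerk scales as amplitude/duration³), so jerk level is controlled by the
submovement count and amplitude. Defaults: 5 s duration, 8 submovements,
amplitude sd 0.15 screen units, no noise. Real finger trajectories differ
from this model in many ways (pauses, drift, digitisation artefacts,
semantic structure); passing tests therefore certify the pipeline's
arithmetic and statistical machinery, not any claim about real movement.

**Inter-subject jerk dispersion** is controlled per cell by a lognormal
multiplier on submovement amplitude (`jerk_level_log_sd`); because mean
jerk is linear in amplitude, this directly sets the between-generator jerk
CV. Defaults give every cell the same expected jerk (the study found no
group difference in mean jerk) and double the spread in the UK-autistic
cell (the study found elevated jerk variability there): log-sd 0.5 vs 0.25.

**Ratings** are generated from a latent trial accuracy

    A = baseline + β_gen·[gen=aut] + β_obs·[obs=aut] + β_int·[both aut]
        + β_mental·[mental] + β_jerk·z(ΔJ) + u_subject + v_animation
        + s_subject·[gen=aut] + ε

with Gaussian random effects and residual. Default effect sizes (score
units): baseline 15, generator group −8, observer group 0, interaction 3,
jerk difference −2 per SD, subject/animation intercept sds 8/10, subject
slope sd 3, residual sd 25 — magnitudes chosen to be of the order reported
for this paradigm. The six ratings are then constructed symmetrically
around the scale midpoint — target 50 + A/2, each non-target 50 − A/2 —
so the accuracy statistic recovers the latent value *exactly* in the
noise-free case, before clipping to [0,100]. Four RNG streams (design,
trajectories, sessions, ratings) all derive from the study seed, so phases
can be re-run modularly and identical seeds give byte-identical studies.

## Kinematics

Derivatives are repeated central finite differences on position; each pass
trims one sample at each end. For polynomials up to degree three the
estimator is exact up to floating point (the t³ oracle returns 6 to within
1e−13); for smooth non-polynomial signals the truncation error is O(h²).
An optional zero-phase 2nd-order Butterworth low-pass (configurable cutoff,
off by default) can be applied to position before differentiating, since
third derivatives amplify high-frequency noise; synthetic trajectories are
smooth so tests run unsmoothed. "Mean jerk" uses derivative magnitudes
(norm of the 2-D jerk vector per sample), never signed components, so it is
a non-negative intensity; the two triangles are weighted equally.

z-standardisation of ΔJ is computed within the dataset entering each model
(e.g. the UK-only subset for within-UK models), with the transform's
mean/sd recorded on the fit object. This matches per-model fitting; it also
means a coefficient's per-SD scale differs slightly between models fit to
different subsets.

## The Bayesian engine

All models are Gaussian linear mixed models with crossed random effects:

    y = Xβ + Σ_g Z_g u_g + ε,  ε ~ N(0, σ²),  u_g ~ N(0, τ_g² I)

with priors β_j ~ N(m_j, s_j²) and half-Cauchy(0, scale) on every sd.
Sampling is a blocked Gibbs scheme: the joint coefficient vector (β, u) has
a multivariate normal full conditional (drawn via Cholesky of the
precision), and the half-Cauchy scales are updated through their
inverse-gamma scale-mixture representation, so every update is an exact
conditional draw. Determinism: each chain's RNG derives from
(seed, chain index); identical settings reproduce draws bit-identically.

Design choices:

- **Independent random-effect blocks.** Each grouping-factor × coefficient
  combination has its own variance; slope–intercept correlations are not
  modelled (the `||` parameterisation). This keeps every conditional
  conjugate and exact; the cost is that correlation between intercepts and
  slopes, if present, is absorbed into the block variances.
- **Identifiable slopes only.** A random slope for a predictor that is
  constant within every level of a grouping factor (e.g. generator group
  within an animation) is confounded with that factor's intercept; the
  model catalogue therefore declares slopes only for terms that vary
  within the grouping factor.
- **Priors.** Coefficients N(0, 10) on the response scale, intercept
  N(0, 50), sds half-Cauchy(0, 5); all config-exposed. The jerk-difference
  coefficient carries an informative prior, N(−2.5, 1.5) by default, whose
  centre/scale must be supplied explicitly (`model_catalogue(jerk_diff_prior=…)`)
  because the value is carried over from earlier studies of the paradigm
  rather than derivable here. Note the N(0, 10) coefficient prior shrinks
  an effect of size ≈8 by roughly 10–15% when its posterior se is ≈3–4;
  recovery experiments show this as a ~1-point attenuation of the
  generator-group effect with nominal CrI coverage (19/20 at two seeds).
- **Convergence.** Split-R-hat is computed for every fixed effect and sd
  (via arviz); any value above 1.01 raises a visible warning and is flagged
  in the report, never silently discarded. The Gibbs scheme has no
  divergence diagnostic (there is no trajectory integrator); the divergence
  count is reported as 0 by construction. Variance components whose
  posterior piles up near zero (typically unneeded random-slope sds) mix
  slowly — R-hat 1.02–1.06 at the default 4 × 4000 iterations — while
  fixed effects sit at 1.00; longer chains are cheap (seconds) if a clean
  gate is needed.
- **Summaries.** Eμ is the posterior mean; CrIs are equal-tailed 2.5/97.5%
  quantiles (not HPD); P(Eμ<0)/P(Eμ>0) are pooled tail fractions.
  Savage-Dickey BF01 = (Gaussian-KDE posterior density at 0, Silverman
  bandwidth) / (prior density at 0), with a floor flag when the posterior
  density at 0 underflows. Contrasts are emmeans-style: cell means on the
  fixed-effect scale with unmentioned factors averaged with equal weights
  and covariates held at 0 on the model (z) scale, evaluated per draw. LOO
  uses PSIS importance sampling (arviz) on stored pointwise
  log-likelihoods; storing them is opt-in because memory scales with
  n × draws.

## The model catalogue

Seventeen named models: within-culture UK.1–UK.5 and JP.1–JP.5 (accuracy as
response; group factors, condition, and jerk difference in the combinations
described in the analysis), and cross-culture JPUK.1–JPUK.7. All factor
codings are explicit: dummy coding with non-autistic / mental / UK as
reference levels; the six-word factor in JPUK.5/6 uses deviation contrasts
(each word vs the grand mean, reference *dancing* omitted). JPUK.4–6 are
fit to per-animation mean jerk, z-standardised before fitting because raw
screen-unit jerk magnitudes are arbitrary; JPUK.7 is fit to the 24
jerk-CV values with a random intercept for word and tighter priors
(coefficients N(0,2), sds half-Cauchy(0,1)) matching the CV's unit scale.
Within-culture models filter to trials where observer and generator share
the culture; JPUK.3 filters to autistic observers rating autistic-generated
animations.

## Problem sizes and tolerances

Tests and the acceptance script run reduced designs chosen to exercise
every code path at desk scale: 4 participants per cell with 2 animations
per word-cell for unit tests; 8 per cell (4,608 trials, 2,304 mental-state)
for inference checks; the full 15-per-cell design for pure counting checks.
Parameter recovery uses 20 simulate-and-refit replicates at 8 per cell with
4 × 1200 Gibbs iterations per fit; conjugate oracles use fixed residual sd
so closed-form posteriors are exact; the Savage-Dickey conjugate check
allows 10% relative error (KDE bias at moderate tail positions); brute-force
LOO (n refits at n = 30) must agree with PSIS-LOO within 2 SE.

## Known limitations

- The trajectory model is a phenomenological stand-in; no claim is made
  that its jerk distribution matches real finger movements beyond the
  controllable group structure.
- Random-effect correlations are not modelled (see above).
- Only Gaussian responses are supported; no location–scale models, no
  cross-validation schemes beyond LOO.
- Real-data ingestion is mapping-driven and computes the same statistics,
  but the deposited files' layout must be described in a mapping config;
  nothing is hard-coded and no download is attempted.
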