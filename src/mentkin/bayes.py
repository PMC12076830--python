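"""Bayesian Gaussian crossed random-effects models.

The model is a linear regression of a continuous response with crossed
Gaussian random intercepts and slopes::

    y = X beta + sum_g Z_g u_g + eps,   eps ~ N(0, sigma^2 I),
    u_g ~ N(0, tau_g^2 I),  beta_j ~ N(m_j, s_j^2),
    tau_g, sigma ~ half-Cauchy(0, scale).

Sampling is by a blocked Gibbs scheme: the joint coefficient vector
(beta, u) has a multivariate-normal full conditional, and the half-Cauchy
scales are handled through their inverse-gamma scale-mixture
representation, so every update is an exact conditional draw (there is no
step-size tuning and no divergence diagnostic; convergence is monitored
with split-R-hat). Random-effect blocks are independent — each grouping
factor x coefficient combination has its own variance and no
slope-intercept correlation is modelled.

Reported quantities are pure functions of the stored draws: posterior
means, equal-tailed 95% credible intervals, directional posterior
probabilities, Savage-Dickey density ratios, emmeans-style cell-mean
contrasts, and PSIS-LOO model comparison (via arviz).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "Factor",
    "Covariate",
    "RandomTerm",
    "PriorSet",
    "ModelSpec",
    "PosteriorSummary",
    "BayesFactorResult",
    "ConvergenceDiagnostics",
    "ModelFit",
    "build_design_matrices",
    "fit",
    "summarise",
    "contrast",
    "savage_dickey",
    "loo",
    "loo_compare",
]


class ModelSpecError(ValueError):
    pass


# --------------------------------------------------------------------------
# declarative model description
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Factor:
    """A categorical predictor with explicit coding.

    ``dummy``: one indicator column per non-reference level (0 at the
    reference level). ``deviation``: k-1 columns comparing each
    non-reference level to the grand mean (+1 at the level, -1 at the
    omitted reference level, 0 elsewhere; columns sum to 0 over levels).
    """

    name: str
    levels: tuple
    reference: Optional[str] = None
    coding: str = "dummy"

    def __post_init__(self):
        ref = self.reference if self.reference is not None else self.levels[0]
        if ref not in self.levels:
            raise ModelSpecError(f"reference {ref!r} not a level of {self.name}")
        object.__setattr__(self, "reference", ref)
        if self.coding not in ("dummy", "deviation"):
            raise ModelSpecError(f"unknown coding {self.coding!r}")

    def column_names(self) -> list:
        tag = "" if self.coding == "dummy" else "dev:"
        return [f"{self.name}[{tag}{lvl}]" for lvl in self.levels if lvl != self.reference]

    def encode(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values)
        unseen = set(np.unique(values)) - set(self.levels)
        if unseen:
            raise ModelSpecError(f"unseen level(s) of {self.name}: {sorted(unseen)}")
        cols = []
        for lvl in self.levels:
            if lvl == self.reference:
                continue
            col = (values == lvl).astype(float)
            if self.coding == "deviation":
                col = col - (values == self.reference).astype(float)
            cols.append(col)
        return np.column_stack(cols)


@dataclass(frozen=True)
class Covariate:
    """A continuous predictor; standardized covariates are z-scored within
    the dataset entering the model (mean/sd recorded on the fit)."""

    name: str
    standardize: bool = True


@dataclass(frozen=True)
class RandomTerm:
    """Random effects varying by ``group``: an intercept and/or slopes for
    the listed fixed terms. Each resulting coefficient column is an
    independent block with its own half-Cauchy sd."""

    group: str
    intercept: bool = True
    slopes: tuple = ()


@dataclass(frozen=True)
class PriorSet:
    """Normal priors for coefficients, half-Cauchy for all sds.

    ``informative`` maps a design-column (or covariate) name to a
    (mean, scale) normal prior, e.g. the informative jerk-difference prior
    carried over from earlier studies of the same task.
    """

    coefficient_scale: float = 10.0
    intercept_scale: float = 50.0
    sd_scale: float = 5.0
    informative: Mapping[str, tuple] = field(default_factory=dict)

    def coefficient_prior(self, column: str) -> tuple:
        if column in self.informative:
            return tuple(self.informative[column])
        if column == "Intercept":
            return (0.0, self.intercept_scale)
        return (0.0, self.coefficient_scale)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model.

    ``terms`` are ':'-joined products of factor/covariate names (main
    effects are single names). ``data_filter`` is a pandas query string
    applied before fitting. ``table`` names which canonical table the model
    consumes ("trials", "animation_jerk" or "jerk_cv").
    """

    name: str
    response: str
    terms: tuple
    factors: Mapping[str, Factor] = field(default_factory=dict)
    covariates: Mapping[str, Covariate] = field(default_factory=dict)
    random: tuple = ()
    priors: PriorSet = field(default_factory=PriorSet)
    data_filter: Optional[str] = None
    table: str = "trials"
    standardize_response: bool = False


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------

def _encode_component(spec: ModelSpec, name: str, df: pd.DataFrame):
    if name in spec.factors:
        fac = spec.factors[name]
        return fac.column_names(), fac.encode(df[name].to_numpy())
    if name in spec.covariates:
        return [name], df[name].to_numpy(float)[:, None]
    raise ModelSpecError(f"term component {name!r} is neither a declared factor nor covariate")


def _encode_term(spec: ModelSpec, term: str, df: pd.DataFrame):
    names, mat = None, None
    for comp in term.split(":"):
        cn, cm = _encode_component(spec, comp, df)
        if names is None:
            names, mat = cn, cm
        else:
            names = [f"{a}:{b}" for a in names for b in cn]
            mat = (mat[:, :, None] * cm[:, None, :]).reshape(len(df), -1)
    return names, mat


def build_fixed_matrix(spec: ModelSpec, df: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect design matrix with an intercept column; covariate
    columns in ``df`` must already be on the model (standardized) scale."""
    cols = {"Intercept": np.ones(len(df))}
    for term in spec.terms:
        names, mat = _encode_term(spec, term, df)
        for j, name in enumerate(names):
            if name in cols:
                raise ModelSpecError(f"duplicate design column {name!r}")
            cols[name] = mat[:, j]
    return pd.DataFrame(cols, index=df.index)


@dataclass
class RandomBlock:
    label: str  # e.g. "observer_id:Intercept" or "observer_id:gen_group[aut]"
    group: str
    level_index: np.ndarray  # (n,) int
    weights: np.ndarray  # (n,)
    n_levels: int


@dataclass
class DesignMatrices:
    X: pd.DataFrame
    blocks: list
    y: np.ndarray
    standardization: dict


def prepare_table(spec: ModelSpec, table: pd.DataFrame):
    """Filter rows and put covariates/response on the model scale."""
    df = table.query(spec.data_filter).copy() if spec.data_filter else table.copy()
    if len(df) == 0:
        raise ModelSpecError(f"data_filter {spec.data_filter!r} leaves no rows")
    standardization = {}
    for cov in spec.covariates.values():
        if cov.standardize:
            vals = df[cov.name].to_numpy(float)
            m, s = vals.mean(), vals.std(ddof=1)
            if s == 0:
                raise ModelSpecError(f"covariate {cov.name!r} is constant; cannot z-score")
            df[cov.name] = (vals - m) / s
            standardization[cov.name] = (m, s)
    if spec.standardize_response:
        vals = df[spec.response].to_numpy(float)
        m, s = vals.mean(), vals.std(ddof=1)
        df[spec.response] = (vals - m) / s
        standardization[spec.response] = (m, s)
    return df, standardization


def build_design_matrices(spec: ModelSpec, table: pd.DataFrame) -> DesignMatrices:
    df, standardization = prepare_table(spec, table)
    X = build_fixed_matrix(spec, df)
    blocks = []
    for rt in spec.random:
        if rt.group not in df.columns:
            raise ModelSpecError(f"grouping factor {rt.group!r} not in table")
        levels, idx = np.unique(df[rt.group].to_numpy(), return_inverse=True)
        if rt.intercept:
            blocks.append(
                RandomBlock(
                    label=f"{rt.group}:Intercept",
                    group=rt.group,
                    level_index=idx,
                    weights=np.ones(len(df)),
                    n_levels=levels.size,
                )
            )
        for slope_term in rt.slopes:
            names, mat = _encode_term(spec, slope_term, df)
            for j, name in enumerate(names):
                blocks.append(
                    RandomBlock(
                        label=f"{rt.group}:{name}",
                        group=rt.group,
                        level_index=idx,
                        weights=mat[:, j].astype(float),
                        n_levels=levels.size,
                    )
                )
    y = df[spec.response].to_numpy(float)
    return DesignMatrices(X=X, blocks=blocks, y=y, standardization=standardization), df


# --------------------------------------------------------------------------
# Gibbs sampler
# --------------------------------------------------------------------------

def _dense_w(dm: DesignMatrices) -> np.ndarray:
    n = len(dm.y)
    parts = [dm.X.to_numpy(float)]
    for b in dm.blocks:
        Z = np.zeros((n, b.n_levels))
        Z[np.arange(n), b.level_index] = b.weights
        parts.append(Z)
    return np.concatenate(parts, axis=1)


def _inv_gamma(rng, shape: float, rate: float) -> float:
    return 1.0 / rng.gamma(shape, 1.0 / rate)


def _run_chain(
    y,
    W,
    WtW,
    Wty,
    prior_mean,
    fixed_prior_prec,
    block_slices,
    sd_scale,
    settings,
    rng,
    sigma_fixed=None,
    store_log_lik=False,
):
    n, d = W.shape
    p = fixed_prior_prec.size
    n_blocks = len(block_slices)
    keep = settings.iterations - settings.warmup

    theta = np.zeros(d)
    sigma2 = max(float(np.var(y)), 1e-6) if sigma_fixed is None else float(sigma_fixed) ** 2
    tau2 = np.ones(n_blocks)
    a_sigma = 1.0
    a_tau = np.ones(n_blocks)

    coef_out = np.empty((keep, p))
    sd_out = np.empty((keep, n_blocks + 1))
    ll_out = np.empty((keep, n), dtype=np.float32) if store_log_lik else None

    prec = np.empty(d)
    prior_rhs = np.zeros(d)
    for it in range(settings.iterations):
        prec[:p] = fixed_prior_prec
        for b, sl in enumerate(block_slices):
            prec[sl] = 1.0 / tau2[b]
        prior_rhs[:p] = fixed_prior_prec * prior_mean
        Q = WtW / sigma2
        Q[np.diag_indices_from(Q)] += prec
        rhs = Wty / sigma2 + prior_rhs
        L = linalg.cholesky(Q, lower=True)
        mu = linalg.cho_solve((L, True), rhs)
        z = rng.standard_normal(d)
        theta = mu + linalg.solve_triangular(L, z, lower=True, trans="T")

        resid = y - W @ theta
        rss = float(resid @ resid)
        if sigma_fixed is None:
            sigma2 = _inv_gamma(rng, 0.5 * (n + 1), 0.5 * rss + 1.0 / a_sigma)
            a_sigma = _inv_gamma(rng, 1.0, 1.0 / sd_scale**2 + 1.0 / sigma2)
        for b, sl in enumerate(block_slices):
            u = theta[sl]
            k = u.size
            tau2[b] = _inv_gamma(rng, 0.5 * (k + 1), 0.5 * float(u @ u) + 1.0 / a_tau[b])
            a_tau[b] = _inv_gamma(rng, 1.0, 1.0 / sd_scale**2 + 1.0 / tau2[b])

        j = it - settings.warmup
        if j >= 0:
            coef_out[j] = theta[:p]
            sd_out[j, :n_blocks] = np.sqrt(tau2)
            sd_out[j, n_blocks] = np.sqrt(sigma2)
            if store_log_lik:
                ll_out[j] = -0.5 * (np.log(2.0 * np.pi * sigma2) + resid**2 / sigma2)
    return coef_out, sd_out, ll_out


# --------------------------------------------------------------------------
# fit object and reporting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorSummary:
    term: str
    e_mu: float
    cri_low: float
    cri_high: float
    p_negative: float
    p_positive: float

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "e_mu": self.e_mu,
            "cri_low": self.cri_low,
            "cri_high": self.cri_high,
            "p_negative": self.p_negative,
            "p_positive": self.p_positive,
        }


@dataclass(frozen=True)
class BayesFactorResult:
    term: str
    bf01: float
    posterior_density_at_zero: float
    prior_density_at_zero: float
    floored: bool = False


@dataclass(frozen=True)
class ConvergenceDiagnostics:
    rhat: Mapping[str, float]
    divergent_transition_count: int = 0

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    @property
    def flagged(self) -> bool:
        return self.divergent_transition_count > 0 or self.max_rhat > 1.01


class ModelFit:
    """Posterior draws plus everything needed to re-summarise them."""

    def __init__(
        self,
        spec,
        settings,
        coef_names,
        coef_draws,
        sd_names,
        sd_draws,
        data,
        standardization,
        log_lik=None,
    ):
        self.spec = spec
        self.settings = settings
        self.coef_names = list(coef_names)
        self.coef_draws = coef_draws  # (chains, keep, p)
        self.sd_names = list(sd_names)
        self.sd_draws = sd_draws  # (chains, keep, q+1)
        self.data = data
        self.standardization = standardization
        self.log_lik = log_lik  # (chains, keep, n) or None
        self.diagnostics = self._diagnose()

    # -- draws access ------------------------------------------------------
    def _posterior_dict(self) -> dict:
        out = {n: self.coef_draws[:, :, j] for j, n in enumerate(self.coef_names)}
        out.update({n: self.sd_draws[:, :, j] for j, n in enumerate(self.sd_names)})
        return out

    def draws(self, term: str) -> np.ndarray:
        """Pooled post-warmup draws of one parameter."""
        if term in self.coef_names:
            return self.coef_draws[:, :, self.coef_names.index(term)].reshape(-1)
        if term in self.sd_names:
            return self.sd_draws[:, :, self.sd_names.index(term)].reshape(-1)
        raise ModelSpecError(
            f"unknown term {term!r}; available: {self.coef_names + self.sd_names}"
        )

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def _diagnose(self) -> ConvergenceDiagnostics:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.rhat(az.from_dict(posterior=self._posterior_dict()))
        rhat = {k: float(ds[k].values) for k in ds.data_vars}
        diag = ConvergenceDiagnostics(rhat=rhat, divergent_transition_count=0)
        if diag.flagged:
            warnings.warn(
                f"model {self.spec.name}: max split-Rhat {diag.max_rhat:.3f} > 1.01 — "
                "treat summaries with caution",
                stacklevel=2,
            )
        return diag

    def to_inference_data(self) -> az.InferenceData:
        kwargs = {"posterior": self._posterior_dict()}
        if self.log_lik is not None:
            kwargs["log_likelihood"] = {"y": self.log_lik.astype(float)}
        return az.from_dict(**kwargs)

    # -- reporting ---------------------------------------------------------
    def summary_table(self) -> pd.DataFrame:
        rows = [summarise(self, t).as_dict() for t in self.coef_names + self.sd_names]
        return pd.DataFrame(rows)


def fit(
    spec: ModelSpec,
    table: pd.DataFrame,
    settings,
    store_log_lik: bool = False,
    sigma_fixed: Optional[float] = None,
) -> ModelFit:
    """Fit one model by blocked Gibbs sampling.

    ``sigma_fixed`` pins the residual sd to a known value (used for
    conjugate-case validation); ``store_log_lik`` keeps the pointwise
    log-likelihood needed for LOO (memory scales with n x draws).
    """
    dm, df = build_design_matrices(spec, table)
    W = _dense_w(dm)
    n, d = W.shape
    p = dm.X.shape[1]
    WtW = W.T @ W
    Wty = W.T @ dm.y

    prior_mean = np.zeros(p)
    fixed_prior_prec = np.empty(p)
    for j, col in enumerate(dm.X.columns):
        m, s = spec.priors.coefficient_prior(col)
        prior_mean[j] = m
        fixed_prior_prec[j] = 1.0 / s**2

    block_slices = []
    start = p
    for b in dm.blocks:
        block_slices.append(slice(start, start + b.n_levels))
        start += b.n_levels

    coef_chains, sd_chains, ll_chains = [], [], []
    for chain in range(settings.chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(settings.seed), chain]))
        coefs, sds, ll = _run_chain(
            dm.y, W, WtW, Wty, prior_mean, fixed_prior_prec, block_slices,
            spec.priors.sd_scale, settings, rng,
            sigma_fixed=sigma_fixed, store_log_lik=store_log_lik,
        )
        coef_chains.append(coefs)
        sd_chains.append(sds)
        ll_chains.append(ll)

    sd_names = [f"sd({b.label})" for b in dm.blocks] + ["sigma"]
    return ModelFit(
        spec=spec,
        settings=settings,
        coef_names=list(dm.X.columns),
        coef_draws=np.stack(coef_chains),
        sd_names=sd_names,
        sd_draws=np.stack(sd_chains),
        data=df,
        standardization=dm.standardization,
        log_lik=np.stack(ll_chains) if store_log_lik else None,
    )


def summarise(fit_or_draws, term: Optional[str] = None) -> PosteriorSummary:
    """Posterior mean, equal-tailed 95% CrI and directional probabilities."""
    if isinstance(fit_or_draws, ModelFit):
        draws = fit_or_draws.draws(term)
        name = term
    else:
        draws = np.asarray(fit_or_draws, float).reshape(-1)
        name = term or "term"
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return PosteriorSummary(
        term=name,
        e_mu=float(draws.mean()),
        cri_low=float(lo),
        cri_high=float(hi),
        p_negative=float(np.mean(draws < 0)),
        p_positive=float(np.mean(draws > 0)),
    )


# --------------------------------------------------------------------------
# contrasts (emmeans-style cell means)
# --------------------------------------------------------------------------

def _cell_fixed_row(fitted: ModelFit, assignment: Mapping, covariate_values: Mapping) -> np.ndarray:
    """Fixed-effect row of a cell mean: mentioned factors at their given
    levels, unmentioned factors averaged with equal cell weights,
    covariates at 0 on the model scale unless overridden."""
    spec = fitted.spec
    for fname, lvl in assignment.items():
        if fname not in spec.factors:
            raise ModelSpecError(f"{fname!r} is not a factor of model {spec.name}")
        if lvl not in spec.factors[fname].levels:
            raise ModelSpecError(f"{lvl!r} is not a level of factor {fname!r}")
    free = [f for f in spec.factors if f not in assignment]
    grids = itertools.product(*[spec.factors[f].levels for f in free]) if free else [()]
    rows = []
    for combo in grids:
        rec = dict(assignment)
        rec.update(dict(zip(free, combo)))
        for cov in spec.covariates:
            rec[cov] = covariate_values.get(cov, 0.0)
        one = pd.DataFrame([rec])
        rows.append(build_fixed_matrix(spec, one).to_numpy(float)[0])
    row = np.mean(rows, axis=0)
    return row


def contrast(
    fitted: ModelFit,
    cells: Sequence[tuple],
    covariate_values: Optional[Mapping] = None,
) -> PosteriorSummary:
    """Posterior of a linear combination of cell means.

    ``cells`` is a sequence of ``(weight, {factor: level, ...})``; factors
    not mentioned in a cell are averaged over with equal weights, and
    covariates are held at 0 on the model scale (override via
    ``covariate_values``). A pairwise contrast is
    ``[(1, {...}), (-1, {...})]``.
    """
    covariate_values = covariate_values or {}
    vec = np.zeros(len(fitted.coef_names))
    labels = []
    for weight, assignment in cells:
        vec += weight * _cell_fixed_row(fitted, assignment, covariate_values)
        labels.append(
            f"{weight:+g}*(" + ",".join(f"{k}={v}" for k, v in assignment.items()) + ")"
        )
    pooled = fitted.coef_draws.reshape(-1, len(fitted.coef_names))
    values = pooled @ vec
    return summarise(values, " ".join(labels))


# --------------------------------------------------------------------------
# Savage-Dickey, LOO
# --------------------------------------------------------------------------

BF01_FLOOR = 1e-10


def savage_dickey(fitted: ModelFit, term: str) -> BayesFactorResult:
    """Savage-Dickey density ratio BF01 for a point null at 0.

    Posterior density at 0 via a Gaussian kernel density (Silverman
    bandwidth) over the pooled draws; prior density from the term's normal
    prior. BF01 > 1 favours the model without the effect.
    """
    draws = fitted.draws(term)
    m, s = fitted.spec.priors.coefficient_prior(term)
    prior_at_zero = float(stats.norm.pdf(0.0, loc=m, scale=s))
    post_at_zero = float(stats.gaussian_kde(draws)(0.0)[0])
    floored = False
    if not np.isfinite(post_at_zero) or post_at_zero <= BF01_FLOOR * prior_at_zero:
        floored = True
        bf01 = BF01_FLOOR
    else:
        bf01 = post_at_zero / prior_at_zero
    return BayesFactorResult(
        term=term,
        bf01=bf01,
        posterior_density_at_zero=post_at_zero,
        prior_density_at_zero=prior_at_zero,
        floored=floored,
    )


def loo(fitted: ModelFit):
    """PSIS leave-one-out expected log predictive density (arviz)."""
    if fitted.log_lik is None:
        raise ModelSpecError(
            f"model {fitted.spec.name} was fit without store_log_lik=True"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return az.loo(fitted.to_inference_data(), pointwise=True)


def loo_compare(fits: Mapping[str, ModelFit]) -> pd.DataFrame:
    """Pairwise LOO comparison of models fit to the same response rows.

    Returns one row per model with elpd_loo, its SE, and the elpd
    difference to the best model with the SE of that difference.
    """
    items = list(fits.items())
    ref_y = items[0][1].data[items[0][1].spec.response].to_numpy(float)
    for name, f in items[1:]:
        y = f.data[f.spec.response].to_numpy(float)
        if y.shape != ref_y.shape or not np.allclose(y, ref_y):
            raise ModelSpecError(
                f"model {name!r} is fit to different data than {items[0][0]!r}"
            )
    loos = {name: loo(f) for name, f in items}
    elpd_i = {name: np.asarray(l.loo_i.values, float) for name, l in loos.items()}
    best = max(loos, key=lambda n: float(loos[n].elpd_loo))
    rows = []
    n = ref_y.size
    for name, l in loos.items():
        diff_i = elpd_i[name] - elpd_i[best]
        rows.append(
            {
                "model": name,
                "elpd_loo": float(l.elpd_loo),
                "se": float(l.se),
                "elpd_diff": float(diff_i.sum()),
                "diff_se": float(np.sqrt(n * np.var(diff_i, ddof=0))),
                "p_loo": float(l.p_loo),
            }
        )
    out = pd.DataFrame(rows).sort_values("elpd_loo", ascending=False).reset_index(drop=True)
    return out
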