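"""Inference engine tests: codings, conjugate oracles, contrasts,
Savage-Dickey ratios, LOO, and the model catalogue."""
import numpy as np
import pandas as pd
import pytest

import mentkin as mk
from mentkin.bayes import (
    Covariate,
    Factor,
    ModelFit,
    ModelSpec,
    ModelSpecError,
    PriorSet,
    RandomTerm,
    build_fixed_matrix,
    contrast,
    fit,
    loo,
    loo_compare,
    savage_dickey,
    summarise,
)
from mentkin.catalogue import model_catalogue
from scipy import stats

LIGHT = mk.McmcSettings(chains=2, iterations=800, warmup=300, seed=1)


class TestCodings:
    def _spec(self, coding="dummy"):
        return ModelSpec(
            name="m",
            response="y",
            terms=("g", "w", "g:w"),
            factors={
                "g": Factor("g", ("a", "b")),
                "w": Factor(
                    "w", ("w1", "w2", "w3", "w4", "w5", "w6"),
                    reference="w6", coding=coding,
                ),
            },
        )

    def test_dummy_reference_rows_are_zero(self):
        spec = self._spec()
        df = pd.DataFrame({"g": ["a", "b"], "w": ["w6", "w1"]})
        X = build_fixed_matrix(spec, df)
        assert X.loc[0, "g[b]"] == 0.0
        assert X.loc[0, [c for c in X if c.startswith("w[")]].eq(0).all()

    def test_deviation_columns_sum_to_zero_over_levels(self):
        spec = self._spec(coding="deviation")
        df = pd.DataFrame({"g": ["a"] * 6, "w": [f"w{i}" for i in range(1, 7)]})
        X = build_fixed_matrix(spec, df)
        dev_cols = [c for c in X if c.startswith("w[dev:")]
        assert len(dev_cols) == 5
        assert np.allclose(X[dev_cols].sum(axis=0), 0.0)
        # omitted level row is -1 everywhere
        assert (X.loc[5, dev_cols] == -1.0).all()

    def test_interaction_is_elementwise_product(self):
        spec = self._spec()
        df = pd.DataFrame({"g": ["a", "b", "b"], "w": ["w1", "w6", "w1"]})
        X = build_fixed_matrix(spec, df)
        assert X["g[b]:w[w1]"].tolist() == [0.0, 0.0, 1.0]

    def test_unseen_level_rejected(self):
        spec = self._spec()
        df = pd.DataFrame({"g": ["zzz"], "w": ["w1"]})
        with pytest.raises(ModelSpecError, match="unseen level"):
            build_fixed_matrix(spec, df)


class TestConjugateOracle:
    def test_intercept_posterior_matches_closed_form(self):
        # y ~ N(mu, 1) with known sigma and a N(0, 10^2) prior is conjugate
        rng = np.random.default_rng(7)
        y = rng.normal(5.0, 1.0, 500)
        spec = ModelSpec(name="c", response="y", terms=(),
                         priors=PriorSet(intercept_scale=10.0))
        f = fit(spec, pd.DataFrame({"y": y}),
                mk.McmcSettings(chains=4, iterations=2000, warmup=500, seed=3),
                sigma_fixed=1.0)
        post_prec = y.size + 1.0 / 100.0
        analytic_mean = y.sum() / post_prec
        draws = f.draws("Intercept")
        ess = 6000  # 4 chains x 1500 independent conditional draws (upper bound)
        mc_se = draws.std() / np.sqrt(ess / 4)
        assert abs(draws.mean() - analytic_mean) < 3 * mc_se
        assert abs(draws.std() - post_prec**-0.5) < 0.1 * post_prec**-0.5

    def test_duplicate_fit_is_bit_identical(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.normal(0, 1, 50)})
        spec = ModelSpec(name="d", response="y", terms=())
        f1 = fit(spec, df, LIGHT)
        f2 = fit(spec, df, LIGHT)
        assert np.array_equal(f1.coef_draws, f2.coef_draws)
        assert np.array_equal(f1.sd_draws, f2.sd_draws)


class TestSummarise:
    def test_degenerate_draws(self):
        s = summarise(np.full(100, 3.5), "c")
        assert (s.e_mu, s.cri_low, s.cri_high) == (3.5, 3.5, 3.5)

    def test_directional_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        s = summarise(rng.normal(0, 1, 10_000), "x")
        assert s.p_negative + s.p_positive == 1.0
        assert abs(s.p_negative - 0.5) < 0.02


def _two_factor_fit():
    rng = np.random.default_rng(5)
    n = 400
    g = rng.choice(["a", "b"], n)
    h = rng.choice(["u", "v", "w"], n)
    y = 1.0 + 2.0 * (g == "b") - 1.0 * (h == "v") + rng.normal(0, 1, n)
    df = pd.DataFrame({"y": y, "g": g, "h": h})
    spec = ModelSpec(
        name="t", response="y", terms=("g", "h"),
        factors={"g": Factor("g", ("a", "b")),
                 "h": Factor("h", ("u", "v", "w"))},
    )
    return fit(spec, df, LIGHT)


class TestContrast:
    def test_self_contrast_is_exactly_zero(self):
        f = _two_factor_fit()
        c = contrast(f, [(1, {"g": "b"}), (-1, {"g": "b"})])
        assert (c.e_mu, c.cri_low, c.cri_high) == (0.0, 0.0, 0.0)

    def test_two_level_contrast_equals_coefficient(self):
        f = _two_factor_fit()
        c = contrast(f, [(1, {"g": "b"}), (-1, {"g": "a"})])
        s = summarise(f, "g[b]")
        assert c.e_mu == pytest.approx(s.e_mu)
        assert c.cri_low == pytest.approx(s.cri_low)

    def test_three_cell_contrast_against_per_draw_oracle(self):
        f = _two_factor_fit()
        cells = [(1.0, {"g": "b", "h": "v"}), (-0.5, {"g": "a", "h": "u"}),
                 (-0.5, {"g": "a", "h": "w"})]
        c = contrast(f, cells)
        # brute force from the coefficient draws
        names = f.coef_names
        pooled = f.coef_draws.reshape(-1, len(names))
        col = {n: pooled[:, i] for i, n in enumerate(names)}
        cell_bv = col["Intercept"] + col["g[b]"] + col["h[v]"]
        cell_au = col["Intercept"]
        cell_aw = col["Intercept"] + col["h[w]"]
        oracle = cell_bv - 0.5 * cell_au - 0.5 * cell_aw
        assert c.e_mu == pytest.approx(oracle.mean())
        assert c.cri_low == pytest.approx(np.quantile(oracle, 0.025))

    def test_unknown_level_rejected(self):
        f = _two_factor_fit()
        with pytest.raises(ModelSpecError, match="not a level"):
            contrast(f, [(1, {"g": "zzz"})])


def _prior_draws_fit(scale=1.0, seed=0):
    """A fit-shaped object whose 'posterior' draws come from the prior."""
    rng = np.random.default_rng(seed)
    spec = ModelSpec(name="prior", response="y", terms=(),
                     priors=PriorSet(intercept_scale=scale))
    draws = rng.normal(0.0, scale, size=(4, 2000, 1))
    return ModelFit(
        spec=spec, settings=LIGHT, coef_names=["Intercept"],
        coef_draws=draws, sd_names=["sigma"],
        sd_draws=np.ones((4, 2000, 1)), data=pd.DataFrame({"y": []}),
        standardization={},
    )


class TestSavageDickey:
    def test_prior_equals_posterior_gives_bf_near_one(self):
        r = savage_dickey(_prior_draws_fit(), "Intercept")
        assert r.bf01 == pytest.approx(1.0, rel=0.1)

    def test_conjugate_case_matches_analytic_ratio(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0.25, 1.0, 50)
        spec = ModelSpec(name="sd", response="y", terms=(),
                         priors=PriorSet(intercept_scale=1.0))
        f = fit(spec, pd.DataFrame({"y": y}),
                mk.McmcSettings(chains=4, iterations=6000, warmup=1000, seed=5),
                sigma_fixed=1.0)
        prec = y.size + 1.0
        mu_n, sd_n = y.sum() / prec, prec**-0.5
        analytic = stats.norm.pdf(0, mu_n, sd_n) / stats.norm.pdf(0, 0, 1.0)
        r = savage_dickey(f, "Intercept")
        assert r.bf01 == pytest.approx(analytic, rel=0.10)

    def test_bf_decreases_as_effect_grows(self):
        bfs = []
        for i, effect in enumerate((0.1, 0.4, 0.7)):
            rng = np.random.default_rng(100)  # shared noise, shifted mean
            y = effect + rng.normal(0.0, 1.0, 60)
            spec = ModelSpec(name=f"e{i}", response="y", terms=(),
                             priors=PriorSet(intercept_scale=1.0))
            f = fit(spec, pd.DataFrame({"y": y}),
                    mk.McmcSettings(chains=4, iterations=3000, warmup=500, seed=6),
                    sigma_fixed=1.0)
            bfs.append(savage_dickey(f, "Intercept").bf01)
        assert bfs[0] > bfs[1] > bfs[2]


class TestLoo:
    def test_self_comparison_difference_is_zero(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.normal(0, 1, 60)})
        spec = ModelSpec(name="m", response="y", terms=())
        f = fit(spec, df, LIGHT, store_log_lik=True)
        out = loo_compare({"a": f, "b": f})
        assert out["elpd_diff"].abs().max() == 0.0

    def test_covariate_model_wins_when_effect_real(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 200)
            y = 0.6 * x + rng.normal(0, 1, 200)
            df = pd.DataFrame({"y": y, "x": x})
            null = ModelSpec(name="null", response="y", terms=())
            cov = ModelSpec(name="cov", response="y", terms=("x",),
                            covariates={"x": Covariate("x")})
            fits = {
                "null": fit(null, df, LIGHT, store_log_lik=True),
                "cov": fit(cov, df, LIGHT, store_log_lik=True),
            }
            out = loo_compare(fits).set_index("model")
            wins += out.loc["cov", "elpd_loo"] > out.loc["null", "elpd_loo"]
        assert wins >= 9

    def test_psis_loo_agrees_with_brute_force_refits(self):
        # exact LOO by n refits on a tiny intercept model
        rng = np.random.default_rng(9)
        y = rng.normal(1.0, 1.0, 30)
        spec = ModelSpec(name="m", response="y", terms=())
        st_ = mk.McmcSettings(chains=2, iterations=1500, warmup=500, seed=4)
        full = fit(spec, pd.DataFrame({"y": y}), st_, store_log_lik=True)
        psis = loo(full)
        brute = 0.0
        for i in range(y.size):
            f_i = fit(spec, pd.DataFrame({"y": np.delete(y, i)}), st_)
            mu = f_i.draws("Intercept")
            sd = f_i.draws("sigma")
            lpd = stats.norm.logpdf(y[i], mu, sd)
            brute += np.logaddexp.reduce(lpd) - np.log(lpd.size)
        assert abs(float(psis.elpd_loo) - brute) < 2 * float(psis.se)

    def test_mismatched_data_rejected(self):
        rng = np.random.default_rng(3)
        spec = ModelSpec(name="m", response="y", terms=())
        f1 = fit(spec, pd.DataFrame({"y": rng.normal(0, 1, 40)}), LIGHT,
                 store_log_lik=True)
        f2 = fit(spec, pd.DataFrame({"y": rng.normal(0, 1, 40)}), LIGHT,
                 store_log_lik=True)
        with pytest.raises(ModelSpecError, match="different data"):
            loo_compare({"a": f1, "b": f2})


class TestCatalogue:
    def test_seventeen_models(self):
        cat = model_catalogue()
        assert len(cat) == 17
        assert set(cat) == (
            {f"UK.{i}" for i in range(1, 6)}
            | {f"JP.{i}" for i in range(1, 6)}
            | {f"JPUK.{i}" for i in range(1, 8)}
        )

    def test_uk1_filter_retains_mental_uk_rows_only(self, small_tables):
        from mentkin.bayes import prepare_table

        spec = model_catalogue()["UK.1"]
        df, _ = prepare_table(spec, small_tables["trials"])
        assert (df["condition"] == "mental").all()
        assert (df["observer_culture"] == "UK").all()
        assert (df["generator_culture"] == "UK").all()

    def test_jpuk7_structure(self):
        spec = model_catalogue()["JPUK.7"]
        assert spec.response == "cv"
        assert "group:culture" in spec.terms
        assert spec.random[0].group == "word"
        assert spec.table == "jerk_cv"

    def test_jerk_models_use_standardised_response(self):
        cat = model_catalogue()
        for name in ("JPUK.4", "JPUK.5", "JPUK.6"):
            assert cat[name].standardize_response
            assert cat[name].response == "mean_jerk"

    def test_word_factor_uses_deviation_contrast(self):
        spec = model_catalogue()["JPUK.5"]
        assert spec.factors["word"].coding == "deviation"

    def test_informative_jerk_prior_is_configurable(self):
        cat = model_catalogue(jerk_diff_prior=(-3.0, 1.0))
        assert cat["UK.3"].priors.informative["jerk_difference"] == (-3.0, 1.0)

    @pytest.mark.parametrize("name", sorted(model_catalogue()))
    def test_every_catalogue_model_fits_the_synthetic_tables(
        self, name, small_tables
    ):
        spec = model_catalogue()[name]
        st_ = mk.McmcSettings(chains=2, iterations=300, warmup=100, seed=1)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # short smoke chains trip Rhat
            f = fit(spec, small_tables[spec.table], st_)
        assert np.isfinite(f.coef_draws).all()
        assert (f.sd_draws > 0).all()
        assert f.n_obs > 0
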