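import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest

from geoadditive._pg import pg_mean, sample_pg
from geoadditive.design import Term
from geoadditive.model import (
    MCMCConfig,
    ModelMatrices,
    ModelSpec,
    PriorConfig,
    _hash_data,
    _sample_precision,
    bernoulli_deviance,
    build_design,
    deviance,
    fit,
    fit_model,
    linear_predictor,
)
from geoadditive.survey_synth import SynthDesign, TrueParams, generate_population, simulate_outcomes

from _oracles import logistic_posterior_grid


def bare_logistic_matrices(y, x):
    """A hand-assembled intercept+slope design bypassing the covariate schema."""
    spec = ModelSpec("m1_glm", fixed_terms=(Term("x", "continuous"),))
    F = np.column_stack([np.ones(y.size), x])
    return ModelMatrices(
        spec=spec, y=y, F=F, fixed_names=["intercept", "x"], data_hash=_hash_data(y, None)
    )


class TestPolyaGamma:
    @pytest.mark.parametrize("z", [0.0, 0.5, 2.0, 6.0])
    def test_mean_matches_closed_form(self, z, rng):
        draws = sample_pg(np.full(100_000, z), rng)
        expected = pg_mean(np.array([z]))[0]
        assert draws.mean() == pytest.approx(expected, rel=0.01)
        assert (draws > 0).all()


class TestBuildDesign:
    def test_fixed_block_matches_aor_table_structure(self, small_survey):
        """One dummy/linear column per reported adjusted odds ratio row."""
        children, graph, _ = small_survey
        mm = build_design(children, ModelSpec.for_model("m2"), None)
        assert mm.fixed_names[0] == "intercept"
        assert len(mm.fixed_names) == 16  # intercept + 15 AOR rows
        assert mm.fixed_names.count("mother_education=secondary+") == 1
        assert sum(n.startswith("toilet=") for n in mm.fixed_names) == 3

    def test_m1_adds_linear_age(self, small_survey):
        children, _, _ = small_survey
        mm = build_design(children, ModelSpec.for_model("m1"), None)
        assert "age_months" in mm.fixed_names
        assert len(mm.fixed_names) == 17

    def test_smooth_block_dimensions_and_penalty_rank(self, small_survey):
        children, graph, _ = small_survey
        mm = build_design(children, ModelSpec.for_model("m3"), graph)
        blk = mm.smooths["age_months"]
        assert blk.B.shape[1] == 20
        assert blk.penalty.rank == 18
        assert blk.T.shape == (20, 19)

    def test_unseen_district_rejected_by_name(self, small_survey):
        children, graph, _ = small_survey
        bad = children.copy()
        bad.loc[bad.index[0], "district_id"] = "atlantis"
        with pytest.raises(ValueError, match="atlantis"):
            build_design(bad, ModelSpec.for_model("m3"), graph)

    def test_absent_level_dropped_with_warning(self, small_survey):
        children, _, _ = small_survey
        no_flush = children[children["toilet"] != "flush"]
        with pytest.warns(UserWarning, match="flush"):
            mm = build_design(no_flush, ModelSpec.for_model("m2"), None)
        assert "toilet=flush" not in mm.fixed_names

    def test_model_class_constraints(self):
        with pytest.raises(ValueError, match="M1"):
            ModelSpec("m1_glm", spatial=True)
        with pytest.raises(ValueError, match="spatial"):
            ModelSpec("m3_geoadditive", spatial=False)


class TestFitOracles:
    def test_intercept_only_matches_beta_binomial(self):
        """25/100 successes under a flat-ish prior: posterior mean of pi near 1/4."""
        y = np.r_[np.ones(25), np.zeros(75)]
        spec = ModelSpec("m1_glm", fixed_terms=())
        mm = ModelMatrices(
            spec=spec, y=y, F=np.ones((100, 1)), fixed_names=["intercept"],
            data_hash=_hash_data(y, None),
        )
        res = fit(mm, mcmc=MCMCConfig(n_iter=6000, burn_in=1000, seed=3))
        pi_draws = 1 / (1 + np.exp(-res.beta[:, 0]))
        assert pi_draws.mean() == pytest.approx(0.25, abs=0.02)

    def test_two_parameter_posterior_matches_grid_quadrature(self, rng):
        """n=20 logistic regression: Gibbs moments agree with dense quadrature."""
        x = rng.normal(size=20)
        y = (rng.uniform(size=20) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        mean_oracle, sd_oracle = logistic_posterior_grid(y, x)
        res = fit(bare_logistic_matrices(y, x), mcmc=MCMCConfig(n_iter=15000, burn_in=2000, seed=7))
        assert np.abs(res.beta.mean(0) - mean_oracle).max() < 0.05
        assert np.abs(res.beta.std(0) - sd_oracle).max() < 0.05

    def test_null_data_credible_intervals_cover_zero(self):
        """With all true effects zero, ~95% of fixed-effect CrIs contain 0."""
        design = SynthDesign(n_districts=10, districts_layout="ring",
                             clusters_per_district=4, households_per_cluster=13, seed=21)
        df = generate_population(design)
        out = simulate_outcomes(df, TrueParams(beta={"intercept": 0.0}, age_curve=None), seed=4)
        res = fit_model(out, "m1", mcmc=MCMCConfig(n_iter=900, burn_in=300, seed=6))
        lo = np.percentile(res.beta, 2.5, axis=0)
        hi = np.percentile(res.beta, 97.5, axis=0)
        covered = ((lo <= 0) & (0 <= hi))[1:]  # exclude intercept
        assert covered.size == 16
        assert covered.sum() >= 14

    def test_precision_full_conditional_is_gamma(self, rng):
        """Frozen latent block: tau2 draws follow Gamma(a + rank/2, b + quad/2)."""
        a, b, rank, quad = 1.0, 0.001, 18, 3.7
        draws = _sample_precision(rng, a, b, rank, quad, size=10_000)
        ref = gamma_dist(a + rank / 2, scale=1 / (b + quad / 2))
        assert kstest(draws, ref.cdf).pvalue > 0.01


class TestFitMechanics:
    def test_chain_determinism(self, small_survey):
        children, graph, _ = small_survey
        cfg = MCMCConfig(n_iter=80, burn_in=20, seed=9)
        a = fit_model(children, "m3", graph=graph, mcmc=cfg)
        b = fit_model(children, "m3", graph=graph, mcmc=cfg)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.f_str, b.f_str)
        assert np.array_equal(a.tau2["unstr"], b.tau2["unstr"])

    def test_constraints_hold_for_every_draw(self, m3_fit, small_survey):
        children, _, _ = small_survey
        from geoadditive.smooth_basis import bspline_design

        # smooth block: basis-column-mean weighted coefficient sum is zero,
        # i.e. the fitted smooth averages to zero over the training data
        B = bspline_design(
            children["age_months"].to_numpy(float), m3_fit.smooth_meta["age_months"]
        )
        w = B.mean(axis=0)
        assert np.abs(m3_fit.alpha["age_months"] @ w).max() < 1e-10
        assert np.abs(m3_fit.f_str.sum(axis=1)).max() < 1e-8
        assert np.abs(m3_fit.f_unstr.sum(axis=1)).max() < 1e-8
        assert all((draws > 0).all() for draws in m3_fit.tau2.values())

    def test_burn_in_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)

    def test_linear_predictor_matches_direct_dot_product(self, m3_fit, small_survey):
        children, _, _ = small_survey
        eta, pi = linear_predictor(m3_fit, children.head(50))
        assert np.all((pi > 0) & (pi < 1))
        # direct recomputation for one draw and one child
        from geoadditive.design import fixed_effects_matrix
        from geoadditive.smooth_basis import bspline_design

        row = children.head(50)
        F, names = fixed_effects_matrix(row, m3_fit.spec.fixed_terms)
        cols = [names.index(c) for c in m3_fit.fixed_names]
        B = bspline_design(row["age_months"].to_numpy(float), m3_fit.smooth_meta["age_months"])
        d = {dd: i for i, dd in enumerate(m3_fit.districts)}
        for s in (0, m3_fit.n_draws - 1):
            direct = (
                F[:, cols] @ m3_fit.beta[s]
                + B @ m3_fit.alpha["age_months"][s]
                + m3_fit.f_str[s][[d[x] for x in row["district_id"]]]
                + m3_fit.f_unstr[s][[d[x] for x in row["district_id"]]]
            )
            assert np.abs(eta[s] - direct).max() < 1e-10

    def test_malaria_dummy_shifts_eta_by_its_coefficient(self, m3_fit, small_survey):
        children, _, _ = small_survey
        base = children.head(5).copy()
        base["malaria_rdt"] = "negative"
        flipped = base.copy()
        flipped["malaria_rdt"] = "positive"
        eta0, _ = linear_predictor(m3_fit, base)
        eta1, _ = linear_predictor(m3_fit, flipped)
        j = m3_fit.fixed_names.index("malaria_rdt=positive")
        assert np.allclose(eta1 - eta0, m3_fit.beta[:, [j]], atol=1e-10)


class TestDeviance:
    def test_half_probability_closed_form(self):
        y = np.r_[np.ones(7), np.zeros(5)]
        assert bernoulli_deviance(y, np.zeros(12)) == pytest.approx(2 * 12 * np.log(2))

    def test_perfect_prediction_limit(self):
        y = np.r_[np.ones(3), np.zeros(3)]
        eta = np.r_[np.full(3, 40.0), np.full(3, -40.0)]
        assert bernoulli_deviance(y, eta) < 1e-10

    def test_matches_independent_loglik_oracle(self, m3_fit, small_survey):
        children, _, _ = small_survey
        sub = children.head(200)
        draws, d_hat = deviance(m3_fit, sub)
        eta, pi = linear_predictor(m3_fit, sub)
        y = sub["anaemic"].to_numpy(float)
        idx = np.linspace(0, m3_fit.n_draws - 1, 100).astype(int)
        for s in idx:
            oracle = -2 * (y * np.log(pi[s]) + (1 - y) * np.log(1 - pi[s])).sum()
            assert draws[s] == pytest.approx(oracle, abs=1e-8)
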