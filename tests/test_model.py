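"""Gibbs sampler correctness, posterior functionals, persistence."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bstmap import (
    MCMCSettings,
    ModelSpec,
    SpaceTimePanel,
    arithmetic_mean_rate,
    coefficient_percent_effect,
    coefficient_significance,
    fit_gibbs,
    generate_area_graph,
    load_draws,
    posterior_summary,
    save_draws,
    simulate_panel,
)

NO_EFFECTS = dict(spatial_family="none", temporal_family="none", interaction_type="none")


def conjugate_posterior(W, z, sigma_sq, prior_sds):
    """Closed-form Gaussian posterior for a linear model with known noise."""
    prior_prec = np.diag(1.0 / np.asarray(prior_sds) ** 2)
    cov = np.linalg.inv(W.T @ W / sigma_sq + prior_prec)
    mean = cov @ (W.T @ z) / sigma_sq
    return mean, cov


class TestSampler:
    def test_intercept_only_matches_conjugate_closed_form(self):
        graph, _ = generate_area_graph(10, seed=3)
        spec = ModelSpec(covariate_names=(), **NO_EFFECTS)
        panel, _, _ = simulate_panel(
            graph, n_years=5, spec=spec, sigma_z_sq=1.0, baseline_log_rate=2.0, seed=3
        )
        draws = fit_gibbs(
            panel, None, None, spec,
            MCMCSettings(iterations=4000, burn_in=1000, chains=2, seed=9, fixed_sigma_z_sq=1.0),
        )
        W = np.ones((panel.n_areas * panel.n_years, 1))
        mean, cov = conjugate_posterior(W, panel.log_rates.ravel(), 1.0, [100.0])
        mc_se = draws.intercept.std() / np.sqrt(len(draws.intercept) / 4)
        assert abs(draws.intercept.mean() - mean[0]) < 3 * mc_se
        assert draws.intercept.std() == pytest.approx(np.sqrt(cov[0, 0]), rel=0.1)

    def test_degenerate_constant_panel_concentrates(self):
        graph, _ = generate_area_graph(6, seed=0)
        spec = ModelSpec(covariate_names=(), **NO_EFFECTS)
        rates = np.full((6, 4), 12.0)
        panel = SpaceTimePanel.from_rates(graph.area_ids, np.arange(2000, 2004), rates)
        draws = fit_gibbs(
            panel, None, None, spec, MCMCSettings(iterations=2000, burn_in=500, seed=1)
        )
        assert draws.intercept.mean() == pytest.approx(np.log(12.0), abs=0.01)
        assert draws.sigma_z_sq.mean() < 0.01

    def test_deterministic_given_seed(self, small_panel):
        graph, panel, covariates, _ = small_panel
        spec = ModelSpec(covariate_names=("x1", "x2"))
        mcmc = MCMCSettings(iterations=200, burn_in=100, chains=2, seed=42)
        a = fit_gibbs(panel, covariates, graph, spec, mcmc)
        b = fit_gibbs(panel, covariates, graph, spec, mcmc)
        np.testing.assert_array_equal(a.intercept, b.intercept)
        np.testing.assert_array_equal(a.mu_z, b.mu_z)

    def test_structured_draws_respect_constraints(self, small_panel):
        graph, panel, covariates, _ = small_panel
        spec = ModelSpec(covariate_names=("x1",), spatial_family="besag",
                         temporal_family="rw2", interaction_type="IV")
        draws = fit_gibbs(
            panel, covariates, graph, spec,
            MCMCSettings(iterations=300, burn_in=200, chains=1, seed=5),
        )
        assert np.abs(draws.spatial_structured.sum(axis=1)).max() < 1e-8
        t = np.arange(panel.n_years, dtype=float)
        phi = draws.temporal_effect
        assert np.abs(phi.sum(axis=1)).max() < 1e-8
        assert np.abs(phi @ (t - t.mean())).max() < 1e-7

    def test_missing_cells_are_imputed(self):
        graph, _ = generate_area_graph(12, seed=2)
        panel, cov, _ = simulate_panel(graph, n_years=6, seed=2, missing_fraction=0.1)
        spec = ModelSpec(covariate_names=())
        draws = fit_gibbs(
            panel, None, graph, spec, MCMCSettings(iterations=300, burn_in=200, seed=2)
        )
        assert np.isfinite(draws.mu_z).all()
        assert (draws.sigma_z_sq > 0).all()

    def test_rejects_degenerate_inputs(self):
        graph, _ = generate_area_graph(6, seed=0)
        rates = np.full((6, 4), 10.0)
        rates[2, :] = np.nan
        with pytest.raises(ValueError, match="A2"):
            panel = SpaceTimePanel.from_rates(graph.area_ids, np.arange(2000, 2004), rates)
            fit_gibbs(panel, None, graph, ModelSpec(covariate_names=()), MCMCSettings(iterations=10, burn_in=5))
        small = SpaceTimePanel.from_rates(["a", "b"], [2000, 2001], np.full((2, 2), 5.0))
        with pytest.raises(ValueError, match="3 years"):
            fit_gibbs(small, None, None, ModelSpec(covariate_names=(), **NO_EFFECTS),
                      MCMCSettings(iterations=10, burn_in=5))


class TestPosteriorFunctionals:
    def test_arithmetic_mean_rate_values(self):
        assert arithmetic_mean_rate(np.log(10.0), 0.0) == pytest.approx(10.0)
        assert arithmetic_mean_rate(2.0, 1.0) == pytest.approx(np.exp(2.5), abs=1e-5)

    def test_geometric_never_exceeds_arithmetic(self, small_panel):
        _, panel, _, _ = small_panel
        rng = np.random.default_rng(0)
        mu = rng.normal(2.0, 0.5, size=(50, 4, 3))
        sig = rng.uniform(0.01, 1.0, size=50)
        assert np.all(np.exp(mu) <= arithmetic_mean_rate(mu, sig) + 1e-12)

    def test_percent_effect_values(self):
        assert coefficient_percent_effect(0.0) == 0.0
        assert coefficient_percent_effect(np.log(2.0)) == pytest.approx(100.0)
        assert coefficient_percent_effect(-0.10536) == pytest.approx(-10.0, abs=0.001)

    def test_significance_thresholds(self):
        rng = np.random.default_rng(1)
        all_pos = rng.uniform(0.1, 1.0, 1000)
        assert coefficient_significance(all_pos) == (True, 1)
        symmetric = np.concatenate([rng.normal(0, 1, 500), -rng.normal(0, 1, 500)])
        assert coefficient_significance(symmetric)[0] is False
        # 97% positive is NOT significant at level 0.05 (needs > 97.5%)
        draws = np.concatenate([np.ones(970), -np.ones(30)])
        assert coefficient_significance(draws, 0.05)[0] is False
        draws = np.concatenate([np.ones(980), -np.ones(20)])
        assert coefficient_significance(draws, 0.05)[0] is True

    @given(st.floats(-3, 3))
    def test_percent_effect_matches_direct_formula(self, beta):
        assert coefficient_percent_effect(beta) == pytest.approx(100 * (np.exp(beta) - 1))


class TestSummaryAndPersistence:
    def test_summary_quantiles_and_rhat(self, small_panel):
        graph, panel, covariates, _ = small_panel
        spec = ModelSpec(covariate_names=("x1",))
        draws = fit_gibbs(
            panel, covariates, graph, spec,
            MCMCSettings(iterations=600, burn_in=200, chains=2, seed=7),
        )
        table = posterior_summary(draws).set_index("unknown")
        vec = draws.intercept
        assert table.loc["intercept", "ci_2.5%"] == pytest.approx(np.quantile(vec, 0.025))
        assert table.loc["intercept", "ci_97.5%"] == pytest.approx(np.quantile(vec, 0.975))
        assert abs(table.loc["intercept", "rhat"] - 1.0) < 0.1

    def test_single_chain_omits_rhat_with_warning(self, small_panel):
        graph, panel, covariates, _ = small_panel
        spec = ModelSpec(covariate_names=())
        draws = fit_gibbs(
            panel, None, graph, spec,
            MCMCSettings(iterations=300, burn_in=200, chains=1, seed=3),
        )
        with pytest.warns(UserWarning, match="single chain"):
            table = posterior_summary(draws)
        assert table["rhat"].isna().all()

    def test_round_trip_to_disk(self, small_panel, tmp_path):
        graph, panel, covariates, _ = small_panel
        spec = ModelSpec(covariate_names=("x1",))
        draws = fit_gibbs(
            panel, covariates, graph, spec,
            MCMCSettings(iterations=120, burn_in=60, chains=1, seed=0),
        )
        save_draws(draws, tmp_path / "draws")
        back = load_draws(tmp_path / "draws")
        np.testing.assert_array_equal(back.mu_z, draws.mu_z)
        np.testing.assert_array_equal(back.sigma_z_sq, draws.sigma_z_sq)
        assert back.meta["covariate_names"] == ["x1"]
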