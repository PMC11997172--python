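"""Covariate screening and information-criterion computation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from bstmap import (
    CovariatePanel,
    MCMCSettings,
    ModelSpec,
    candidate_grid,
    compute_cpo,
    compute_dic,
    compute_fit_errors,
    compute_waic,
    fit_gibbs,
    generate_area_graph,
    pointwise_loglik,
    screen_covariates,
    simulate_panel,
    two_step_select,
)
from bstmap.selection import plugin_pointwise_loglik


def make_cov(panel, arrays_by_name):
    names = list(arrays_by_name)
    values = np.stack([arrays_by_name[n] for n in names], axis=-1)
    return CovariatePanel(
        area_ids=panel.area_ids, years=panel.years, names=names, values=values
    )


@pytest.fixture(scope="module")
def panel():
    graph, _ = generate_area_graph(15, seed=8)
    panel, _, _ = simulate_panel(
        graph, n_years=8, spec=ModelSpec(covariate_names=()), seed=8
    )
    return panel


class TestScreening:
    def test_perfect_predictor_and_noise_both_retained(self, panel):
        rng = np.random.default_rng(0)
        cov = make_cov(panel, {"x1": panel.log_rates.copy(), "x2": rng.standard_normal(panel.rates.shape)})
        report = screen_covariates(cov, panel)
        assert set(report.retained_names) == {"x1", "x2"}
        assert report.correlation_with_outcome["x1"] == pytest.approx(1.0)

    def test_collinear_pair_drops_weaker_member(self, panel):
        rng = np.random.default_rng(1)
        z = panel.log_rates
        noise = rng.standard_normal(z.shape)
        x1 = 0.6 * (z - z.mean()) / z.std() + 0.8 * noise
        x2 = x1 + 0.01 * rng.standard_normal(z.shape)  # pairwise r > 0.99
        cov = make_cov(panel, {"x1": x1, "x2": x2})
        report = screen_covariates(cov, panel, collinearity_threshold=0.7)
        r1 = abs(report.correlation_with_outcome["x1"])
        r2 = abs(report.correlation_with_outcome["x2"])
        stronger, weaker = ("x1", "x2") if r1 >= r2 else ("x2", "x1")
        assert report.retained_names == [stronger]
        assert report.pruned_pairs[0][0] == stronger and report.pruned_pairs[0][1] == weaker

    def test_orthogonal_covariates_all_retained(self, panel):
        rng = np.random.default_rng(2)
        cov = make_cov(
            panel, {f"x{m}": rng.standard_normal(panel.rates.shape) for m in range(10)}
        )
        report = screen_covariates(cov, panel)
        assert len(report.retained_names) == 10

    def test_constant_covariate_dropped_with_warning(self, panel):
        cov = make_cov(panel, {"flat": np.ones(panel.rates.shape)})
        with pytest.warns(UserWarning, match="constant"):
            report = screen_covariates(cov, panel)
        assert report.retained_names == []


def slow_waic(loglik):
    n_draws, n_cells = loglik.shape
    lppd = p = 0.0
    for i in range(n_cells):
        lik = [np.exp(loglik[d, i]) for d in range(n_draws)]
        lppd += np.log(sum(lik) / n_draws)
        mean_ll = sum(loglik[:, i]) / n_draws
        p += sum((ll - mean_ll) ** 2 for ll in loglik[:, i]) / (n_draws - 1)
    return -2 * (lppd - p), p


def slow_cpo(loglik):
    n_draws, n_cells = loglik.shape
    cpo = np.array(
        [1.0 / (np.mean([np.exp(-loglik[d, i]) for d in range(n_draws)])) for i in range(n_cells)]
    )
    return cpo, float(np.sum(np.log(cpo)))


class TestCriteria:
    def test_loglik_density_one_case(self):
        # z = mu and sigma^2 = 1/(2*pi) makes the Normal density exactly 1
        from bstmap import SpaceTimePanel
        panel = SpaceTimePanel.from_rates(["a", "b"], [2000, 2001, 2002], np.full((2, 3), 10.0))

        class Fake:
            mu_z = np.full((4, 2, 3), np.log(10.0))
            sigma_z_sq = np.full(4, 1.0 / (2 * np.pi))

        ll = pointwise_loglik(Fake(), panel)
        assert ll.shape == (4, 6)
        np.testing.assert_allclose(ll, 0.0, atol=1e-12)
        Fake.sigma_z_sq = np.ones(4)
        np.testing.assert_allclose(pointwise_loglik(Fake(), panel), -0.5 * np.log(2 * np.pi))

    def test_identical_draws_have_zero_penalty(self):
        ll = np.tile(np.array([-1.3, -0.2, -2.0]), (5, 1))
        dic, p_dic = compute_dic(ll, plugin_loglik=ll[0])
        assert p_dic == pytest.approx(0.0, abs=1e-10)
        assert dic == pytest.approx(-2 * ll[0].sum())
        waic, p_waic = compute_waic(ll)
        assert p_waic == pytest.approx(0.0, abs=1e-12)
        assert waic == pytest.approx(-2 * ll[0].sum())
        cpo, lpml = compute_cpo(ll)
        np.testing.assert_allclose(cpo, np.exp(ll[0]))

    def test_two_draw_harmonic_mean(self):
        # likelihoods 1 and 1/3 -> harmonic mean 2/(1+3) = 0.5
        ll = np.log(np.array([[1.0], [1.0 / 3.0]]))
        cpo, lpml = compute_cpo(ll)
        assert cpo[0] == pytest.approx(0.5)
        assert lpml == pytest.approx(np.log(0.5))

    def test_waic_hand_computed_2x2(self):
        ll = np.array([[-1.0, -2.0], [-1.5, -0.5]])
        lppd = np.log((np.exp(-1.0) + np.exp(-1.5)) / 2) + np.log((np.exp(-2.0) + np.exp(-0.5)) / 2)
        p = np.var([-1.0, -1.5], ddof=1) + np.var([-2.0, -0.5], ddof=1)
        waic, p_waic = compute_waic(ll)
        assert waic == pytest.approx(-2 * (lppd - p))
        assert p_waic == pytest.approx(p)

    def test_vectorized_criteria_match_slow_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            ll = rng.normal(-1.0, 0.7, size=(5, 5))
            waic, p_waic = compute_waic(ll)
            ref_waic, ref_p = slow_waic(ll)
            assert waic == pytest.approx(ref_waic, abs=1e-10)
            assert p_waic == pytest.approx(ref_p, abs=1e-10)
            cpo, lpml = compute_cpo(ll)
            ref_cpo, ref_lpml = slow_cpo(ll)
            np.testing.assert_allclose(cpo, ref_cpo, atol=1e-10)
            assert lpml == pytest.approx(ref_lpml, abs=1e-10)

    @given(
        arrays(np.float64, (4, 6), elements=st.floats(-8, 0)),
    )
    def test_lpml_never_exceeds_lppd(self, ll):
        # harmonic mean <= arithmetic mean, logged
        _, lpml = compute_cpo(ll)
        n = ll.shape[0]
        from scipy.special import logsumexp

        lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(n)))
        assert lpml <= lppd + 1e-9

    def test_dic_on_conjugate_normal_matches_analytic_posterior(self):
        # y ~ N(theta, 1), theta ~ N(0, 10^2): posterior is closed-form, so
        # DIC can be brute-forced from exact posterior draws
        rng = np.random.default_rng(4)
        y = rng.normal(1.0, 1.0, size=20)
        post_var = 1.0 / (len(y) + 1.0 / 100.0)
        post_mean = post_var * y.sum()
        theta = rng.normal(post_mean, np.sqrt(post_var), size=40_000)
        ll = -0.5 * (np.log(2 * np.pi) + (y[None, :] - theta[:, None]) ** 2)
        plugin = -0.5 * (np.log(2 * np.pi) + (y - post_mean) ** 2)
        dic, p_dic = compute_dic(ll, plugin)
        # analytic: p_DIC = n * post_var (one effective parameter here)
        assert p_dic == pytest.approx(len(y) * post_var, rel=0.05)


class TestFitErrors:
    def test_exact_and_shifted_fits(self):
        graph, _ = generate_area_graph(6, seed=0)
        panel, _, _ = simulate_panel(
            graph, n_years=4, spec=ModelSpec(covariate_names=()), seed=0
        )

        class Fake:
            sigma_z_sq = np.zeros(3)
            mu_z = np.tile(panel.log_rates, (3, 1, 1))

        bias, rmse, r = compute_fit_errors(panel, Fake())
        assert bias == pytest.approx(0.0, abs=1e-9)
        assert rmse == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

        class Shifted:
            sigma_z_sq = np.zeros(3)
            mu_z = np.tile(np.log(panel.rates + 2.0), (3, 1, 1))

        bias, rmse, r = compute_fit_errors(panel, Shifted())
        assert bias == pytest.approx(2.0, abs=1e-9)
        assert rmse == pytest.approx(2.0, abs=1e-9)
        assert r == pytest.approx(1.0)


class TestStructureSearch:
    def test_grid_has_36_candidates(self):
        specs = candidate_grid()
        assert len(specs) == 36
        assert len({s.label for s in specs}) == 36

    def test_identical_specs_get_identical_metrics(self):
        graph, _ = generate_area_graph(8, seed=6)
        panel, _, _ = simulate_panel(
            graph, n_years=5, spec=ModelSpec(covariate_names=()), seed=6
        )
        spec = ModelSpec(covariate_names=(), spatial_family="iid",
                         temporal_family="rw1", interaction_type="I")
        table, best = two_step_select(
            panel, None, graph, [spec, spec],
            MCMCSettings(iterations=200, burn_in=100, seed=0),
        )
        assert table.iloc[0]["waic"] == table.iloc[1]["waic"]

    def test_failed_fit_is_recorded_not_fatal(self):
        graph, _ = generate_area_graph(8, seed=6)
        panel, _, _ = simulate_panel(
            graph, n_years=5, spec=ModelSpec(covariate_names=()), seed=6
        )
        bad = ModelSpec(covariate_names=("missing_cov",))
        good = ModelSpec(covariate_names=(), spatial_family="iid",
                         temporal_family="iid", interaction_type="I")
        table, best = two_step_select(
            panel, None, graph, [bad, good],
            MCMCSettings(iterations=150, burn_in=50, seed=0),
        )
        assert (table["status"] == "ok").sum() == 1
        assert best.label == good.label
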