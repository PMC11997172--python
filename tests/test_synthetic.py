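"""Generator: graphs, panels, ground truth, hotspot scenarios."""

import numpy as np
import pytest

from bstmap import (
    ModelSpec,
    generate_area_graph,
    make_hotspot_scenario,
    simulate_panel,
)


def morans_i(graph, values):
    """Plain-formula Moran's I over the contiguity graph."""
    adj = graph.adjacency_matrix().toarray()
    x = values - values.mean()
    w_sum = adj.sum()
    return (len(x) / w_sum) * (x @ adj @ x) / (x @ x)


class TestGraphs:
    def test_grid_layouts(self):
        g, polys = generate_area_graph(9, layout="grid")
        degrees = dict(zip(g.area_ids, g.degrees()))
        assert degrees["A0"] == 3  # corner under queen contiguity
        assert len(polys) == 9

    def test_study_size_grid_connected(self):
        g, _ = generate_area_graph(183, layout="grid")
        assert g.n_areas == 183 and g.n_components == 1

    def test_seed_reproducibility(self):
        a, _ = generate_area_graph(30, layout="random_planar", seed=5)
        b, _ = generate_area_graph(30, layout="random_planar", seed=5)
        assert a.edges == b.edges

    def test_random_planar_is_connected(self):
        g, polys = generate_area_graph(40, layout="random_planar", seed=7)
        assert g.n_components == 1 and len(polys) == 40


class TestPanels:
    def test_noise_free_panel_is_constant(self):
        g, _ = generate_area_graph(6)
        spec = ModelSpec(covariate_names=(), spatial_family="none",
                         temporal_family="none", interaction_type="none")
        panel, cov, truth = simulate_panel(
            g, n_years=4, spec=spec, sigma_z_sq=0.0, seed=0
        )
        np.testing.assert_allclose(panel.rates, 12.0, rtol=1e-12)

    def test_default_grand_mean_envelope(self):
        g, _ = generate_area_graph(183)
        for seed in range(3):
            panel, _, _ = simulate_panel(g, n_years=20, seed=seed)
            assert 8.0 < np.nanmean(panel.rates) < 18.0

    def test_same_seed_bit_identical(self):
        g, _ = generate_area_graph(12)
        a = simulate_panel(g, n_years=5, seed=3)
        b = simulate_panel(g, n_years=5, seed=3)
        np.testing.assert_array_equal(a[0].rates, b[0].rates)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_truth_reconstructs_z_exactly(self):
        g, _ = generate_area_graph(10)
        spec = ModelSpec(covariate_names=("x1", "x2"), interaction_type="IV")
        panel, cov, truth = simulate_panel(g, n_years=6, spec=spec, seed=4)
        np.testing.assert_allclose(truth.reconstruct_z(cov), panel.log_rates, atol=1e-12)

    def test_spatial_variance_raises_morans_i(self):
        g, _ = generate_area_graph(64)
        spec = ModelSpec(covariate_names=(), spatial_family="besag",
                         temporal_family="none", interaction_type="none")
        wins = 0
        for seed in range(10):
            with_icar, _, _ = simulate_panel(
                g, n_years=5, spec=spec, variances={"spatial": 1.0},
                sigma_z_sq=0.05, seed=seed,
            )
            spec0 = ModelSpec(covariate_names=(), spatial_family="none",
                              temporal_family="none", interaction_type="none")
            without, _, _ = simulate_panel(g, n_years=5, spec=spec0, sigma_z_sq=0.05, seed=seed)
            i_with = morans_i(g, np.nanmean(with_icar.log_rates, axis=1))
            i_without = morans_i(g, np.nanmean(without.log_rates, axis=1))
            wins += i_with > i_without
        assert wins == 10

    def test_noise_variance_matches_sigma(self):
        g, _ = generate_area_graph(100)
        panel, _, truth = simulate_panel(
            g, n_years=20,
            spec=ModelSpec(covariate_names=(), spatial_family="none",
                           temporal_family="none", interaction_type="none"),
            sigma_z_sq=0.25, seed=11,
        )
        assert truth.effect_vectors["noise"].var() == pytest.approx(0.25, rel=0.05)

    def test_covariates_are_standardized(self):
        g, _ = generate_area_graph(20)
        _, cov, _ = simulate_panel(g, n_years=10, seed=2)
        np.testing.assert_allclose(cov.values.mean(axis=(0, 1)), 0.0, atol=1e-12)
        np.testing.assert_allclose(cov.values.std(axis=(0, 1)), 1.0, atol=1e-12)

    def test_correlated_covariate_option(self):
        g, _ = generate_area_graph(40)
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        spec = ModelSpec(covariate_names=("x1", "x2"), spatial_family="none",
                         temporal_family="none", interaction_type="none")
        _, cov, _ = simulate_panel(
            g, n_years=10, spec=spec, covariate_correlation=corr, seed=6
        )
        r = np.corrcoef(cov.values[:, :, 0].ravel(), cov.values[:, :, 1].ravel())[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)


class TestHotspotScenario:
    def test_factor_one_means_no_intended_hotspots(self):
        g, _ = generate_area_graph(10)
        panel, truth = make_hotspot_scenario(
            g, n_years=5, elevated_areas=[g.area_ids[0]], elevation_factor=1.0, seed=0
        )
        assert truth.intended_hotspots == []

    def test_elevated_rates_exceed_every_yearly_median(self):
        g, _ = generate_area_graph(50)
        elevated = [g.area_ids[i] for i in range(5)]
        panel, truth = make_hotspot_scenario(
            g, n_years=10, elevated_areas=elevated, elevation_factor=3.0, seed=1
        )
        from bstmap import yearly_median_threshold

        q = yearly_median_threshold(panel)
        idx = [panel.area_ids.index(a) for a in elevated]
        assert (panel.rates[idx, :] > q[None, :]).all()

    def test_unknown_area_is_error(self):
        g, _ = generate_area_graph(10)
        with pytest.raises(ValueError, match="unknown"):
            make_hotspot_scenario(g, elevated_areas=["nope"], seed=0)
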