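"""BYM smoothing and Matérn surface interpolation."""

import numpy as np
import pytest

from spatialenroll.disease_mapping import (
    GPConfig,
    GridSpec,
    InferenceConfig,
    MappingInputs,
    expected_counts,
    fit_bym,
    interpolate_surface,
    predict_surface_at,
    smoothed_rates,
)
from spatialenroll.posterior import PosteriorSummary
from spatialenroll.spatial_structure import build_adjacency
from spatialenroll.synthetic_region import (
    SimulationConfig,
    generate_region,
    sample_icar_field,
)
from .conftest import grid_areas

FAST = InferenceConfig(chains=2, draws=1200, burn=600, seed=0)


class TestExpectedCounts:
    def test_global_rate_times_diabetics(self):
        # 100 diabetics at a 36.8% overall unenrollment rate expect 36.8
        n_diab = np.array([100.0, 900.0])
        O = np.array([30.0, 338.0])  # total rate 0.368
        E = expected_counts(n_diab, O)
        assert E[0] == pytest.approx(36.8)

    def test_equal_populations_equal_expectations(self):
        E = expected_counts(np.full(5, 40.0), np.array([3.0, 9.0, 5.0, 1.0, 2.0]))
        assert np.allclose(E, E[0])

    def test_totals_match_exactly(self, rng):
        n_diab = rng.integers(10, 200, size=30).astype(float)
        O = rng.integers(0, 50, size=30).astype(float)
        E = expected_counts(n_diab, O)
        assert E.sum() == pytest.approx(O.sum(), abs=1e-9)

    def test_cases_without_population_rejected(self):
        with pytest.raises(ValueError):
            expected_counts(np.array([0.0, 50.0]), np.array([2.0, 10.0]))


class TestFitBym:
    def test_null_data_gives_unit_relative_risk(self):
        areas = grid_areas(4, 4)
        graph = build_adjacency(areas)
        O = np.full(16, 500.0)
        post = fit_bym(MappingInputs(O, O.copy(), graph), inference=FAST)
        thetas = [post.mean(f"theta[{a}]") for a in graph.area_ids]
        assert all(0.95 <= t <= 1.05 for t in thetas)

    def test_recovers_known_risk_surface(self):
        cfg = SimulationConfig(n_rows=15, n_cols=15, seed=7)
        areas, graph, _ = generate_region(cfg)
        rng = np.random.default_rng(42)
        truth = sample_icar_field(graph, 0.5, rng=rng)
        E0 = np.full(graph.n_areas, 50.0)
        O = rng.poisson(E0 * np.exp(truth)).astype(float)
        E = E0 * O.sum() / E0.sum()
        post = fit_bym(MappingInputs(O, E, graph), inference=FAST)
        est = np.log([post.mean(f"theta[{a}]") for a in graph.area_ids])
        assert np.corrcoef(est, truth)[0, 1] > 0.7

    def test_extreme_low_count_area_is_shrunk(self):
        # tiny expected count with an extreme crude rate is pulled inward
        areas = grid_areas(5, 5)
        graph = build_adjacency(areas)
        n_diab = np.array([2.0] + [50.0] * 24)
        O = np.array([4.0] + [50.0] * 24)
        E = expected_counts(n_diab, O)
        post = fit_bym(MappingInputs(O, E, graph), inference=FAST)
        log_post = np.log(post.mean(f"theta[{graph.area_ids[0]}]"))
        crude = np.log(O[0] / E[0])
        assert abs(log_post) < abs(crude)

    def test_reports_convergence_diagnostics_and_seeds(self):
        areas = grid_areas(3, 3)
        graph = build_adjacency(areas)
        O = np.full(9, 100.0)
        p1 = fit_bym(MappingInputs(O, O.copy(), graph), inference=FAST)
        p2 = fit_bym(MappingInputs(O, O.copy(), graph), inference=FAST)
        assert "rhat" in p1.diagnostics and "converged" in p1.diagnostics
        assert np.array_equal(p1.samples, p2.samples)  # seeded reproducibility

    def test_invalid_inputs_rejected(self, demo_dataset):
        O = np.full(100, 5.0)
        E = np.full(100, 5.0)
        E[3] = 0.0
        with pytest.raises(ValueError):
            MappingInputs(O, E, demo_dataset.graph)


class TestSmoothedRates:
    def test_scales_theta_by_global_rate(self):
        post = PosteriorSummary(
            names=["theta[a]", "theta[b]"],
            samples=np.array([[1.0, 2.0], [1.0, 2.0]]),
            deviance_samples=np.array([1.0, 1.0]),
            deviance_at_mean=1.0,
        )
        out = smoothed_rates(post, 0.368).set_index("area_id")["rate"]
        assert out["a"] == pytest.approx(0.368)
        assert out["b"] == pytest.approx(0.736)


class TestSurface:
    def _centroids(self, n=6, spread=10.0, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(0, spread, size=(n, 2)) + 500

    def test_constant_values_give_constant_surface(self):
        pts = self._centroids()
        s = interpolate_surface(pts, np.full(6, 0.37))
        assert np.allclose(s.values, 0.37, atol=1e-9)

    def test_small_nugget_interpolates_observations(self):
        pts = self._centroids(n=10)
        vals = np.sin(pts[:, 0] / 3) + 0.1 * pts[:, 1]
        s = interpolate_surface(
            pts, vals, gp_config=GPConfig(range_km=5.0, marginal_sd=1.0, nugget=1e-8)
        )
        pred = predict_surface_at(s, pts)
        assert np.abs(pred - vals).max() < 1e-3

    def test_far_field_reverts_to_constant_mean(self):
        pts = self._centroids(n=8)
        vals = np.linspace(0.2, 0.6, 8)
        s = interpolate_surface(
            pts, vals, gp_config=GPConfig(range_km=2.0, marginal_sd=0.2, nugget=1e-8)
        )
        far = predict_surface_at(s, np.array([[500 + 2.0 * 100, 500.0]]))
        assert far[0] == pytest.approx(vals.mean(), abs=1e-2)

    def test_adding_constant_shifts_surface(self):
        pts = self._centroids(n=9, seed=3)
        vals = np.cos(pts[:, 0]) * 0.2 + 0.4
        cfg = GPConfig(range_km=4.0, marginal_sd=0.3, nugget=1e-6)
        grid = GridSpec.from_bbox(500, 500, 510, 510, n=10)
        s1 = interpolate_surface(pts, vals, grid, cfg)
        s2 = interpolate_surface(pts, vals + 5.0, grid, cfg)
        assert np.allclose(s2.values - s1.values, 5.0, atol=1e-6)

    def test_duplicate_centroids_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [2.0, 0.5]])
        with pytest.raises(ValueError, match="duplicate"):
            interpolate_surface(pts, np.arange(4.0))
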