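"""Synthetic region generator: determinism, calibration and field structure."""

import math

import numpy as np
import pandas as pd
import pytest

from spatialenroll.spatial_structure import icar_structure
from spatialenroll.synthetic_region import (
    SimulationConfig,
    assign_enrollment,
    generate_insurants,
    generate_region,
    sample_icar_field,
    simulate_dataset,
)


class TestGenerateRegion:
    def test_lattice_shape_and_edges(self):
        areas, graph, cov = generate_region(SimulationConfig(n_rows=10, n_cols=10, seed=3))
        assert len(areas) == 100
        assert len(graph.edges) == 180  # 2 * 10 * 9 grid edges
        assert len(cov) == 100

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_rows=4, n_cols=4, seed=1)
        a1, g1, c1 = generate_region(cfg)
        a2, g2, c2 = generate_region(SimulationConfig(n_rows=4, n_cols=4, seed=1))
        assert [a.n_insurants for a in a1] == [a.n_insurants for a in a2]
        assert g1.edges == g2.edges
        pd.testing.assert_frame_equal(c1, c2)

    def test_total_insurants_near_poisson_mean(self):
        areas, _, _ = generate_region(
            SimulationConfig(n_rows=10, n_cols=10, mean_insurants_per_area=300, seed=7)
        )
        total = sum(a.n_insurants for a in areas)
        assert abs(total - 30_000) < 3 * math.sqrt(30_000)

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_rows=0, n_cols=5)


class TestICARField:
    def test_zero_sd_gives_zero_field(self, demo_dataset):
        f = sample_icar_field(demo_dataset.graph, 0.0, seed=1)
        assert np.array_equal(f, np.zeros(100))

    def test_component_means_are_zero(self, demo_dataset):
        f = sample_icar_field(demo_dataset.graph, 1.0, seed=2)
        assert f.mean() == pytest.approx(0, abs=1e-10)
        assert f.std() == pytest.approx(1.0)

    def test_positive_spatial_autocorrelation(self):
        # Moran's I of the structured field is positive in nearly all draws
        areas, graph, _ = generate_region(SimulationConfig(n_rows=20, n_cols=20, seed=5))
        W = graph.adjacency_matrix()
        n = graph.n_areas
        s0 = W.sum()
        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            f = sample_icar_field(graph, 1.0, seed=1000 + s)
            z = f - f.mean()
            moran = (n / s0) * (z @ (W @ z)) / (z @ z)
            hits += moran > 0
        assert hits >= 95

    def test_negative_sd_rejected(self, demo_dataset):
        with pytest.raises(ValueError):
            sample_icar_field(demo_dataset.graph, -1.0, seed=0)


class TestGenerateInsurants:
    def test_diabetic_fraction_matches_prevalence_target(self):
        # target 17.3% of insurants with type 2 diabetes
        cfg = SimulationConfig(n_rows=10, n_cols=10, mean_insurants_per_area=320, seed=9)
        areas, graph, cov = generate_region(cfg)
        ins = generate_insurants(areas, cov, cfg)
        assert len(ins) >= 30_000
        assert 0.15 <= ins["diabetic"].mean() <= 0.20

    def test_fixed_seed_identical_roster(self):
        cfg = SimulationConfig(n_rows=5, n_cols=5, seed=4)
        areas, graph, cov = generate_region(cfg)
        r1 = generate_insurants(areas, cov, cfg)
        r2 = generate_insurants(areas, cov, cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_age_range_and_enrollment_undefined_before_assignment(self):
        cfg = SimulationConfig(n_rows=4, n_cols=4, seed=2)
        areas, graph, cov = generate_region(cfg)
        ins = generate_insurants(areas, cov, cfg)
        assert ins["age"].between(18, 100).all()
        assert ins["enrolled"].isna().all()


class TestAssignEnrollment:
    @staticmethod
    def _null_config(**kw):
        zero = {k: 1.0 for k in SimulationConfig().enrollment_coefficients}
        return SimulationConfig(
            n_rows=7,
            n_cols=7,
            mean_insurants_per_area=600,
            spatial_sd_structured=0,
            spatial_sd_unstructured=0,
            enrollment_coefficients=zero,
            **kw,
        )

    def test_logistic_zero_gives_half(self):
        cfg = self._null_config(enrollment_intercept=0.0, seed=11)
        areas, graph, cov = generate_region(cfg)
        ins = generate_insurants(areas, cov, cfg)
        out = assign_enrollment(ins, cov, cfg)
        d = out[out["diabetic"] == 1]
        assert len(d) > 3_000
        assert (1 - d["enrolled"]).mean() == pytest.approx(0.5, abs=0.02)

    def test_intercept_calibration_hits_published_rate(self):
        # intercept logit(0.368) with all else null -> 36.8% unenrolled
        cfg = self._null_config(
            enrollment_intercept=math.log(0.368 / 0.632), seed=12
        )
        areas, graph, cov = generate_region(cfg)
        ins = generate_insurants(areas, cov, cfg)
        out = assign_enrollment(ins, cov, cfg)
        d = out[out["diabetic"] == 1]
        assert (1 - d["enrolled"]).mean() == pytest.approx(0.368, abs=0.03)

    def test_male_odds_ratio_reproduced_at_large_n(self):
        cfg = SimulationConfig(
            n_rows=10,
            n_cols=10,
            mean_insurants_per_area=2000,
            diabetes_target=0.5,
            spatial_sd_structured=0,
            spatial_sd_unstructured=0,
            enrollment_coefficients={
                **{k: 1.0 for k in SimulationConfig().enrollment_coefficients},
                "male": 0.938,
            },
            enrollment_intercept=0.0,
            seed=13,
        )
        ds = simulate_dataset(cfg)
        d = ds.insurants[ds.insurants["diabetic"] == 1]
        tab = pd.crosstab(d["male"], d["enrolled"])
        odds_m = tab.loc[1, 0.0] / tab.loc[1, 1.0]
        odds_f = tab.loc[0, 0.0] / tab.loc[0, 1.0]
        assert odds_m / odds_f == pytest.approx(0.938, abs=0.05)

    def test_non_diabetics_keep_undefined_enrollment(self, demo_dataset):
        ins = demo_dataset.insurants
        assert ins.loc[ins["diabetic"] == 0, "enrolled"].isna().all()
        assert ins.loc[ins["diabetic"] == 1, "enrolled"].notna().all()


class TestSimulateDataset:
    def test_rate_converges_to_target_with_n(self):
        errs = []
        for mean_ins, seed in [(60, 1), (600, 1), (6000, 1)]:
            cfg = SimulationConfig(
                n_rows=5, n_cols=5, mean_insurants_per_area=mean_ins, seed=seed,
                spatial_sd_structured=0, spatial_sd_unstructured=0,
            )
            ds = simulate_dataset(cfg)
            errs.append(abs(ds.unenrollment_rate - cfg.unenrollment_target))
        assert errs[-1] < 0.02
        assert errs[-1] <= errs[0] + 0.01

    def test_area_counts_consistent_with_roster(self, demo_dataset):
        ins = demo_dataset.insurants
        by_area = ins.groupby("area_id")["diabetic"].sum()
        for a in demo_dataset.areas:
            assert a.n_diabetics == by_area.get(a.area_id, 0)
            assert 0 <= a.n_unenrolled <= a.n_diabetics <= a.n_insurants

    def test_ground_truth_carried(self, demo_dataset):
        assert demo_dataset.config.seed == 1
        assert len(demo_dataset.structured_field) == 100
        assert demo_dataset.structured_field.std() == pytest.approx(
            demo_dataset.config.spatial_sd_structured, rel=1e-6
        )
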