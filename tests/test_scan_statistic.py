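"""Kulldorff spatial scan: windows, likelihood ratio, Monte-Carlo inference."""

import math

import numpy as np
import pytest

from spatialenroll.scan_statistic import (
    detect_clusters,
    enumerate_windows,
    monte_carlo_null,
    poisson_llr,
)


def brute_force_max_llr(O, E, distances, max_radius_km):
    """Independent oracle: evaluate every (center, radius) ball exhaustively."""
    n = len(O)
    O_tot = O.sum()
    E = E * O_tot / E.sum()
    best = 0.0
    for c in range(n):
        for r in sorted(set(distances[c])):
            if r > max_radius_km:
                continue
            inside = distances[c] <= r
            O_in, E_in = O[inside].sum(), E[inside].sum()
            O_out, E_out = O_tot - O_in, E.sum() - E_in
            if E_in <= 0 or E_out <= 0:
                continue
            if O_in / E_in <= (O_out / E_out if E_out else np.inf):
                continue
            t1 = O_in * math.log(O_in / E_in) if O_in else 0.0
            t2 = O_out * math.log(O_out / E_out) if O_out else 0.0
            best = max(best, t1 + t2)
    return best


class TestEnumerateWindows:
    def test_zero_radius_gives_singletons(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        ws = enumerate_windows(d, 0.0, ["a", "b"])
        assert [(w.center_area_id, w.member_area_ids) for w in ws] == [
            ("a", ["a"]),
            ("b", ["b"]),
        ]

    def test_collinear_growth(self):
        # centroids at 0, 10, 25 km; from the left end the window grows
        # {A}, {A,B}, {A,B,C} within a 30 km cap
        x = np.array([0.0, 10.0, 25.0])
        d = np.abs(x[:, None] - x[None, :])
        ws = [w for w in enumerate_windows(d, 30.0, ["A", "B", "C"]) if w.center_area_id == "A"]
        assert [w.member_area_ids for w in ws] == [["A"], ["A", "B"], ["A", "B", "C"]]

    def test_members_equal_brute_force_balls(self, rng):
        pts = rng.uniform(0, 10, size=(12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"a{i}" for i in range(12)]
        for w in enumerate_windows(d, 6.0, ids):
            c = ids.index(w.center_area_id)
            ball = {ids[j] for j in range(12) if d[c, j] <= w.radius_km}
            assert set(w.member_area_ids) == ball

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            enumerate_windows(np.zeros((2, 2)), -1.0)


class TestPoissonLLR:
    def test_equal_rates_give_zero(self):
        assert poisson_llr(10, 10, 100, 100) == 0.0

    def test_worked_value(self):
        # 20 * ln 2 + 80 * ln(80/90)
        assert poisson_llr(20, 10, 100, 100) == pytest.approx(4.4403, abs=1e-3)

    def test_all_cases_inside(self):
        assert poisson_llr(100, 50, 100, 100) == pytest.approx(100 * math.log(2))

    def test_low_rate_window_scores_zero(self):
        assert poisson_llr(5, 10, 100, 100) == 0.0

    def test_label_permutation_invariance(self, rng):
        O = rng.poisson(20, size=8).astype(float)
        E = np.full(8, O.sum() / 8)
        pts = rng.uniform(0, 5, size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        perm = rng.permutation(8)
        m1 = brute_force_max_llr(O, E, d, 4.0)
        m2 = brute_force_max_llr(O[perm], E[perm], d[np.ix_(perm, perm)], 4.0)
        assert m1 == pytest.approx(m2, rel=1e-12)


class TestMonteCarloNull:
    def test_seeded_and_nonnegative(self):
        E = np.full(9, 10.0)
        pts = np.array([(i % 3, i // 3) for i in range(9)], float)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ws = enumerate_windows(d, 1.5)
        n1 = monte_carlo_null(90, E, ws, n_sim=200, seed=5)
        n2 = monte_carlo_null(90, E, ws, n_sim=200, seed=5)
        assert np.array_equal(n1, n2)
        assert (n1 >= 0).all()

    def test_default_replication_count_is_9999(self):
        import inspect

        assert inspect.signature(monte_carlo_null).parameters["n_sim"].default == 9999
        assert inspect.signature(detect_clusters).parameters["n_sim"].default == 9999


class TestDetectClusters:
    @staticmethod
    def _lattice(n_side):
        pts = np.array([(i % n_side, i // n_side) for i in range(n_side**2)], float)
        return np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))

    def test_matches_exhaustive_oracle_on_small_maps(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            pts = rng.uniform(0, 8, size=(n, 2))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            E = rng.uniform(5, 30, size=n)
            O = rng.poisson(E).astype(float)
            if O.sum() == 0:
                continue
            cl = detect_clusters(O, E, d, max_radius_km=6.0, n_sim=19, seed=1)
            oracle = brute_force_max_llr(O, E, d, 6.0)
            found = cl[0].llr if cl else 0.0
            assert found == pytest.approx(oracle, rel=1e-10, abs=1e-12)

    def test_injected_cluster_found_with_min_p(self):
        d = self._lattice(10)
        E = np.full(100, 50.0)
        block = [44, 45, 54, 55, 46]
        lam = E.copy()
        lam[block] *= 3
        O = np.random.default_rng(3).poisson(lam).astype(float)
        cl = detect_clusters(O, E, d, max_radius_km=3.0, n_sim=999, seed=0)
        assert cl[0].p_value == pytest.approx(1 / 1000)
        members = {int(a) for a in cl[0].window.member_area_ids}
        assert set(block) <= members

    def test_secondary_clusters_do_not_overlap(self):
        d = self._lattice(10)
        E = np.full(100, 50.0)
        lam = E.copy()
        lam[[0, 1, 10]] *= 3
        lam[[88, 89, 98, 99]] *= 3
        O = np.random.default_rng(4).poisson(lam).astype(float)
        cl = detect_clusters(O, E, d, max_radius_km=2.0, n_sim=99, seed=0)
        seen = set()
        for c in cl:
            assert not (seen & set(c.window.member_area_ids))
            seen |= set(c.window.member_area_ids)
        assert [c.llr for c in cl] == sorted((c.llr for c in cl), reverse=True)

    def test_no_cases_warns_and_returns_empty(self):
        d = self._lattice(3)
        with pytest.warns(UserWarning):
            out = detect_clusters(np.zeros(9), np.full(9, 1.0), d, n_sim=9)
        assert out == []
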