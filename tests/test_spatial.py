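"""Ripley K / Besag L estimators, envelopes and bivariate association."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendrostand.spatial import (
    PointPattern,
    Window,
    besag_l,
    bivariate_k12,
    bivariate_null_envelope,
    csr_envelope,
    ripley_k,
    simulate_csr,
)
from oracles import naive_k, naive_k12

from dendrostand.synthetic import (
    Hardcore,
    Poisson,
    Repulsion,
    SpatialScenario,
    ThomasCluster,
    generate_point_pattern,
)


class TestRipleyK:
    def test_three_point_manual_oracle(self):
        """K(4) for points (0,0),(3,0),(0,4): 4 ordered pairs within 4 m."""
        pat = PointPattern([(0, 0), (3, 0), (0, 4)], Window(40))
        res = ripley_k(pat, d_max=10, step=1.0)
        assert res.k[3] == pytest.approx(math.pi * 40**2 * 4 / 9, rel=1e-12)
        assert res.l[3] == pytest.approx(80 / 3 - 4, rel=1e-12)
        # d = 5 picks up the remaining pair (distance 5, closed inequality)
        assert res.k[4] == pytest.approx(math.pi * 40**2 * 6 / 9, rel=1e-12)

    def test_single_point_is_degenerate_zero(self):
        pat = PointPattern([(1.0, 2.0)], Window(40))
        with pytest.warns(UserWarning):
            res = ripley_k(pat, d_max=5)
        assert res.degenerate
        assert np.all(res.k == 0)

    def test_matches_bruteforce_oracle_on_random_patterns(self, rng):
        win = Window(30.0)
        for _ in range(5):
            n = int(rng.integers(3, 51))
            pat = PointPattern(simulate_csr(n, win, rng), win)
            grid = np.arange(1.0, 11.0)
            res = ripley_k(pat, d_max=10, step=1.0)
            assert np.array_equal(res.k, naive_k(pat.xy, win.area, grid))

    def test_rigid_motion_invariance(self, rng):
        win = Window(40.0)
        xy = simulate_csr(30, Window(15.0), rng)  # keep away from the boundary
        k0 = ripley_k(PointPattern(xy, win), d_max=10).k
        ang = 0.7
        rot = xy @ np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        k1 = ripley_k(PointPattern(rot + np.array([3.0, -2.0]), win), d_max=10).k
        assert np.allclose(k0, k1)

    def test_k_nondecreasing_and_d_max_validation(self, rng):
        win = Window(40.0)
        pat = PointPattern(simulate_csr(60, win, rng), win)
        res = ripley_k(pat, d_max=40)
        assert np.all(np.diff(res.k) >= 0)
        with pytest.raises(ValueError):
            ripley_k(pat, d_max=41)

    def test_isotropic_edge_correction_increases_k(self, rng):
        win = Window(40.0)
        pat = PointPattern(simulate_csr(80, win, rng), win)
        plain = ripley_k(pat, d_max=30).k
        corrected = ripley_k(pat, d_max=30, edge_correction="isotropic").k
        assert np.all(corrected >= plain)
        # correction brings mean K closer to the CSR expectation pi d^2 at
        # large distances, where edge losses bite
        d = np.arange(1.0, 31.0)
        assert abs(corrected[-1] - math.pi * 30**2) < abs(plain[-1] - math.pi * 30**2)


class TestBesagL:
    def test_csr_identity_and_empty_count(self):
        d = np.arange(1.0, 6.0)
        assert np.allclose(besag_l(math.pi * d**2, d), 0.0)
        assert besag_l(np.array([0.0]), np.array([5.0]))[0] == -5.0

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            besag_l(np.array([-1.0]), np.array([1.0]))

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_transform_inverts(self, ks):
        k = np.asarray(ks)
        d = np.arange(1.0, len(k) + 1)
        l = besag_l(k, d)
        assert np.allclose(math.pi * (l + d) ** 2, k, atol=1e-6)


class TestCsrEnvelope:
    def test_thomas_cluster_detected(self):
        pat = generate_point_pattern(SpatialScenario(
            n_per_class={"A": 100},
            process_per_class={"A": ThomasCluster(parent_intensity=4e-4, cluster_sd=2.0)},
            seed=1))
        res = csr_envelope(pat, d_max=15, seed=11)
        assert "clustered" in res.classification[1:10]

    def test_hardcore_detected_regular(self):
        pat = generate_point_pattern(SpatialScenario(
            n_per_class={"A": 60}, process_per_class={"A": Hardcore(6.0)}, seed=1))
        res = csr_envelope(pat, d_max=10, seed=12)
        assert "regular" in res.classification[0:5]

    def test_envelope_ordering_and_params(self, rng):
        win = Window(40.0)
        pat = PointPattern(simulate_csr(50, win, rng), win)
        res = csr_envelope(pat, n_sims=39, level=0.9, d_max=20, seed=3)
        assert np.all(res.envelope_low <= res.envelope_high)
        assert res.n_simulations == 39
        with pytest.raises(ValueError):
            csr_envelope(pat, n_sims=10)
        with pytest.raises(ValueError):
            csr_envelope(pat, level=1.2)


class TestBivariate:
    def test_two_point_cross_pair(self):
        pat = PointPattern([(0, 0), (0, 10)], Window(40), ["A", "B"])
        res = bivariate_k12(pat, "A", "B", d_max=10, step=1.0)
        assert res.k[4] == 0.0  # K12(5): no cross pairs within 5 m
        area = math.pi * 40**2
        assert res.k12_hat[9] == pytest.approx(area)  # single pair at exactly 10 m
        assert res.k[9] == pytest.approx(area)

    def test_symmetric_in_classes(self, rng):
        win = Window(40.0)
        xy = simulate_csr(40, win, rng)
        marks = ["A"] * 25 + ["B"] * 15
        pat = PointPattern(xy, win, marks)
        r1 = bivariate_k12(pat, "A", "B", d_max=20)
        r2 = bivariate_k12(pat, "B", "A", d_max=20)
        assert np.allclose(r1.k, r2.k)

    def test_missing_class_named_in_error(self, rng):
        win = Window(40.0)
        pat = PointPattern(simulate_csr(10, win, rng), win, ["A"] * 10)
        with pytest.raises(ValueError, match="B"):
            bivariate_k12(pat, "A", "B")

    def test_matches_bruteforce_cross_oracle(self, rng):
        win = Window(30.0)
        for _ in range(3):
            n1, n2 = int(rng.integers(3, 26)), int(rng.integers(3, 26))
            xy = simulate_csr(n1 + n2, win, rng)
            pat = PointPattern(xy, win, ["A"] * n1 + ["B"] * n2)
            grid = np.arange(1.0, 11.0)
            res = bivariate_k12(pat, "A", "B", d_max=10)
            expect = naive_k12(xy[:n1], xy[n1:], win.area, grid)
            assert np.array_equal(res.k12_hat, expect)

    def test_planted_repulsion_detected(self):
        pat = generate_point_pattern(SpatialScenario(
            n_per_class={"A": 40, "B": 40},
            process_per_class={"A": Poisson(), "B": Poisson()},
            cross_class_rule=Repulsion(8.0), seed=1))
        res = bivariate_null_envelope(pat, "A", "B", d_max=10, seed=21)
        assert "repulsion" in res.classification[0:8]

    def test_jittered_copy_shows_attraction(self, rng):
        win = Window(40.0)
        a = simulate_csr(50, win, rng)
        b = a + rng.uniform(-0.7, 0.7, a.shape)
        b = b[np.hypot(b[:, 0], b[:, 1]) <= 40]
        pat = PointPattern(np.vstack([a, b]), win, ["A"] * len(a) + ["B"] * len(b))
        res = bivariate_null_envelope(pat, "A", "B", d_max=10, seed=22)
        assert "attraction" in res.classification[:5]
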