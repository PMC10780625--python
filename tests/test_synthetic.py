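"""Generators: determinism, process properties, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from dendrostand.synthetic import (
    AgeCurve,
    ClimateScenario,
    DEFAULT_P_MEANS,
    Hardcore,
    Poisson,
    RingScenario,
    SpatialScenario,
    ThomasCluster,
    climate_signal,
    generate_climate,
    generate_point_pattern,
    generate_ring_series,
    generate_study,
)


class TestPointPatternGenerator:
    def test_empty_and_exact_counts(self):
        pat = generate_point_pattern(SpatialScenario(n_per_class={"A": 0}, seed=1))
        assert pat.n == 0
        pat = generate_point_pattern(SpatialScenario(n_per_class={"A": 10, "B": 7}, seed=1))
        assert pat.mark_counts() == {"A": 10, "B": 7}
        assert np.all(np.hypot(pat.xy[:, 0], pat.xy[:, 1]) <= 40.0)

    def test_hardcore_min_distance_holds(self):
        pat = generate_point_pattern(SpatialScenario(
            n_per_class={"A": 10}, process_per_class={"A": Hardcore(5.0)}, seed=2))
        assert pdist(pat.xy).min() >= 5.0

    def test_infeasible_hardcore_raises(self):
        with pytest.raises(RuntimeError, match="hardcore"):
            generate_point_pattern(SpatialScenario(
                window_radius=5.0, n_per_class={"A": 200},
                process_per_class={"A": Hardcore(2.0)}, seed=3))

    def test_fixed_seed_bit_identical(self):
        s = SpatialScenario(n_per_class={"A": 30, "B": 20},
                            process_per_class={"A": ThomasCluster(5e-4, cluster_sd=2.0)},
                            seed=7)
        assert np.array_equal(generate_point_pattern(s).xy, generate_point_pattern(s).xy)

    def test_thomas_clusters_tighter_than_poisson(self):
        """Mean nearest-neighbour distance of a Thomas pattern falls below the
        range of 200 matched CSR simulations."""
        from scipy.spatial import cKDTree

        def mean_nn(xy):
            d, _ = cKDTree(xy).query(xy, k=2)
            return d[:, 1].mean()

        pat = generate_point_pattern(SpatialScenario(
            n_per_class={"A": 100},
            process_per_class={"A": ThomasCluster(parent_intensity=2.5e-4, cluster_sd=2.0)},
            seed=4))
        obs = mean_nn(pat.xy)
        rng = np.random.default_rng(5)
        sims = []
        for _ in range(200):
            p = generate_point_pattern(SpatialScenario(
                n_per_class={"A": 100}, seed=int(rng.integers(2**31))))
            sims.append(mean_nn(p.xy))
        assert obs < np.mean(sims)

    def test_poisson_intensity_matches(self):
        """Empirical intensity n/A is exact by construction; points uniform:
        mean squared radius ~ R^2/2 over 100 replicates."""
        rng = np.random.default_rng(6)
        msr = []
        for _ in range(100):
            p = generate_point_pattern(SpatialScenario(
                n_per_class={"A": 50}, seed=int(rng.integers(2**31))))
            msr.append(np.mean(p.xy[:, 0] ** 2 + p.xy[:, 1] ** 2))
        assert np.mean(msr) == pytest.approx(40**2 / 2, rel=0.03)


class TestClimateGenerator:
    def test_zero_sd_reproduces_means_exactly(self):
        sc = ClimateScenario(start_year=1990, end_year=1992,
                             p_sds=np.zeros(12), tmax_sds=np.zeros(12), tmin_sds=np.zeros(12))
        clim = generate_climate(sc)
        assert np.allclose(clim.groupby("month")["p_mm"].mean(), DEFAULT_P_MEANS)

    def test_single_year_has_12_rows(self):
        assert len(generate_climate(ClimateScenario(start_year=2000, end_year=2000))) == 12

    def test_long_run_annual_total_within_2pct(self):
        clim = generate_climate(ClimateScenario(start_year=1000, end_year=1999, seed=8))
        annual = clim.groupby("year")["p_mm"].sum().mean()
        assert annual == pytest.approx(644.6, rel=0.02)

    def test_physical_invariants(self):
        clim = generate_climate(ClimateScenario(start_year=1950, end_year=1999, seed=9))
        assert (clim["p_mm"] >= 0).all()
        assert (clim["tmax_c"] >= clim["tmin_c"]).all()
        assert not clim.isna().any().any()

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            generate_climate(ClimateScenario(start_year=2000, end_year=1999))

    def test_seasonality_nov_max_jul_min(self):
        clim = generate_climate(ClimateScenario(start_year=1900, end_year=1999, seed=10))
        monthly = clim.groupby("month")["p_mm"].mean()
        assert monthly.idxmax() == 11 and monthly.idxmin() == 7


class TestRingGenerator:
    def test_noise_free_limit_equals_age_curve(self):
        sc = RingScenario(n_per_class={"Y": 1}, age_range_per_class={"Y": (30, 30)},
                          beta={}, phi=0.0, sigma=0.0, sigma_core=0.0,
                          pith_offset_range=(0, 0), quantize=False, seed=1)
        clim = generate_climate(ClimateScenario(start_year=1950, end_year=1997))
        s = generate_ring_series(sc, clim)[0]
        assert np.allclose(s.widths, sc.age_curve_per_class["Y"](np.arange(1, 31)))
        assert len(s.widths) == 30 and s.last_year == 1997

    def test_ar1_recovered_from_long_series(self):
        """phi = 0.7: lag-1 autocorrelation of log residuals within 0.05."""
        sc = RingScenario(n_per_class={"Y": 1}, age_range_per_class={"Y": (1000, 1000)},
                          age_curve_per_class={"Y": AgeCurve(0.0, 0.1, 1.0)},
                          beta={}, phi=0.7, sigma=0.3, sigma_core=0.0,
                          pith_offset_range=(0, 0), quantize=False, seed=2)
        clim = generate_climate(ClimateScenario(start_year=990, end_year=1997, seed=2))
        s = generate_ring_series(sc, clim)[0]
        resid = np.log(s.widths)
        r = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert r == pytest.approx(0.7, abs=0.05)

    def test_single_regressor_signal_ranks_first(self, climate_1956_1997):
        """beta only on Oct(t-1) precipitation: that regressor has the top
        |correlation| with mean log-detrended width across 50 trees."""
        from dendrostand.climate import build_regressor_matrix

        curve = AgeCurve(2.0, 0.05, 1.0)
        sc = RingScenario(n_per_class={"Y": 50}, age_range_per_class={"Y": (38, 40)},
                          age_curve_per_class={"Y": curve},
                          beta={("p", "oct", True): 0.5}, phi=0.0, sigma=0.15,
                          sigma_core=0.0, pith_offset_range=(0, 0), quantize=False, seed=3)
        series = generate_ring_series(sc, climate_1956_1997)
        logdet = {}
        for s in series:
            cambial = np.arange(1, len(s.widths) + 1)
            logdet[s.core_id] = pd.Series(np.log(s.widths / curve(cambial)), index=s.years)
        mean_log = pd.DataFrame(logdet).mean(axis=1).loc[1960:1997]
        X = build_regressor_matrix(climate_1956_1997, 1960, 1997, "tmax")
        corr = X.apply(lambda c: abs(np.corrcoef(c, mean_log)[0, 1]))
        assert corr.idxmax() == "p_oct_prev"

    def test_widths_positive_and_deterministic(self, climate_1956_1997):
        sc = RingScenario(n_per_class={"M": 5}, seed=4,
                          age_range_per_class={"M": (35, 40)})
        a = generate_ring_series(sc, climate_1956_1997)
        b = generate_ring_series(sc, climate_1956_1997)
        for s, t in zip(a, b):
            assert np.array_equal(s.widths, t.widths)
            assert (s.widths > 0).all()

    def test_climate_coverage_enforced(self):
        sc = RingScenario(n_per_class={"O": 1}, age_range_per_class={"O": (120, 120)}, seed=5)
        clim = generate_climate(ClimateScenario(start_year=1950, end_year=1997))
        with pytest.raises(ValueError, match="climate"):
            generate_ring_series(sc, clim)


class TestDefaultStudy:
    def test_counts_mirror_design(self, study):
        assert len(study.trees) == 111
        assert study.trees["age_class"].value_counts().to_dict() == {"Y": 56, "M": 31, "O": 24}
        assert len(study.series) == 222
        assert len(study.regeneration) == 50
        assert len(study.truth["bad_cores"]) == 26
        assert len(study.truth["surviving_trees"]) == 103
        assert len(study.truth["stunted_trees"]) == 33
        assert len(study.truth["retained_trees"]) == 70
        assert len(study.truth["pith_cores"]) == 25

    def test_age_structure_bimodal_with_30yr_gap(self, study):
        """Old cohort separated from the mature/young block by >= 30 years."""
        ages = np.sort(study.trees["corrected_age"].to_numpy())
        gaps = np.diff(ages)
        assert gaps.max() >= 30

    def test_deterministic_under_seed(self):
        a, b = generate_study(3), generate_study(3)
        pd.testing.assert_frame_equal(a.trees, b.trees)
        assert all(np.array_equal(x.widths, y.widths) for x, y in zip(a.series, b.series))
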