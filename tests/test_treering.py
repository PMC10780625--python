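"""Ring-series statistics, screening rules and age estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendrostand.treering import (
    RingSeries,
    age_structure,
    assign_age_class,
    biometric_screen,
    coefficient_of_variation,
    correlation_with_master,
    cumulative_dib,
    cv_percent,
    estimate_pith_offset,
    first_order_autocorrelation,
    fit_age_correction,
    mean_sensitivity,
    missing_radius,
)


class TestMeanSensitivity:
    @pytest.mark.parametrize(
        "series, expected",
        [([5.0, 5.0, 5.0], 0.0), ([1.0, 3.0, 1.0], 1.0), ([1.0, 2.0], 2.0 / 3.0)],
    )
    def test_hand_computed_values(self, series, expected):
        assert mean_sensitivity(series) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mean_sensitivity([1.0, 0.0, 2.0])

    @given(st.lists(st.floats(1e-3, 1e3), min_size=2, max_size=50))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bounded_between_0_and_2(self, xs):
        assert 0.0 <= mean_sensitivity(xs) <= 2.0


class TestAutocorrelation:
    def test_alternating_series_negative(self):
        assert first_order_autocorrelation([1, 2, 1, 2, 1, 2]) < 0

    def test_linear_ramp_near_one(self):
        assert first_order_autocorrelation(np.arange(1.0, 101.0)) > 0.9

    def test_ar1_estimate_consistent(self, rng):
        n, phi = 10_000, 0.75
        x = np.empty(n)
        x[0] = rng.normal()
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.normal()
        assert first_order_autocorrelation(x + 10) == pytest.approx(phi, abs=0.03)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            first_order_autocorrelation([2.0, 2.0, 2.0])


class TestCrossdatingScreen:
    def test_identical_series_kept(self):
        m = pd.Series(np.sin(np.arange(30.0)) + 2, index=np.arange(1960, 1990))
        r, flag = correlation_with_master(m, m)
        assert r == pytest.approx(1.0) and flag == "keep"

    def test_negated_anomalies_discarded(self):
        yrs = np.arange(1960, 1990)
        m = pd.Series(np.sin(np.arange(30.0)) + 2, index=yrs)
        inv = pd.Series(-(m - m.mean()) + m.mean(), index=yrs)
        r, flag = correlation_with_master(inv, m)
        assert r == pytest.approx(-1.0) and flag == "discard"

    def test_short_overlap_undatable(self):
        a = pd.Series(np.arange(10.0), index=np.arange(1980, 1990))
        b = pd.Series(np.arange(30.0) % 7 + 1, index=np.arange(1960, 1990))
        r, flag = correlation_with_master(a, b, min_overlap=20)
        assert flag == "undatable" and np.isnan(r)


class TestPithOffset:
    def test_sagitta_formula(self):
        assert missing_radius(8.0, 1.0) == pytest.approx(8.5)

    def test_core_reaching_pith(self):
        assert estimate_pith_offset(0.0, 1.0, [1.0, 1.0]) == 0

    def test_concentric_ring_geometry(self):
        """Core stopping 5 mm short of the pith of perfectly circular rings,
        inner widths 1 mm: arc of the innermost visible ring (radius 5)."""
        r = 5.0
        h = 0.8
        chord = 2 * np.sqrt(2 * r * h - h**2)
        assert estimate_pith_offset(chord, h, np.ones(5)) == 5

    def test_invalid_sagitta(self):
        with pytest.raises(ValueError):
            estimate_pith_offset(8.0, 0.0, [1.0])


class TestAgeCorrection:
    def test_exact_line_hits_printed_range(self):
        """Differences on the line 16 - 0.1*age predict 15 years at age 10
        and 3 years at age 130."""
        ages = np.arange(10, 140, 10)
        pairs = np.column_stack([ages, 16.0 - 0.1 * ages])
        model = fit_age_correction(pairs)
        assert model.predict(10) == 15
        assert model.predict(130) == 3

    def test_constant_differences(self):
        model = fit_age_correction([(20, 7.0), (50, 7.0), (90, 7.0)])
        assert model.intercept == pytest.approx(7.0)
        assert model.slope == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_recovery(self, rng):
        ages = rng.uniform(10, 140, 50)
        diffs = 16 - 0.1 * ages + rng.normal(0, 1.0, 50)
        model = fit_age_correction(np.column_stack([ages, diffs]))
        se = 1.0 / np.sqrt(np.sum((ages - ages.mean()) ** 2))
        assert abs(model.slope + 0.1) < 2 * se

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_age_correction([(50, 5.0), (50, 6.0), (50, 7.0)])


class TestAgeClasses:
    @pytest.mark.parametrize("age, label", [(40, "Y"), (41, "M"), (80, "M"), (81, "O"), (0, "Y")])
    def test_adult_boundaries(self, age, label):
        assert assign_age_class(age) == label

    def test_regeneration_rule(self):
        assert assign_age_class(3, adult=False) == "ER"
        assert assign_age_class(2, adult=False) is None


class TestBiometricScreen:
    @staticmethod
    def _trees():
        rng = np.random.default_rng(1)
        n = 20
        df = pd.DataFrame(
            {
                "dbh": rng.normal(30, 1.0, n),
                "h": rng.normal(12, 0.5, n),
                "cw": rng.normal(40, 2.0, n),
                "age": np.full(n, 55.0),
            },
            index=[f"T{i}" for i in range(n)],
        )
        return df

    def test_tree_above_mean_everywhere_kept(self):
        df = self._trees()
        df.loc["T0", ["dbh", "h", "cw"]] = [35, 14, 50]
        res = biometric_screen(df, {t: 30 for t in df.index})
        assert res.loc["T0", "keep"]

    def test_exactly_20_rings_discarded(self):
        df = self._trees()
        rings = {t: 30 for t in df.index}
        rings["T1"] = 20  # "more than 20" is strict
        res = biometric_screen(df, rings)
        assert not res.loc["T1", "keep"] and not res.loc["T1", "rings_ok"]

    def test_stunted_on_all_three_removed(self):
        df = self._trees()
        df.loc["T2", ["dbh", "h", "cw"]] = [10, 5, 10]
        res = biometric_screen(df, {t: 30 for t in df.index})
        assert not res.loc["T2", "keep"]

    def test_single_tree_bin_passes_flagged(self):
        df = self._trees()
        df.loc["T3", "age"] = 95.0
        res = biometric_screen(df, {t: 30 for t in df.index})
        assert res.loc["T3", "keep"] and res.loc["T3", "single_bin_flag"]


class TestDibAndHistogram:
    def test_dib_doubles_cumulative_width(self):
        assert np.array_equal(cumulative_dib([1.0, 1.0, 1.0]), [2.0, 4.0, 6.0])

    def test_dib_strictly_increasing(self, rng):
        w = rng.uniform(0.1, 4.0, 80)
        assert np.all(np.diff(cumulative_dib(w)) > 0)

    def test_histogram_conserves_total(self, rng):
        ages = rng.integers(5, 140, 111)
        h = age_structure(ages, bin_width=5)
        assert h["count"].sum() == 111

    def test_single_tree_histogram(self):
        h = age_structure([50], bin_width=5)
        assert len(h) == 1 and h.loc[0, "midpoint"] == 52.5 and h.loc[0, "count"] == 1

    def test_slow_cohort_dib_below_fast_cohort(self):
        """Trees grown on a slower age curve accumulate less diameter at
        every common cambial age."""
        from dendrostand.synthetic import AgeCurve

        ages = np.arange(1, 61)
        fast = cumulative_dib(AgeCurve(3.0, 0.03, 1.3)(ages))
        slow = cumulative_dib(AgeCurve(1.8, 0.10, 0.8)(ages))
        assert np.all(slow < fast)


class TestCoefficientOfVariation:
    def test_from_values_and_constant(self):
        assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0
        v = [1.0, 2.0, 3.0]
        assert coefficient_of_variation(v) == pytest.approx(100 * np.std(v, ddof=1) / 2.0)

    def test_from_printed_summary_stats(self):
        assert round(cv_percent(12.56, 6.61), 1) == 52.6
        assert round(cv_percent(27.61, 6.44), 1) == 23.3

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_percent(0.0, 1.0)


class TestRingSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            RingSeries("t", "c", 1990, np.array([1.0, -0.5]))
        s = RingSeries("t", "c", 1990, np.array([1.0, 2.0]), pith_offset_rings=3)
        assert s.last_year == 1991
        assert s.mean_ring_width == pytest.approx(1.5)
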