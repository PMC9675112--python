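"""Biweekly metrics, semivariograms, ordinary kriging, pregnancy averages."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from npbmix.kriging import (
    VariogramModel,
    assign_pregnancy_exposure,
    biweekly_aggregate,
    biweekly_periods,
    daily_8h_max,
    empirical_semivariogram,
    fit_variogram,
    krige_point,
    pregnancy_average,
)
from npbmix.synthetic import SpatialFieldSpec, simulate_monitors


def brute_force_8h_max(hours):
    """Independent enumeration of all 17 windows (>= 6 valid hours each)."""
    hours = np.asarray(hours, float)
    best = -np.inf
    for s in range(17):
        w = hours[s : s + 8]
        ok = np.isfinite(w)
        if ok.sum() >= 6:
            best = max(best, w[ok].mean())
    return best if np.isfinite(best) else float("nan")


class TestDaily8hMax:
    def test_constant_series(self):
        assert daily_8h_max([40.0] * 24) == pytest.approx(40.0)

    def test_ascending_hours_max_window(self):
        # hours 1..24: best window is the last 8 hours, mean 20.5
        assert daily_8h_max(np.arange(1.0, 25.0)) == pytest.approx(20.5)

    def test_all_missing_returns_sentinel(self):
        assert np.isnan(daily_8h_max([np.nan] * 24))

    def test_incomplete_day_returns_sentinel(self):
        v = np.arange(24.0)
        v[:7] = np.nan  # 17 valid hours < 18
        assert np.isnan(daily_8h_max(v))

    def test_matches_brute_force_with_missingness(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            v = rng.uniform(0, 80, 24)
            v[rng.random(24) < 0.15] = np.nan
            got = daily_8h_max(v)
            want = brute_force_8h_max(v) if np.isfinite(v).sum() >= 18 else float("nan")
            assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)


class TestBiweeklyAggregate:
    def test_constant_window(self):
        assert biweekly_aggregate([7.5] * 14) == pytest.approx(7.5)

    def test_alternating_symmetry(self):
        assert biweekly_aggregate([6.0, 8.0] * 7) == pytest.approx(7.0)

    def test_partial_availability(self):
        v = list(range(1, 11)) + [np.nan] * 4
        assert biweekly_aggregate(v) == pytest.approx(5.5)

    def test_empty_window_sentinel(self):
        assert np.isnan(biweekly_aggregate([np.nan] * 14))

    def test_periods_anchor(self):
        periods = biweekly_periods(date(2009, 1, 5), date(2009, 2, 1))
        assert periods[0] == (date(2009, 1, 1), date(2009, 1, 14))
        assert all((b - a).days == 13 for a, b in periods)


class TestEmpiricalSemivariogram:
    def test_constant_field_zero_semivariance(self):
        coords = np.array([[0, 0], [1, 0], [2, 0], [0, 3]])
        emp = empirical_semivariogram(coords, np.full(4, 5.0), [0, 2, 4])
        assert (emp.loc[emp["n_pairs"] > 0, "semivariance"] == 0).all()

    def test_two_monitor_hand_value(self):
        emp = empirical_semivariogram(np.array([[0, 0], [1, 0]]), np.array([0.0, 2.0]), [0, 2])
        assert emp["semivariance"].iloc[0] == pytest.approx(2.0)
        assert emp["n_pairs"].iloc[0] == 1

    def test_line_matches_pair_enumeration(self):
        coords = np.array([[float(i), 0.0] for i in range(5)])
        values = np.array([0.0, 1.0, 2.0, 3.0, 4.0]) * 1.5
        edges = [0.0, 1.5, 2.5, 3.5, 4.5]
        emp = empirical_semivariogram(coords, values, edges)
        # brute-force pair loop oracle
        for b, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            acc, cnt = 0.0, 0
            for i in range(5):
                for j in range(i + 1, 5):
                    d = abs(coords[i, 0] - coords[j, 0])
                    if lo <= d < hi:
                        acc += (values[i] - values[j]) ** 2
                        cnt += 1
            assert emp["n_pairs"].iloc[b] == cnt
            if cnt:
                assert emp["semivariance"].iloc[b] == pytest.approx(acc / (2 * cnt))

    def test_empty_bin_reported(self):
        emp = empirical_semivariogram(np.array([[0, 0], [1, 0]]), np.array([1.0, 2.0]), [0, 0.5, 2])
        assert emp["n_pairs"].iloc[0] == 0 and np.isnan(emp["semivariance"].iloc[0])


class TestFitVariogram:
    def test_exact_recovery_from_noiseless_points(self):
        truth = VariogramModel("exponential", nugget=0.0, partial_sill=1.0, range_km=5.0)
        h = np.linspace(0.5, 20, 12)
        emp = pd.DataFrame(
            {"lag": h, "semivariance": truth.semivariance(h), "n_pairs": 10}
        )
        fit = fit_variogram(emp, "exponential")
        assert fit.nugget == pytest.approx(0.0, abs=1e-4)
        assert fit.partial_sill == pytest.approx(1.0, abs=1e-4)
        assert fit.range_km == pytest.approx(5.0, abs=1e-3)

    def test_flat_variogram_pure_nugget(self):
        emp = pd.DataFrame({"lag": [1, 2, 3, 4.0], "semivariance": 0.7, "n_pairs": 5})
        fit = fit_variogram(emp)
        assert fit.semivariance(0.0) + 0.0 == pytest.approx(0.7, abs=1e-3)
        assert fit.semivariance(100.0) == pytest.approx(0.7, abs=2e-2)

    def test_too_few_bins_raises(self):
        emp = pd.DataFrame({"lag": [1.0], "semivariance": [0.5], "n_pairs": [3]})
        with pytest.raises(ValueError, match="non-empty"):
            fit_variogram(emp)


@pytest.fixture
def model():
    return VariogramModel("exponential", nugget=0.0, partial_sill=2.0, range_km=4.0)


class TestKrigePoint:
    def test_exact_interpolation_zero_nugget(self, model):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, (6, 2))
        values = rng.uniform(20, 60, 6)
        for i in range(6):
            pred, var = krige_point(model, coords, values, coords[i])
            assert pred == pytest.approx(values[i], abs=1e-8)

    def test_single_monitor(self, model):
        pred, var, w = krige_point(model, [[0.0, 0.0]], [7.0], (5.0, 5.0), return_weights=True)
        assert pred == 7.0 and w[0] == 1.0

    def test_two_equidistant_monitors_split_weights(self, model):
        coords = np.array([[-1.0, 0.0], [1.0, 0.0]])
        values = np.array([10.0, 30.0])
        pred, var, w = krige_point(model, coords, values, (0.0, 2.0), return_weights=True)
        assert w == pytest.approx([0.5, 0.5], abs=1e-10)
        assert pred == pytest.approx(20.0)
        assert var >= 0

    def test_weights_sum_to_one(self, model):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 20, (8, 2))
        values = rng.uniform(0, 100, 8)
        for _ in range(10):
            _, _, w = krige_point(model, coords, values, rng.uniform(0, 20, 2), return_weights=True)
            assert w.sum() == pytest.approx(1.0, abs=1e-8)

    def test_translation_equivariance(self, model):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 20, (7, 2))
        values = rng.uniform(0, 10, 7)
        target = (4.0, 9.0)
        p0, _ = krige_point(model, coords, values, target)
        p1, _ = krige_point(model, coords, values + 123.0, target)
        assert p1 == pytest.approx(p0 + 123.0, abs=1e-8)

    def test_duplicate_monitors_deduplicated(self, model):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
        values = np.array([10.0, 20.0, 5.0])
        pred, _ = krige_point(model, coords, values, (0.0, 0.0))
        assert pred == pytest.approx(15.0, abs=1e-8)  # co-located pair averaged


class TestPregnancyAverage:
    def periods(self, n, start=date(2010, 1, 1)):
        return [
            (start + timedelta(days=14 * k), start + timedelta(days=14 * k + 13))
            for k in range(n)
        ]

    def test_constant_series(self):
        pp = self.periods(20)
        v = [3.3] * 20
        got = pregnancy_average(pp, v, date(2010, 2, 1), date(2010, 9, 1))
        assert got == pytest.approx(3.3)

    def test_two_equal_periods(self):
        pp = self.periods(2)
        got = pregnancy_average(pp, [40.0, 50.0], pp[0][0], pp[1][1])
        assert got == pytest.approx(45.0)

    def test_day_weighted_overlap(self):
        pp = self.periods(2)
        conception = pp[0][0]
        delivery = conception + timedelta(days=20)  # 14 days of A, 7 of B
        got = pregnancy_average(pp, [10.0, 16.0], conception, delivery)
        assert got == pytest.approx(12.0)

    def test_no_overlap_sentinel(self):
        pp = self.periods(2)
        assert np.isnan(
            pregnancy_average(pp, [1.0, 2.0], date(2012, 1, 1), date(2012, 9, 1))
        )

    def test_bounded_by_contributing_values(self):
        rng = np.random.default_rng(4)
        pp = self.periods(25)
        v = rng.uniform(10, 90, 25)
        got = pregnancy_average(pp, v, date(2010, 3, 10), date(2010, 11, 28))
        assert v.min() <= got <= v.max()


def test_assignment_chain_constant_field():
    """End to end: constant spatial field -> every pregnancy average = mean."""
    spec = SpatialFieldSpec(sill=0.0, nugget=1e-12, mean=50.0)
    monitors = simulate_monitors(5, (0, 20, 0, 20), spec, n_days=300, seed=7)
    targets = pd.DataFrame(
        {
            "dyad_id": [1, 2],
            "x_km": [5.0, 12.0],
            "y_km": [5.0, 7.0],
            "conception_date": [date(2009, 2, 1), date(2009, 3, 1)],
            "delivery_date": [date(2009, 10, 1), date(2009, 11, 1)],
        }
    )
    out = assign_pregnancy_exposure(monitors, targets)
    assert np.allclose(out["pregnancy_avg"], 50.0, atol=1e-5)
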