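import numpy as np
import pytest
from scipy import optimize

from pyrograss.fire_frequency import (
    LN2,
    BreakpointRegression,
    CensoredWeibull,
    FireHistory,
    IntervalSet,
    classify_fire_prone,
    extract_intervals,
    filter_fri_bounds,
    fit_breakpoint,
    median_fri,
    pool_species_intervals,
    proportion_burned,
)

import pandas as pd

WINDOW = (2000.25, 2020.08)


class TestExtractIntervals:
    def test_known_history(self):
        h = FireHistory("p", *WINDOW, burn_dates=[2005.0, 2010.0, 2018.0])
        iv = extract_intervals(h)
        np.testing.assert_allclose(sorted(iv.complete), [5.0, 8.0])
        np.testing.assert_allclose(iv.recurrence, [4.75])
        np.testing.assert_allclose(iv.censored, [2.08], atol=1e-9)

    def test_single_fire_at_midpoint(self):
        mid = 0.5 * (WINDOW[0] + WINDOW[1])
        iv = extract_intervals(FireHistory("p", *WINDOW, burn_dates=[mid]))
        assert iv.n_complete == 0
        np.testing.assert_allclose(sorted(iv.open_tailed), [mid - WINDOW[0]] * 2)

    def test_no_fires_whole_window_censored(self):
        iv = extract_intervals(FireHistory("p", *WINDOW))
        assert iv.n_complete == 0
        np.testing.assert_allclose(iv.open_tailed, [WINDOW[1] - WINDOW[0]])

    def test_duration_conserved(self, rng):
        for _ in range(20):
            k = rng.integers(0, 8)
            dates = np.sort(rng.uniform(*WINDOW, size=k))
            iv = extract_intervals(FireHistory("p", *WINDOW, burn_dates=dates))
            total = iv.complete.sum() + iv.open_tailed.sum()
            np.testing.assert_allclose(total, WINDOW[1] - WINDOW[0])

    def test_burn_date_outside_window_rejected(self):
        with pytest.raises(ValueError):
            FireHistory("p", *WINDOW, burn_dates=[1999.0])


class TestPooling:
    def test_two_burnt_locations(self):
        hs = {
            "a": FireHistory("a", *WINDOW, burn_dates=[2005.0, 2010.0, 2015.0]),
            "b": FireHistory("b", *WINDOW, burn_dates=[2003.0, 2012.0, 2019.0]),
        }
        iv = pool_species_intervals(hs, ["a", "b"])
        assert iv.n_complete == 4 and iv.n_censored == 4

    def test_unburnt_location_excluded(self):
        hs = {
            "a": FireHistory("a", *WINDOW, burn_dates=[2005.0, 2010.0]),
            "b": FireHistory("b", *WINDOW),
        }
        iv = pool_species_intervals(hs, ["a", "b"])
        assert iv.n_complete == 1 and iv.n_censored == 2

    def test_empty_mapping(self):
        iv = pool_species_intervals({}, [])
        assert iv.n_complete == 0 and iv.n_censored == 0


def grid_oracle_mle(t_obs, t_cens, b_range, c_range, n=160):
    """Brute-force maximization of the plain censored Weibull likelihood."""

    def nll(b, c):
        val = -np.sum(
            np.log(c / b) + (c - 1) * np.log(t_obs / b) - (t_obs / b) ** c
        )
        if t_cens.size:
            val += np.sum((t_cens / b) ** c)
        return val

    bs = np.linspace(*b_range, n)
    cs = np.linspace(*c_range, n)
    vals = np.array([[nll(b, c) for b in bs] for c in cs])
    i, j = np.unravel_index(np.argmin(vals), vals.shape)
    # local polish with a derivative-free method, still on the same objective
    res = optimize.minimize(
        lambda x: nll(*x), x0=[bs[j], cs[i]], method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12},
    )
    return res.x


class TestCensoredWeibull:
    def test_complete_data_matches_grid_oracle(self):
        t = np.array([2.0, 3.0, 5.0, 7.0])
        est = CensoredWeibull().fit(t)
        b_o, c_o = grid_oracle_mle(t, np.empty(0), (1, 15), (0.3, 8))
        assert abs(est.scale_ - b_o) / b_o < 1e-4
        assert abs(est.shape_ - c_o) / c_o < 1e-4

    def test_right_censored_matches_grid_oracle(self):
        rng = np.random.default_rng(3)
        t = 6 * rng.weibull(1.3, 80)
        cens = rng.random(80) < 0.35
        est = CensoredWeibull().fit(t, ~cens)
        b_o, c_o = grid_oracle_mle(t[~cens], t[cens], (2, 20), (0.3, 6))
        assert abs(est.scale_ - b_o) / b_o < 1e-4
        assert abs(est.shape_ - c_o) / c_o < 1e-4

    def test_complete_data_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        t = 8 * rng.weibull(1.4, 2000)
        cens = rng.random(2000) < 0.3
        est = CensoredWeibull().fit(t, ~cens)
        wf = lifelines.WeibullFitter().fit(t, (~cens).astype(int))
        assert abs(est.scale_ - wf.lambda_) / wf.lambda_ < 1e-4
        assert abs(est.shape_ - wf.rho_) / wf.rho_ < 1e-3

    def test_large_sample_parameter_recovery(self, rng):
        t = 8 * rng.weibull(1.4, 5000)
        est = CensoredWeibull().fit(t)
        assert abs(est.scale_ - 8) / 8 < 0.05
        assert abs(est.shape_ - 1.4) / 1.4 < 0.10

    def test_regular_fires_give_large_shape(self):
        est = CensoredWeibull().fit(np.array([4.0, 4.0, 4.0, 4.0]))
        assert est.shape_ > 100
        assert abs(est.median_fri_ - 4.0) < 0.01

    def test_all_censored_flagged_nonconverged(self):
        est = CensoredWeibull().fit(IntervalSet(censored=[5.0, 7.0, 19.8]))
        assert not est.converged_
        assert np.isnan(est.median_fri_)


class TestMedianFRI:
    def test_exponential_closed_form(self):
        est = CensoredWeibull()
        est.scale_, est.shape_, est.converged_ = 10.0, 1.0, True
        est.median_fri_ = est.scale_ * LN2 ** (1 / est.shape_)
        assert abs(median_fri(est) - 10 * np.log(2)) < 1e-12

    def test_large_shape_limit_is_scale(self):
        est = CensoredWeibull()
        est.scale_, est.shape_, est.converged_ = 7.3, 1e6, True
        assert abs(median_fri(est) - 7.3) < 1e-4 * 7.3

    def test_matches_monte_carlo_median(self, rng):
        b, c = 8.0, 1.3
        draws = b * rng.weibull(c, 1_000_000)
        est = CensoredWeibull()
        est.scale_, est.shape_, est.converged_ = b, c, True
        assert abs(median_fri(est) - np.median(draws)) / np.median(draws) < 0.005

    def test_strictly_increasing_in_scale(self):
        fris = []
        for b in [2.0, 5.0, 9.0, 20.0]:
            est = CensoredWeibull()
            est.scale_, est.shape_, est.converged_ = b, 1.3, True
            fris.append(median_fri(est))
        assert np.all(np.diff(fris) > 0)

    def test_nonconverged_flagged(self):
        est = CensoredWeibull().fit(IntervalSet(censored=[3.0]))
        with pytest.warns(UserWarning):
            assert np.isnan(median_fri(est))


class TestProportionBurned:
    def test_known_fraction(self):
        df = pd.DataFrame({"location_id": [f"l{i}" for i in range(50)]})
        df["species"] = "A"
        lookup = {f"l{i}": i < 13 for i in range(50)}
        assert proportion_burned(df, lookup) == pytest.approx(0.26)

    @pytest.mark.parametrize("burnt, expected", [(True, 1.0), (False, 0.0)])
    def test_extremes(self, burnt, expected):
        df = pd.DataFrame({"location_id": ["a", "b"], "species": "A"})
        assert proportion_burned(df, {"a": burnt, "b": burnt}) == expected

    def test_zero_records_error(self):
        with pytest.raises(ValueError):
            proportion_burned(pd.DataFrame({"location_id": []}), {})


def hinge(x, psi=0.26, a=50.0, s1=200.0, s2=-40.0):
    return a + s1 * np.minimum(x, psi) + s2 * np.maximum(x - psi, 0) + s1 * 0 * x


class TestBreakpoint:
    def test_noiseless_hinge_recovered_exactly(self):
        x = np.linspace(0.0, 1.0, 101)
        y = 50 + 200 * x - 240 * np.clip(x - 0.26, 0, None)
        fit = fit_breakpoint(x, y)
        assert abs(fit.breakpoint - 0.26) < 1e-6
        assert fit.rss < 1e-12

    def test_matches_grid_oracle_rss(self, rng):
        x = np.sort(rng.uniform(0, 1, 60))
        y = 10 + 30 * x - 55 * np.clip(x - 0.4, 0, None) + rng.normal(0, 1.0, 60)
        fit = fit_breakpoint(x, y)
        # independent exhaustive oracle over a fine hinge grid
        best = np.inf
        for psi in np.linspace(x[1], x[-2], 4000):
            design = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0, None)])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            best = min(best, float(np.sum((y - design @ coef) ** 2)))
        assert fit.rss <= best + 1e-8

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(11)
        x = np.sort(rng.uniform(0, 1, 100))
        y = 50 + 200 * x - 240 * np.clip(x - 0.26, 0, None)
        y += rng.normal(0, 0.05 * np.ptp(y), 100)
        fit = fit_breakpoint(x, y)
        assert abs(fit.breakpoint - 0.26) < 0.03

    def test_collinear_data_flagged_degenerate(self):
        x = np.linspace(0, 1, 20)
        fit = fit_breakpoint(x, 2 * x + 1)
        assert fit.degenerate

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            BreakpointRegression().fit([0, 0.5, 1], [1, 2, 3])


class TestFireProneClassification:
    def _profiles(self, props):
        return pd.DataFrame({"proportion_burned": props, "median_fri": 5.0})

    def test_threshold_boundary(self):
        out = classify_fire_prone(self._profiles([0.25, 0.26, 0.9]), 0.26)
        assert list(out["fire_prone"]) == [False, True, True]

    def test_zero_threshold_all_fire_prone(self):
        out = classify_fire_prone(self._profiles([0.0, 0.5]), 0.0)
        assert out["fire_prone"].all()

    @pytest.mark.parametrize("fri, kept", [(101.0, False), (1.0, True), (6.9, True), (0.5, False)])
    def test_fri_bounds(self, fri, kept):
        prof = pd.DataFrame({"median_fri": [fri]})
        out = filter_fri_bounds(prof, 1.0, 100.0)
        assert out["median_fri"].notna().iloc[0] is np.bool_(kept)
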