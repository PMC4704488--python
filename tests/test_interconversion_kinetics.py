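"""Analytic two-state kinetics, rate fitting, timescales, growth comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from mirswitch import (
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    PopulationState,
    RandomSpec,
    SwitchingRates,
    analytic_fraction,
    analytic_population,
    fit_growth,
    fit_rates,
    gen_timecourse,
    switching_timescales,
)

LN2 = math.log(2.0)


def integrate_two_state(rates, H0, L0, t):
    """Independent oracle: Runge-Kutta integration of the raw ODEs."""
    def f(_t, z):
        H, L = z
        return [
            rates.k_div * H - rates.k_hl * H + rates.k_lh * L,
            rates.k_div * L + rates.k_hl * H - rates.k_lh * L,
        ]

    sol = solve_ivp(f, (0.0, t), [H0, L0], rtol=1e-11, atol=1e-12, dense_output=True)
    return sol.y[0, -1], sol.y[1, -1]


class TestAnalyticPopulation:
    def test_pure_growth_doubles_every_division(self):
        rates = SwitchingRates(0.0, 0.0)
        out = analytic_population(rates, PopulationState(H=1, L=0), 3.0)
        assert out.H == pytest.approx(8.0, rel=1e-12)
        assert out.L == pytest.approx(0.0, abs=1e-12)

    def test_time_zero_is_identity(self, rates):
        init = PopulationState(H=3.0, L=7.0)
        out = analytic_population(rates, init, 0.0)
        assert out.H == pytest.approx(init.H, rel=1e-14)
        assert out.L == pytest.approx(init.L, rel=1e-14)

    def test_fraction_relaxes_to_equilibrium(self, rates):
        out = analytic_population(rates, PopulationState(H=1, L=0), 200.0)
        assert out.fraction_high == pytest.approx(0.4, abs=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(
        k_hl=st.floats(0.0, 0.45),
        k_lh=st.floats(0.0, 0.45),
        t=st.floats(0.0, 50.0),
        h0=st.floats(0.1, 10.0),
        l0=st.floats(0.0, 10.0),
    )
    def test_matches_ode_oracle(self, k_hl, k_lh, t, h0, l0):
        rates = SwitchingRates(k_hl, k_lh)
        out = analytic_population(rates, PopulationState(H=h0, L=l0), t)
        H, L = integrate_two_state(rates, h0, l0, t)
        assert out.H == pytest.approx(H, rel=1e-8, abs=1e-8 * (H + L))
        assert out.L == pytest.approx(L, rel=1e-8, abs=1e-8 * (H + L))


class TestAnalyticFraction:
    def test_equilibrium_start_is_constant(self, rates):
        t = np.linspace(0, 30, 7)
        np.testing.assert_allclose(analytic_fraction(rates, 0.4, t), 0.4, atol=1e-12)

    def test_one_relaxation_time(self, rates):
        t = 1.0 / rates.k_sum
        assert analytic_fraction(rates, 1.0, t) == pytest.approx(
            0.4 + 0.6 / math.e, rel=1e-12)

    def test_zero_rates_keep_initial_fraction(self):
        rates = SwitchingRates(0.0, 0.0)
        assert analytic_fraction(rates, 0.7, 100.0) == 0.7

    @settings(derandomize=True, max_examples=40)
    @given(
        k_hl=st.floats(1e-3, 0.45),
        k_lh=st.floats(1e-3, 0.45),
        f0=st.floats(0.0, 1.0),
    )
    def test_agrees_with_population_solution(self, k_hl, k_lh, f0):
        rates = SwitchingRates(k_hl, k_lh)
        for t in (0.5, 3.0, 17.0):
            pop = analytic_population(rates, PopulationState(H=f0, L=1 - f0), t)
            assert analytic_fraction(rates, f0, t) == pytest.approx(
                pop.fraction_high, abs=1e-12)

    def test_equilibrium_reached_after_twenty_relaxation_times(self, rates):
        t = 20.0 / rates.k_sum
        assert analytic_fraction(rates, 1.0, t) == pytest.approx(0.4, abs=1e-8)


class TestFitRates:
    def test_exact_fraction_recovery(self, rates):
        t = np.linspace(0, 25, 12)
        f = analytic_fraction(rates, 1.0, t)
        n = 10**7  # huge counts make the binomial likelihood sharp
        tc = pd.DataFrame({"t_divisions": t, "n_high": np.round(f * n).astype(int),
                           "n_total": n})
        fit = fit_rates(tc, f0=1.0)
        assert fit.k_hl == pytest.approx(rates.k_hl, rel=1e-4)
        assert fit.k_lh == pytest.approx(rates.k_lh, rel=1e-4)

    def test_joint_fit_from_both_purified_starts(self, rates):
        t = np.linspace(0, 20, 20)
        hi, _ = gen_timecourse(rates, 1.0, t, 10_000, RandomSpec(41))
        lo, _ = gen_timecourse(rates, 0.0, t, 10_000, RandomSpec(42))
        fit = fit_rates([hi, lo], f0=[1.0, 0.0])
        assert fit.k_hl == pytest.approx(rates.k_hl, rel=0.15)
        assert fit.k_lh == pytest.approx(rates.k_lh, rel=0.15)
        assert fit.se_hl is not None and fit.se_lh is not None

    def test_monte_carlo_recovery_within_15_percent(self, rates):
        """Both rates within +/-15% in at least 90% of seeded replicates."""
        t = np.linspace(0, 20, 20)
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            hi, _ = gen_timecourse(rates, 1.0, t, 10_000, RandomSpec(rep, "rates-hi"))
            lo, _ = gen_timecourse(rates, 0.0, t, 10_000, RandomSpec(rep, "rates-lo"))
            fit = fit_rates([hi, lo], f0=[1.0, 0.0])
            ok = (abs(fit.k_hl - rates.k_hl) <= 0.15 * rates.k_hl
                  and abs(fit.k_lh - rates.k_lh) <= 0.15 * rates.k_lh)
            hits += ok
        assert hits / n_rep >= 0.90

    def test_estimator_consistency_with_sample_size(self, rates):
        """RMSE of the rate estimate shrinks as cells per timepoint grow."""
        t = np.linspace(0, 20, 15)
        rmse = []
        for n_cells in (100, 1000, 10_000):
            errs = []
            for rep in range(30):
                tc, _ = gen_timecourse(rates, 1.0, t, n_cells,
                                       RandomSpec(rep, f"cons-{n_cells}"))
                fit = fit_rates(tc, f0=1.0)
                errs.append((fit.k_hl - rates.k_hl) ** 2 + (fit.k_lh - rates.k_lh) ** 2)
            rmse.append(math.sqrt(np.mean(errs)))
        assert rmse[0] > rmse[1] > rmse[2]

    def test_least_squares_fallback(self, rates):
        t = np.linspace(0, 25, 12)
        f = analytic_fraction(rates, 1.0, t)
        tc = pd.DataFrame({"t_divisions": t,
                           "n_high": np.round(f * 10**6).astype(int),
                           "n_total": 10**6})
        fit = fit_rates(tc, f0=1.0, method="ls")
        assert fit.k_hl == pytest.approx(rates.k_hl, rel=1e-3)
        assert fit.k_lh == pytest.approx(rates.k_lh, rel=1e-3)

    def test_too_few_timepoints_rejected(self):
        tc = pd.DataFrame({"t_divisions": [0.0, 5.0], "n_high": [100, 60],
                           "n_total": [100, 100]})
        with pytest.raises(InsufficientDataError):
            fit_rates(tc)

    def test_constant_fractions_rejected(self):
        tc = pd.DataFrame({"t_divisions": [0.0, 5.0, 10.0],
                           "n_high": [40, 40, 40], "n_total": [100, 100, 100]})
        with pytest.raises(FitFailureError):
            fit_rates(tc)


class TestSwitchingTimescales:
    def test_fitted_rates_give_14_21_8_divisions(self, rates):
        scales = switching_timescales(rates)
        assert scales["divisions_per_hl_switch"] == 14
        assert scales["divisions_per_lh_switch"] == 21
        assert scales["relaxation_divisions"] == 8

    def test_symmetric_half_rates(self):
        scales = switching_timescales(SwitchingRates(0.5 - 1e-12, 0.5 - 1e-12))
        assert scales["divisions_per_hl_switch"] == 2
        assert scales["relaxation_divisions"] == 1

    def test_zero_rate_gives_infinite_sentinel(self):
        scales = switching_timescales(SwitchingRates(0.1, 0.0))
        assert scales["divisions_per_hl_switch"] == 10
        assert math.isinf(scales["divisions_per_lh_switch"])
        assert scales["relaxation_divisions"] == 10


class TestFitGrowth:
    @staticmethod
    def _counts(rate_a, rate_b, noise_sd, seed):
        gen = RandomSpec(seed, "growth").generator()
        t = np.arange(0.0, 8.0)
        rows = []
        for cond, rate in (("high", rate_a), ("low", rate_b)):
            n = 100 * np.exp(rate * t + gen.normal(0, noise_sd, t.size))
            rows.append(pd.DataFrame({"t_divisions": t, "n_cells": n,
                                      "condition": cond}))
        return pd.concat(rows, ignore_index=True)

    def test_exact_doubling_recovers_ln2(self):
        df = self._counts(LN2, LN2, 0.0, 1)
        out = fit_growth(df)
        for cond in out["conditions"].values():
            assert cond["growth_rate"] == pytest.approx(LN2, rel=1e-9)

    def test_equal_rates_rarely_rejected(self):
        rejections = 0
        for rep in range(40):
            out = fit_growth(self._counts(LN2, LN2, 0.05, 100 + rep))
            rejections += out["slope_equality_p"] <= 0.05
        assert rejections / 40 <= 0.10

    def test_different_rates_detected(self):
        out = fit_growth(self._counts(LN2, 0.5 * LN2, 0.02, 7))
        assert out["slope_equality_p"] < 1e-4

    def test_non_positive_counts_rejected(self):
        df = pd.DataFrame({"t_divisions": [0, 1, 2], "n_cells": [1.0, 0.0, 4.0],
                           "condition": "a"})
        with pytest.raises(InvalidInputError):
            fit_growth(df)

    def test_single_timepoint_rejected(self):
        df = pd.DataFrame({"t_divisions": [0], "n_cells": [100.0], "condition": "a"})
        with pytest.raises(InsufficientDataError):
            fit_growth(df)
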