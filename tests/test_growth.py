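import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bacterivory.growth import (
    AbundanceSeries,
    doubling_time,
    fit_exponential_window,
    fit_lagged_exponential,
    gross_growth_efficiency,
    lag_phase,
    relative_growth_rate,
    summarize_growth,
)
from bacterivory.io import abundance_frame_to_series
from bacterivory.synthetic import TrueParams, simulate_timeseries

TIMES = np.array([0.0, 8.0, 16.0, 27.0, 40.0, 52.0, 66.0])


def make_series(hnf, times=None, bacteria=None, treatment="t", replicate=1, **kw):
    times = TIMES[: len(hnf)] if times is None else np.asarray(times, float)
    bacteria = np.full_like(times, 1e6) if bacteria is None else np.asarray(bacteria, float)
    return AbundanceSeries(treatment, replicate, times, bacteria, np.asarray(hnf, float), **kw)


def paper_regime_replicates(mu=0.0806, lag=1.0, gge=0.33, cv=0.0, seed=0, n_rep=3):
    p = TrueParams(mu_max=mu, lag=lag, gge=gge, count_cv=cv,
                   i_max=2 * mu * 5.0 / (gge * 0.051), seed=seed)
    frames = [simulate_timeseries(p, "t", replicate=r) for r in range(1, n_rep + 1)]
    import pandas as pd

    return abundance_frame_to_series(pd.concat(frames, ignore_index=True))["t"]


class TestExponentialWindow:
    def test_exact_exponential_recovered_with_perfect_fit(self):
        t = np.array([0.0, 8.0, 16.0, 27.0])
        s = make_series(5000 * np.exp(0.08 * t), times=t)
        fit = fit_exponential_window(s)
        assert fit.slope == pytest.approx(0.08, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)
        assert not fit.degraded

    def test_constant_series_has_zero_slope(self):
        fit = fit_exponential_window(make_series([5e3] * 5))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generator_rate_on_noiseless_run(self):
        reps = paper_regime_replicates()
        fit = fit_exponential_window(reps[0])
        assert fit.slope == pytest.approx(0.0806, rel=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_window(make_series([1e3, 2e3]))


class TestSegmentedFit:
    def test_noiseless_run_recovered_exactly(self):
        reps = paper_regime_replicates(mu=0.0806, lag=1.0)
        seg = fit_lagged_exponential(reps)
        assert seg.mu == pytest.approx(0.0806, rel=0.005)
        assert seg.lag == pytest.approx(1.0, abs=0.05)

    def test_replicate_slopes_average_to_pooled_rate(self):
        reps = paper_regime_replicates(cv=0.05, seed=11)
        seg = fit_lagged_exponential(reps)
        assert np.mean(seg.mu_per_replicate) == pytest.approx(seg.mu, rel=1e-9)

    def test_needs_four_sampling_times(self):
        with pytest.raises(ValueError):
            fit_lagged_exponential([make_series([1e3, 2e3, 4e3])])


class TestDoublingTime:
    @pytest.mark.parametrize(
        "mu,expected", [(math.log(2), 1.0), (0.0693147, 10.0), (0.0806, 8.60)]
    )
    def test_closed_form(self, mu, expected):
        assert doubling_time(mu) == pytest.approx(expected, rel=1e-3)

    def test_non_positive_rate_rejected(self):
        for mu in (0.0, -0.1):
            with pytest.raises(ValueError):
                doubling_time(mu)


class TestLagPhase:
    def test_line_through_t0_level_gives_zero_lag(self):
        assert lag_phase(0.08, math.log(5000), 5000) == 0.0

    def test_algebraic_lag(self):
        # ln N = ln 5000 + 0.08 (t - 2)
        assert lag_phase(0.08, math.log(5000) - 0.16, 5000) == pytest.approx(2.0)

    def test_negative_lag_clamped_to_zero(self):
        assert lag_phase(0.08, math.log(5000) + 0.5, 5000) == 0.0

    def test_non_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            lag_phase(0.0, 1.0, 5000)


class TestRelativeGrowth:
    def test_identical_treatments_all_score_100(self):
        s = {t: [make_series(5e3 * np.exp(0.05 * TIMES), treatment=t)] for t in "abc"}
        assert all(v == 100.0 for v in relative_growth_rate(s).values())

    def test_half_the_net_increase_scores_50(self):
        base = 5e3
        ref = base + np.array([0, 15e3, 30e3, 45e3, 45e3, 45e3, 45e3])
        half = base + np.array([0, 7.5e3, 15e3, 22.5e3, 22.5e3, 22.5e3, 22.5e3])
        out = relative_growth_rate(
            {"ref": [make_series(ref, treatment="ref")],
             "half": [make_series(half, treatment="half")]}
        )
        assert out["ref"] == 100.0
        assert out["half"] == pytest.approx(50.0)

    def test_slower_treatment_scores_below_reference(self):
        # compare over the pre-depletion phase, where the mu ratio (1 : 0.9)
        # and not the shared prey capacity separates the treatments
        grid = (0.0, 8.0, 16.0, 27.0)
        series = {}
        for name, mu in (("fast", 0.10), ("slow", 0.09)):
            p = TrueParams(mu_max=mu, lag=1.0, gge=0.33, count_cv=0.0,
                           i_max=2 * 0.10 * 5.0 / (0.33 * 0.051))
            df = simulate_timeseries(p, name, sampling_times=grid)
            series[name] = abundance_frame_to_series(df)[name]
        out = relative_growth_rate(series)
        assert out["fast"] == 100.0
        assert 0 < out["slow"] < 100.0

    def test_all_flat_rejected(self):
        with pytest.raises(ValueError):
            relative_growth_rate({"a": [make_series([5e3] * 5)]})


class TestGge:
    def test_simple_biovolume_quotient(self):
        hnf = np.array([1e3, 2e3, 4e3, 4.5e3])
        bact = np.array([1e6, 8e5, 5e5, 4e5])
        s = make_series(hnf, times=TIMES[:4], bacteria=bact,
                        bact_mcv=np.full(4, 1.0), hnf_mcv=np.full(4, 10.0))
        # gained 35e3 um3, lost 0.6e6 um3
        assert gross_growth_efficiency(s) == pytest.approx(35e3 / 6e5)

    def test_recovers_generator_efficiency(self):
        reps = paper_regime_replicates(gge=0.30)
        assert gross_growth_efficiency(reps[0]) == pytest.approx(0.30, rel=0.05)

    def test_bacterial_regrowth_flags_missing(self):
        hnf = np.array([1e3, 2e3, 4e3])
        bact = np.array([1e6, 1.2e6, 1.5e6])
        s = make_series(hnf, times=TIMES[:3], bacteria=bact,
                        bact_mcv=np.full(3, 1.0), hnf_mcv=np.full(3, 10.0))
        assert math.isnan(gross_growth_efficiency(s))

    def test_missing_biovolumes_rejected(self):
        with pytest.raises(ValueError):
            gross_growth_efficiency(make_series([1e3, 2e3, 4e3]))


class TestSummarize:
    def test_single_replicate_mean_equals_value_sd_zero(self):
        reps = paper_regime_replicates(n_rep=1)
        tab = summarize_growth({"t": reps})
        rep = tab[tab.statistic == "replicate"].iloc[0]
        mean = tab[tab.statistic == "mean"].iloc[0]
        sd = tab[tab.statistic == "sd"].iloc[0]
        assert mean.mu_max == pytest.approx(rep.mu_max)
        assert sd.mu_max == 0.0

    def test_identical_replicates_have_zero_sd(self):
        reps = paper_regime_replicates(n_rep=3)  # noiseless => identical
        tab = summarize_growth({"t": reps})
        assert tab[tab.statistic == "sd"].mu_max.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_triplicates_recover_doubling_time(self):
        reps = paper_regime_replicates(cv=0.05, seed=3)
        tab = summarize_growth({"t": reps})
        dt = tab[tab.statistic == "mean"].doubling_time.iloc[0]
        assert dt == pytest.approx(math.log(2) / 0.0806, rel=0.05)

    def test_doubling_time_times_rate_is_ln2_for_every_replicate_row(self):
        reps = paper_regime_replicates(cv=0.05, seed=9)
        tab = summarize_growth({"t": reps})
        rows = tab[tab.statistic == "replicate"]
        np.testing.assert_allclose(rows.doubling_time * rows.mu_max, math.log(2))

    def test_paper_regime_doubling_times_fall_in_printed_range(self):
        # treatments spanning the observed fastest and slowest responses
        import pandas as pd

        series = {}
        for name, mu in (("fast", math.log(2) / 8.6), ("slow", math.log(2) / 13.0)):
            p = TrueParams(mu_max=mu, lag=1.0, gge=0.33, count_cv=0.05,
                           i_max=2 * mu * 5.0 / (0.33 * 0.051), seed=17)
            frames = [simulate_timeseries(p, name, replicate=r) for r in (1, 2, 3)]
            series[name] = abundance_frame_to_series(pd.concat(frames))[name]
        tab = summarize_growth(series)
        dts = tab[tab.statistic == "mean"].set_index("treatment").doubling_time
        assert 8.6 * 0.93 <= dts["fast"] <= 13.0 * 1.07
        assert 8.6 * 0.93 <= dts["slow"] <= 13.0 * 1.07


@settings(deadline=None, max_examples=25)
@given(st.floats(0.1, 1000.0))
def test_scaling_hnf_counts_leaves_kinetics_unchanged(scale):
    t = TIMES
    hnf = 5e3 * np.exp(0.07 * np.clip(t - 1.5, 0, 30))
    a = fit_exponential_window(make_series(hnf))
    b = fit_exponential_window(make_series(hnf * scale))
    assert b.slope == pytest.approx(a.slope, rel=1e-9, abs=1e-12)
    la = lag_phase(a.slope, a.intercept, hnf[0])
    lb = lag_phase(b.slope, b.intercept, hnf[0] * scale)
    assert lb == pytest.approx(la, rel=1e-6, abs=1e-9)
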