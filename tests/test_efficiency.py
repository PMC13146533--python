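"""Inverse pipeline: θ linearization, time-constant fit, hA and η recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photothermics import (
    LaserProtocol,
    PhotothermalEfficiencyModel,
    TemperatureTrace,
    ThermalSystem,
    compute_eta,
    compute_hA,
    compute_theta,
    estimate_efficiency,
    extract_cooling,
    fit_time_constant,
    make_trace,
    simulate_trace,
    TraceGenSpec,
)
from photothermics.exceptions import (
    DegenerateFitError,
    InsufficientDataError,
    InvalidInputError,
)

from conftest import steady_state_pair


def exp_cooling(tau, ambient=26.3, dT0=35.7, dt=60.0, n=11, label="cool"):
    t = np.arange(n) * dt
    return TemperatureTrace(t, ambient + dT0 * np.exp(-t / tau), label=label)


class TestExtractCooling:
    def test_midpoint_slice_rezeroed(self):
        t = np.arange(20.0)
        trace = TemperatureTrace(t, 25.0 + t)
        cool = extract_cooling(trace, 10.0)
        assert len(cool) == 10
        assert cool.times[0] == 0.0

    def test_off_after_last_sample(self):
        trace = TemperatureTrace([0.0, 1.0, 2.0], [25.0, 26.0, 27.0])
        with pytest.raises(InsufficientDataError):
            extract_cooling(trace, 5.0)

    def test_too_few_post_off_samples(self):
        trace = TemperatureTrace([0.0, 1.0, 2.0, 3.0], [25.0, 26.0, 27.0, 26.0])
        with pytest.raises(InsufficientDataError):
            extract_cooling(trace, 2.5)

    def test_cycle_boundary_slice_matches_construction(self, demo):
        times = np.arange(0.0, 1201.0, 60.0)
        trace = simulate_trace(demo.sample_system, demo.protocol, times)
        cool = extract_cooling(trace, 600.0)
        assert np.array_equal(cool.times, times[10:] - 600.0)
        assert np.array_equal(cool.temps, trace.temps[10:])


class TestComputeTheta:
    def test_endpoints(self):
        cool = TemperatureTrace([0.0, 60.0, 120.0], [62.0, 44.15, 26.3])
        series = compute_theta(cool, ambient_temp=26.3, max_temp=62.0)
        assert series.theta[0] == pytest.approx(1.0)
        assert series.theta[1] == pytest.approx(0.5)
        assert series.n_dropped_low == 1  # the ambient point (theta = 0)

    def test_exponential_identity(self):
        cool = exp_cooling(tau=200.0)
        series = compute_theta(cool, 26.3, 26.3 + 35.7)
        assert np.max(np.abs(series.theta - np.exp(-series.times / 200.0))) < 1e-12

    def test_invalid_max_temp(self):
        with pytest.raises(InvalidInputError):
            compute_theta(exp_cooling(200.0), ambient_temp=62.0, max_temp=26.3)

    def test_all_dropped(self):
        cool = TemperatureTrace([0.0, 60.0], [26.31, 26.30])
        with pytest.raises(InsufficientDataError):
            compute_theta(cool, ambient_temp=26.3, max_temp=62.0)


class TestFitTimeConstant:
    def test_exact_exponential(self):
        series = compute_theta(exp_cooling(200.0), 26.3, 26.3 + 35.7)
        fit = fit_time_constant(series)
        assert fit.tau_s == pytest.approx(200.0, abs=1e-9)
        assert fit.intercept_s == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_through_origin_mode(self):
        series = compute_theta(exp_cooling(200.0), 26.3, 26.3 + 35.7)
        fit = fit_time_constant(series, through_origin=True)
        assert fit.tau_s == pytest.approx(200.0, abs=1e-9)
        assert fit.intercept_s == 0.0

    def test_constant_theta_degenerate(self):
        cool = TemperatureTrace([0.0, 60.0, 120.0], [40.0, 40.0, 40.0])
        series = compute_theta(cool, 26.3, 62.0)
        with pytest.raises(DegenerateFitError):
            fit_time_constant(series)

    def test_noisy_recovery_within_5pct(self):
        """tau=300 s, sigma=0.2 K, 60-s sampling, 10-min window, 100 seeds."""
        rng_taus = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.arange(0.0, 601.0, 60.0)
            temps = 26.3 + 35.7 * np.exp(-t / 300.0) + rng.normal(0, 0.2, t.size)
            series = compute_theta(TemperatureTrace(t, temps), 26.3, 62.0)
            rng_taus.append(fit_time_constant(series).tau_s)
        assert abs(np.mean(rng_taus) - 300.0) / 300.0 < 0.05

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(scale=st.floats(0.1, 50.0), tau=st.floats(50.0, 500.0))
    def test_time_scale_equivariance(self, scale, tau):
        series = compute_theta(exp_cooling(tau), 26.3, 62.0)
        scaled = compute_theta(
            TemperatureTrace(series.times * scale,
                             26.3 + 35.7 * series.theta),
            26.3, 62.0)
        assert fit_time_constant(scaled).tau_s == pytest.approx(
            scale * fit_time_constant(series).tau_s, rel=1e-9)

    def test_theta_floor_insensitive_on_noiseless_data(self):
        cool = exp_cooling(tau=150.0, n=11)
        taus = []
        for floor in (0.05, 0.1):
            series = compute_theta(cool, 26.3, 62.0, theta_floor=floor)
            taus.append(fit_time_constant(series).tau_s)
        assert abs(taus[0] - taus[1]) / taus[0] < 1e-6


class TestScalars:
    def test_compute_hA(self):
        assert compute_hA(300.0, 4.2) == pytest.approx(0.014)
        assert compute_hA(4.2, 4.2) == pytest.approx(1.0)
        with pytest.raises(InvalidInputError):
            compute_hA(-1.0, 4.2)

    def test_hA_tau_round_trip(self):
        hA = compute_hA(287.3, 4.18)
        assert 4.18 / hA == pytest.approx(287.3, rel=1e-12)

    def test_eta_balance_identity(self):
        # hA * dT difference chosen to equal I (1 - 10^-A) exactly
        assert compute_eta(0.02, 55.0, 1.0, 1.2, 1.0) == pytest.approx(
            0.02 * 54.0 / (1.2 * 0.9))
        val = 1.2 * 0.9 / 0.02  # dT difference making eta exactly 1
        assert compute_eta(0.02, val + 1.0, 1.0, 1.2, 1.0) == pytest.approx(1.0)

    def test_eta_zero_numerator(self):
        assert compute_eta(0.015, 0.5, 0.5, 1.2, 1.0) == 0.0

    def test_eta_worked_example(self):
        assert compute_eta(0.015, 35.7, 0.5, 1.2, 1.0) == pytest.approx(0.48889, abs=1e-5)

    def test_eta_zero_absorbance_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_eta(0.015, 35.7, 0.5, 1.2, 0.0)


class TestEstimateEfficiency:
    def test_noiseless_round_trip(self):
        sample, water, sys_, kwargs = steady_state_pair()
        res = estimate_efficiency(sample, water, **kwargs)
        assert res.tau_s == pytest.approx(sys_.tau_s, rel=0.005)
        assert res.hA == pytest.approx(sys_.hA, rel=0.005)
        assert res.eta == pytest.approx(sys_.eta, rel=0.005)
        assert res.fit.r_squared > 0.9999

    @pytest.mark.parametrize("eta_true, tau", [(0.3, 90.0), (0.9, 200.0)])
    def test_round_trip_other_systems(self, eta_true, tau):
        sample, water, sys_, kwargs = steady_state_pair(eta_true=eta_true, tau_s=tau)
        res = estimate_efficiency(sample, water, **kwargs)
        assert res.eta == pytest.approx(eta_true, rel=0.005)
        assert res.tau_s == pytest.approx(tau, rel=0.005)

    def test_water_equals_sample_gives_zero(self):
        sample, _, _, kwargs = steady_state_pair()
        res = estimate_efficiency(sample, sample, **kwargs)
        assert res.eta == 0.0

    def test_ambient_offset_invariance(self):
        sample, water, sys_, kwargs = steady_state_pair()
        res = estimate_efficiency(sample, water, **kwargs)
        shifted = dict(kwargs, ambient_temp=kwargs["ambient_temp"] + 4.0)
        res2 = estimate_efficiency(
            TemperatureTrace(sample.times, sample.temps + 4.0),
            TemperatureTrace(water.times, water.temps + 4.0),
            **shifted)
        assert res2.eta == pytest.approx(res.eta, rel=1e-9)

    def test_noisy_recovery_mean_within_5pct(self, demo):
        errs = []
        for seed in range(40):
            s, _ = make_trace(TraceGenSpec(demo.sample_system, demo.protocol,
                                           noise_sigma_K=0.2, seed=seed))
            w, _ = make_trace(TraceGenSpec(demo.water_system, demo.protocol,
                                           noise_sigma_K=0.2, seed=seed + 50_000))
            res = estimate_efficiency(
                s, w, demo.laser_off_s, demo.sample_system.heat_capacity_total,
                demo.laser_power_W, demo.sample_system.absorbance,
                demo.sample_system.ambient_temp)
            errs.append(abs(res.eta - demo.eta_true) / demo.eta_true)
        assert np.mean(errs) < 0.05

    def test_model_summary_mentions_key_quantities(self):
        sample, water, _, kwargs = steady_state_pair()
        text = PhotothermalEfficiencyModel(sample, water, **kwargs).fit().summary()
        for token in ("tau", "hA", "eta", "R^2"):
            assert token in text
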