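"""Membrane-potential and current statistics: Up-state detection, spike
excision, CV definitions, and the drift-corrected pooled distribution."""

import numpy as np
import pytest
from scipy import integrate

from cortexval.fixtures import updown_vm
from cortexval.subthreshold import (
    AnalogTrace,
    DriftModel,
    UndefinedCVError,
    UpStateInterval,
    balance_regression,
    cv_current_detrended,
    cv_vm,
    detect_up_states,
    estimate_resting_potential,
    excise_spikes,
    pooled_density,
    pooled_std,
    solve_local_sigma,
    time_averaged_cv,
)


class TestDriftModel:
    def test_sigma_zero_is_uniform(self):
        m = DriftModel(400.0, 200.0, 0.0)
        assert pooled_density(300.0, m) == pytest.approx(1.0 / 200.0)
        assert pooled_density(500.0, m) == 0.0

    def test_density_normalizes(self):
        m = DriftModel(400.0, 200.0, 43.0)
        total, _ = integrate.quad(lambda x: pooled_density(x, m), -200.0, 900.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_large_sigma_approaches_normal(self):
        m = DriftModel(400.0, 200.0, 2000.0)
        from scipy.stats import norm

        mid = 300.0
        assert pooled_density(mid, m) == pytest.approx(norm.pdf(0.0, scale=2000.0), rel=0.01)

    @pytest.mark.parametrize("I1, I2, sigma", [(400.0, 200.0, 43.0), (100.0, 350.0, 10.0),
                                               (50.0, 40.0, 80.0)])
    def test_variance_decomposition(self, I1, I2, sigma):
        """Pooled variance = sigma^2 + (I2-I1)^2/12 (quadrature vs closed form)."""
        sd = pooled_std(DriftModel(I1, I2, sigma))
        closed = np.sqrt(sigma**2 + (I2 - I1) ** 2 / 12.0)
        assert sd == pytest.approx(closed, rel=1e-4)

    def test_solve_local_sigma_worked_example(self):
        # overall sd 72 pA with a 400 -> 200 pA linear decay
        sigma = solve_local_sigma(72.0, 400.0, 200.0)
        assert sigma == pytest.approx(43.0, abs=0.5)
        assert sigma == pytest.approx(np.sqrt(72.0**2 - 200.0**2 / 12.0), rel=1e-4)

    def test_solve_local_sigma_limits(self):
        assert solve_local_sigma(30.0, 300.0, 300.0) == 30.0
        boundary = 200.0 / np.sqrt(12.0)
        assert solve_local_sigma(boundary, 400.0, 200.0) == 0.0
        with pytest.raises(ValueError, match="inconsistent"):
            solve_local_sigma(boundary * 0.9, 400.0, 200.0)

    def test_time_averaged_cv(self):
        sigma = solve_local_sigma(72.0, 400.0, 200.0)
        assert time_averaged_cv(sigma, 400.0, 200.0) == pytest.approx(0.15, abs=0.005)
        assert time_averaged_cv(30.0, 300.0, 300.0) == pytest.approx(0.1)
        assert time_averaged_cv(0.0, 400.0, 200.0) == 0.0
        with pytest.raises(ValueError):
            time_averaged_cv(10.0, -5.0, 200.0)

    def test_time_averaged_cv_monotone_and_scale_invariant(self):
        vals = [time_averaged_cv(s, 400.0, 200.0) for s in (10.0, 20.0, 40.0)]
        assert vals == sorted(vals)
        assert time_averaged_cv(43.0, 400.0, 200.0) == pytest.approx(
            time_averaged_cv(4.3, 40.0, 20.0)
        )


class TestCvVm:
    def test_constant_trace_zero(self):
        tr = AnalogTrace(np.full(1000, -55.0), dt=0.1)
        assert cv_vm(tr, UpStateInterval(0.0, 100.0), -70.0) == 0.0

    def test_sinusoid_analytic(self):
        t = 0.1 * np.arange(100_000)
        mu, A = 10.0, 3.0
        tr = AnalogTrace(mu + A * np.sin(2 * np.pi * t / 100.0), dt=0.1)
        got = cv_vm(tr, UpStateInterval(0.0, t[-1]), 0.0)
        assert got == pytest.approx((A / np.sqrt(2)) / mu, rel=1e-3)

    def test_offset_invariance(self, rng):
        vals = -60.0 + rng.normal(0, 2.0, 5000)
        a = cv_vm(AnalogTrace(vals, 0.1), UpStateInterval(0.0, 400.0), -70.0)
        b = cv_vm(AnalogTrace(vals + 13.0, 0.1), UpStateInterval(0.0, 400.0), -57.0)
        assert a == pytest.approx(b, rel=1e-10)

    def test_sign_kept_when_mean_below_rest(self, rng):
        vals = -80.0 + rng.normal(0, 1.0, 5000)
        assert cv_vm(AnalogTrace(vals, 0.1), UpStateInterval(0.0, 400.0), -70.0) < 0

    def test_undefined_at_rest(self):
        tr = AnalogTrace(np.full(1000, -70.0), dt=0.1)
        with pytest.raises(UndefinedCVError):
            cv_vm(tr, UpStateInterval(0.0, 100.0), -70.0)


class TestExciseSpikes:
    def test_no_spikes_identity(self):
        tr = AnalogTrace(np.zeros(1000), dt=0.1)
        out = excise_spikes(tr, [])
        assert out.mask is not None and out.mask.sum() == 0

    def test_mask_is_inclusive_grid_window(self):
        tr = AnalogTrace(np.zeros(1001), dt=0.1)
        out = excise_spikes(tr, [50.0])
        assert out.mask.sum() == 101  # [45.0, 55.0] inclusive at 0.1 ms

    def test_overlapping_windows_merge(self):
        tr = AnalogTrace(np.zeros(1001), dt=0.1)
        out = excise_spikes(tr, [50.0, 54.0])
        assert out.mask.sum() == 141  # union [45, 59] = 14 ms inclusive

    def test_statistics_skip_masked_samples(self):
        vals = np.full(1001, -60.0)
        vals[500:520] = 0.0  # a "spike"
        tr = excise_spikes(AnalogTrace(vals, 0.1), [51.0])
        assert cv_vm(tr, UpStateInterval(0.0, 100.0), -70.0) == 0.0


class TestUpStateDetection:
    @staticmethod
    def _telegraph(up_ms, seed=0):
        trace, _ = updown_vm(1, up_ms=up_ms, down_ms=400.0, noise_sd=0.8, seed=seed)
        return trace

    def test_flat_trace_has_no_up_states(self):
        tr = AnalogTrace(np.full(20_000, -70.0), dt=0.1)
        with pytest.warns(UserWarning, match="bimodality"):
            assert detect_up_states(tr) == []

    def test_single_plateau_recovered(self):
        tr = self._telegraph(600.0)
        states = detect_up_states(tr)
        assert len(states) == 1
        assert states[0].duration == pytest.approx(600.0, abs=60.0)

    def test_short_plateau_rejected(self):
        tr = self._telegraph(300.0)
        assert detect_up_states(tr) == []

    def test_trending_plateau_rejected(self):
        trace, _ = updown_vm(1, up_ms=600.0, down_ms=300.0, noise_sd=0.5, seed=1)
        ramp = np.zeros(trace.values.size)
        i0, i1 = trace.index(300.0), trace.index(900.0)
        ramp[i0:i1] = np.linspace(0.0, 12.0, i1 - i0)  # strong upward trend in the Up state
        trended = AnalogTrace(trace.values + ramp, trace.dt)
        assert detect_up_states(trended) == []


class TestRestingPotential:
    def test_constant_pre_interval(self):
        tr = AnalogTrace(np.full(20_000, -70.0), dt=0.1)
        assert estimate_resting_potential(tr, UpStateInterval(1000.0, 1600.0)) == -70.0

    def test_linear_ramp_mean(self):
        t = 0.1 * np.arange(20_000)
        tr = AnalogTrace(-70.0 + 10.0 * t / 1000.0, dt=0.1)
        got = estimate_resting_potential(tr, UpStateInterval(1000.0, 1600.0))
        assert got == pytest.approx(-70.0 + 10.0 * 0.925, abs=1e-6)  # midpoint 925 ms

    def test_fallback_warns(self):
        trace, _ = updown_vm(2, up_ms=600.0, down_ms=200.0, noise_sd=0.5, seed=2)
        with pytest.warns(UserWarning, match="insufficient"):
            got = estimate_resting_potential(trace, UpStateInterval(50.0, 650.0))
        assert got == pytest.approx(-70.0, abs=1.0)


class TestDetrendedCurrentCv:
    def test_pure_linear_decay_is_zero(self):
        t = 0.05 * np.arange(20_000)
        tr = AnalogTrace(400.0 - 0.2 * t, dt=0.05, kind="exc_current")
        assert cv_current_detrended(tr) == pytest.approx(0.0, abs=1e-12)

    def test_noise_around_decay(self, rng):
        t = 0.05 * np.arange(20_000)
        vals = (400.0 - 0.2 * t) + rng.normal(0.0, 43.0, t.size)
        tr = AnalogTrace(vals, dt=0.05, kind="exc_current")
        assert cv_current_detrended(tr) == pytest.approx(43.0 / 300.0, abs=0.01)

    def test_zero_mean_undefined(self, rng):
        tr = AnalogTrace(rng.normal(0.0, 1.0, 20_000) * 1e-9, dt=0.05, kind="exc_current")
        with pytest.raises(UndefinedCVError):
            cv_current_detrended(tr)


class TestBalanceRegression:
    def test_proportional_currents(self, rng):
        e = 300.0 + rng.normal(0, 40.0, 40_000)
        i = -4.0 * e + rng.normal(0, 5.0, 40_000)
        res = balance_regression(
            AnalogTrace(e, 0.05, "exc_current"), AnalogTrace(i, 0.05, "inh_current")
        )
        assert res.slope == pytest.approx(4.0, rel=0.1)
        assert res.pearson_r > 0.95

    def test_independent_currents_uncorrelated(self, rng):
        e = 300.0 + rng.normal(0, 40.0, 40_000)
        i = -300.0 + rng.normal(0, 40.0, 40_000)
        res = balance_regression(
            AnalogTrace(e, 0.05, "exc_current"), AnalogTrace(i, 0.05, "inh_current")
        )
        assert abs(res.pearson_r) < 0.15

    def test_degenerate_input_rejected(self):
        e = AnalogTrace(np.full(40_000, 300.0), 0.05, "exc_current")
        i = AnalogTrace(np.full(40_000, -300.0), 0.05, "inh_current")
        with pytest.raises(ValueError, match="degenerate"):
            balance_regression(e, i)
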