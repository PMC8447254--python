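"""Per-trace stage: Soumpasis curve, normalization, fitting, ROI extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hydrafrap as hf
from hydrafrap.frap_core import FrapTrace


def make_trace(spot, ref, time=None, n_pre=3):
    spot = np.asarray(spot, dtype=float)
    if time is None:
        time = np.arange(spot.size, dtype=float) - n_pre
    pre = np.asarray(time) < 0
    return FrapTrace(time=time, spot_intensity=spot,
                     reference_intensity=np.asarray(ref, dtype=float),
                     prebleach_mask=pre, normalized=False)


class TestSoumpasisF:
    def test_value_at_tau_matches_series_oracle(self, bessel_oracle):
        # f(tau_d) = e^-2 (I0(2) + I1(2)), evaluated by independent series
        expected = bessel_oracle(2.0)
        assert expected == pytest.approx(0.5237776, abs=1e-6)
        assert hf.soumpasis_f(3.77, 3.77) == pytest.approx(expected, rel=1e-12)

    def test_long_time_limit_is_one(self):
        assert hf.soumpasis_f(1e12, 1.0) == pytest.approx(1.0, abs=1e-5)

    def test_early_time_stable_and_matches_oracle(self, bessel_oracle):
        # t = tau/100 -> argument 2 tau/t = 200; no overflow allowed
        tau = 3.0
        val = hf.soumpasis_f(tau / 100.0, tau)
        assert np.isfinite(val)
        assert val == pytest.approx(bessel_oracle(200.0), rel=1e-10)
        assert val < 0.06

    def test_extreme_argument_no_overflow(self):
        val = hf.soumpasis_f(2e-4, 1.0)  # 2 tau/t = 1e4
        assert 0 < val < 1e-2
        assert np.isfinite(val)

    def test_zero_time_continuous_extension(self):
        assert hf.soumpasis_f(0.0, 1.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hf.soumpasis_f(1.0, 0.0)
        with pytest.raises(ValueError):
            hf.soumpasis_f(-1.0, 1.0)

    @settings(deadline=None, derandomize=True)
    @given(tau=st.floats(0.01, 100.0),
           t1=st.floats(1e-6, 1e4), t2=st.floats(1e-6, 1e4))
    def test_monotone_increasing_and_bounded(self, tau, t1, t2):
        lo, hi = sorted((t1, t2))
        f_lo, f_hi = hf.soumpasis_f(lo, tau), hf.soumpasis_f(hi, tau)
        assert 0.0 <= f_lo <= 1.0 and 0.0 <= f_hi <= 1.0
        if hi > lo:
            assert f_hi >= f_lo


class TestRecoveryModel:
    @pytest.mark.parametrize("a,b,t,tau,expected", [
        (0.0, 0.3, 5.0, 1.0, 0.3),                       # no recovery
        (0.7, 0.3, 1e12, 1.0, 1.0),                      # full recovery limit
        (0.6, 0.2, 3.77, 3.77, 0.2 + 0.6 * 0.5237776),   # at t = tau_d
    ])
    def test_values(self, a, b, t, tau, expected):
        assert hf.recovery_model(t, a, b, tau) == pytest.approx(expected, abs=2e-6)


class TestNormalizeTrace:
    def test_constant_signals_give_unity(self):
        tr = make_trace([5.0] * 15, [5.0] * 15)
        out = hf.normalize_trace(tr)
        assert np.allclose(out.spot_intensity, 1.0)
        assert out.normalized

    def test_common_exponential_decay_cancels(self):
        # acquisition photobleaching affects spot and reference alike;
        # the ratio must be independent of the decay rate
        t = np.arange(20, dtype=float) - 4
        post_shape = np.where(t < 0, 1.0, 0.3)
        results = []
        for k in (0.0, 0.05, 0.2):
            decay = np.exp(-k * (t - t[0]))
            tr = make_trace(1000 * post_shape * decay, 1000 * decay, time=t)
            results.append(hf.normalize_trace(tr).spot_intensity)
        assert np.allclose(results[0], results[1])
        assert np.allclose(results[0], results[2])

    def test_prebleach_scaling(self):
        spot = np.array([250.0] * 3 + [50.0] * 12)
        tr = make_trace(spot, np.ones(15))
        out = hf.normalize_trace(tr)
        assert out.spot_intensity[3] == pytest.approx(0.2)

    def test_double_normalization_is_error(self):
        tr = hf.normalize_trace(make_trace([1.0] * 15, [2.0] * 15))
        with pytest.raises(ValueError, match="already normalized"):
            hf.normalize_trace(tr)

    def test_trace_invariants_enforced(self):
        with pytest.raises(ValueError, match="reference"):
            make_trace([1.0] * 15, [0.0] * 15)
        with pytest.raises(ValueError, match="pre-bleach"):
            FrapTrace(time=np.arange(15.0), spot_intensity=np.ones(15),
                      reference_intensity=np.ones(15),
                      prebleach_mask=np.zeros(15, bool))


class TestFitRecovery:
    def test_noiseless_exact_recovery(self):
        tr = hf.generate_analytic_trace(3.77, a=0.8, b=0.15)
        fit = hf.fit_recovery(hf.normalize_trace(tr), w=5.0)
        assert fit.a == pytest.approx(0.8, rel=1e-6)
        assert fit.b == pytest.approx(0.15, rel=1e-6)
        assert fit.tau_d == pytest.approx(3.77, rel=1e-6)
        assert fit.converged

    def test_d_from_tau_and_w(self):
        tr = hf.generate_analytic_trace(3.77, a=0.8, b=0.15)
        fit5 = hf.fit_recovery(hf.normalize_trace(tr), w=5.0)
        fit10 = hf.fit_recovery(hf.normalize_trace(tr), w=10.0)
        assert fit5.D == pytest.approx(fit5.w ** 2 / (4 * fit5.tau_d), rel=1e-12)
        # doubling the spot radius quadruples D for the same trace
        assert fit10.D == pytest.approx(4.0 * fit5.D, rel=1e-9)

    def test_immobile_fraction_recovered(self):
        # a = 0.465, b = 0.5 -> mobile fraction 0.465 / (1 - 0.5) = 0.93
        tr = hf.generate_analytic_trace(3.77, a=0.465, b=0.5)
        fit = hf.fit_recovery(hf.normalize_trace(tr), w=5.0)
        assert fit.mobile_fraction == pytest.approx(0.93, abs=1e-6)

    def test_parameter_recovery_and_ci_coverage(self):
        # 100 noisy traces: median relative D error <= 5% and the 95%
        # interval on D covers the truth at close-to-nominal rate
        true_tau, w = 3.77, 5.0
        true_d = w ** 2 / (4 * true_tau)
        errors, covered = [], 0
        for seed in range(100):
            tr = hf.generate_analytic_trace(true_tau, a=0.7, b=0.2,
                                            noise_sd=0.02, seed=seed)
            fit = hf.fit_recovery(hf.normalize_trace(tr), w=w)
            errors.append(abs(fit.D - true_d) / true_d)
            if abs(fit.D - true_d) <= fit.ciw_D:
                covered += 1
        assert np.median(errors) <= 0.05
        assert 88 <= covered <= 99

    def test_unnormalized_trace_rejected(self):
        tr = hf.generate_analytic_trace(3.77, a=0.8, b=0.15)
        with pytest.raises(ValueError, match="normalized"):
            hf.fit_recovery(tr, w=5.0)


class TestMobileFraction:
    @pytest.mark.parametrize("a,b,expected", [
        (0.7, 0.3, 1.0),   # a = 1 - b: fully mobile
        (0.0, 0.4, 0.0),
        (0.4, 0.2, 0.5),
    ])
    def test_values(self, a, b, expected, fit_factory):
        fit = fit_factory(1.0)
        fit.a, fit.b = a, b
        assert hf.mobile_fraction(fit) == pytest.approx(expected)

    def test_no_bleach_depth_is_error(self, fit_factory):
        fit = fit_factory(1.0)
        fit.b = 1.0
        with pytest.raises(ValueError, match="bleach depth"):
            hf.mobile_fraction(fit)

    def test_super_unity_clipped_with_warning(self, fit_factory):
        fit = fit_factory(1.0)
        fit.a, fit.b = 0.9, 0.2
        with pytest.warns(UserWarning, match="clipping"):
            assert hf.mobile_fraction(fit) == 1.0


class TestExtractTraceFromStack:
    def test_uniform_image(self):
        stack = np.full((15, 32, 32), 7.0)
        tr = hf.extract_trace_from_stack(stack, center=(16.0, 16.0),
                                         radius_px=5.0, bleach_frame=3,
                                         frame_interval=0.5)
        assert np.allclose(tr.spot_intensity, 7.0)
        assert np.allclose(tr.reference_intensity, 7.0)
        assert tr.time[3] == 0.0 and tr.n_prebleach == 3

    def test_degenerate_and_out_of_field(self):
        stack = np.ones((15, 32, 32))
        with pytest.raises(ValueError, match="radius"):
            hf.extract_trace_from_stack(stack, (16, 16), 0.0,
                                        bleach_frame=3, frame_interval=0.5)
        with pytest.raises(ValueError, match="inside the field"):
            hf.extract_trace_from_stack(stack, (2, 2), 5.0,
                                        bleach_frame=3, frame_interval=0.5)

    def test_matches_simulator_particle_counts(self):
        # the rendered stack and the simulator's own count trace must
        # agree after normalization, up to rasterization of the circle
        params = hf.BrownianSimParams(n_particles=5000, seed=7,
                                      postbleach_frames=40)
        trace, truth = hf.simulate_frap_brownian(params, return_stack=True,
                                                 image_px=120)
        px_per_um = truth["image_px"] / params.box_size
        stack_trace = hf.extract_trace_from_stack(
            truth["stack"],
            center=(truth["image_px"] / 2, truth["image_px"] / 2),
            radius_px=params.bleach_radius * px_per_um,
            bleach_frame=params.prebleach_frames,
            frame_interval=truth["frame_interval"])
        a = hf.normalize_trace(trace).spot_intensity
        b = hf.normalize_trace(stack_trace).spot_intensity
        assert np.max(np.abs(a - b)) < 0.12
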