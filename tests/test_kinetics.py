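"""IPSC measurement, biexponential decomposition and train summation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

import seizurekit as sk
from seizurekit.kinetics import average_sweeps


def flat_sweep(value=0.0, rate=20_000.0, duration=1.0, stim=(0.1,)):
    return sk.Sweep(values=np.full(int(duration * rate), value), sampling_rate=rate,
                    stimulus_times=stim)


class TestMeasurePeak:
    def test_instant_rise_peak_is_total_amplitude(self, noiseless_sweep, simple_decay):
        assert sk.measure_peak(noiseless_sweep) == pytest.approx(simple_decay.amplitude)

    def test_flat_trace_gives_zero(self):
        assert sk.measure_peak(flat_sweep()) == 0.0

    def test_finite_rise_peak_matches_dense_closed_form(self, simple_decay):
        spec = sk.SweepSpec(decay=simple_decay, duration=1.0, baseline_noise_sd=0.0,
                            rise_tau_ms=2.0, stimulus_times=(0.1,))
        sw = sk.gen_eipsc(spec, seed=0)
        t = np.linspace(0.0, 50.0, 2_000_001)  # dense oracle evaluation, ms
        y = (1 - np.exp(-t / 2.0)) * simple_decay.evaluate(t)
        assert sk.measure_peak(sw) == pytest.approx(y.max(), rel=1e-4)

    def test_out_of_range_stimulus_index(self, noiseless_sweep):
        with pytest.raises(ValueError, match="stimulus_index"):
            sk.measure_peak(noiseless_sweep, stimulus_index=3)


class TestMeasureArea:
    def test_rectangular_pulse(self):
        sw = flat_sweep()
        v = sw.values.copy()
        i0 = sw.index_at(0.1)
        v[i0: i0 + int(0.1 * sw.sampling_rate)] = 10.0  # 10 pA for 100 ms
        sw = dataclasses.replace(sw, values=v)
        assert sk.measure_area(sw) == pytest.approx(1000.0, rel=1e-3)

    def test_zero_trace(self):
        assert sk.measure_area(flat_sweep()) == 0.0

    def test_biexponential_matches_closed_form_integral(self, noiseless_sweep, simple_decay):
        d = simple_decay
        expected = (d.a_fast * d.tau_fast * (1 - math.exp(-750 / d.tau_fast))
                    + d.a_slow * d.tau_slow * (1 - math.exp(-750 / d.tau_slow)))
        assert sk.measure_area(noiseless_sweep) == pytest.approx(expected, rel=1e-3)

    def test_truncated_sweep_rejected_naming_available_span(self, simple_decay):
        spec = sk.SweepSpec(decay=simple_decay, duration=0.5, baseline_noise_sd=0.0,
                            stimulus_times=(0.4,))
        sw = sk.gen_eipsc(spec, seed=0)
        with pytest.raises(ValueError, match="100.0 ms available"):
            sk.measure_area(sw)


class TestPercentBlock:
    def test_printed_pid_amplitude_example(self):
        assert sk.percent_block(716.0, 577.0) == pytest.approx(19.4, abs=0.05)

    def test_identity_is_zero(self):
        assert sk.percent_block(123.4, 123.4) == 0.0

    def test_potentiation_is_negative(self):
        assert sk.percent_block(100.0, 160.0) == pytest.approx(-60.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            sk.percent_block(0.0, 5.0)

    @given(a=st.floats(1.0, 1e4), f=st.floats(-1.0, 1.0))
    def test_exact_fraction_identity(self, a, f):
        assert sk.percent_block(a, a * (1 - f)) == pytest.approx(100 * f, abs=1e-9)


class TestExtractDecaySegment:
    def test_single_exponential_span_is_tau_ln9(self):
        decay = sk.DecayComponents(200.0, 30.0, 1e-12, 30.000001)
        spec = sk.SweepSpec(decay=decay, duration=1.0, baseline_noise_sd=0.0,
                            rise_tau_ms=0.0, stimulus_times=(0.1,))
        t, y = sk.extract_decay_segment(sk.gen_eipsc(spec, seed=0))
        assert t[-1] - t[0] == pytest.approx(30.0 * math.log(9), abs=0.2)
        assert y[0] <= 0.9 * 200.0 and y[-1] <= 0.1 * 200.0

    def test_endpoints_match_root_finding_oracle(self, noiseless_sweep, simple_decay):
        t, y = sk.extract_decay_segment(noiseless_sweep, smooth_ms=0.0)
        peak = simple_decay.amplitude
        f = lambda tt, frac: simple_decay.evaluate(tt) - frac * peak
        t90 = brentq(f, 0.0, 700.0, args=(0.9,))
        t10 = brentq(f, 0.0, 700.0, args=(0.1,))
        dt = 1000.0 / noiseless_sweep.sampling_rate
        assert t[0] == pytest.approx(t90, abs=2 * dt)
        assert t[-1] == pytest.approx(t10, abs=2 * dt)

    def test_clipped_trace_rejected(self, simple_decay):
        spec = sk.SweepSpec(decay=simple_decay, duration=0.15, baseline_noise_sd=0.0,
                            stimulus_times=(0.1,))
        with pytest.raises(ValueError, match="10%"):
            sk.extract_decay_segment(sk.gen_eipsc(spec, seed=0))


class TestFitBiexponential:
    def test_noiseless_exact_recovery(self, noiseless_sweep, simple_decay):
        fit = sk.fit_biexponential(*sk.extract_decay_segment(noiseless_sweep))
        c = fit.components
        for got, true in [(c.a_fast, 300.0), (c.tau_fast, 10.0),
                          (c.a_slow, 100.0), (c.tau_slow, 80.0)]:
            assert abs(got - true) / true < 1e-4
        assert fit.converged and not fit.ill_separated

    def test_single_exponential_input_flagged_ill_separated(self):
        t = np.linspace(0.0, 200.0, 2000)
        y = 250.0 * np.exp(-t / 40.0)
        with pytest.warns(UserWarning, match="ill-separated"):
            fit = sk.fit_biexponential(t, y)
        assert fit.ill_separated

    def test_weighted_tau_recovered_under_noise(self, simple_decay):
        true_tw = sk.weighted_tau(simple_decay)
        spec = sk.SweepSpec(decay=simple_decay, duration=1.0,
                            baseline_noise_sd=0.01 * simple_decay.amplitude,
                            rise_tau_ms=0.0, stimulus_times=(0.1,))
        errs = []
        for seed in range(30):
            sw = sk.gen_eipsc(spec, seed=seed)
            fit = sk.fit_biexponential(*sk.extract_decay_segment(sw))
            errs.append(abs(fit.tau_weighted - true_tw) / true_tw)
        assert np.median(errs) < 0.05

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="20 samples"):
            sk.fit_biexponential(np.arange(10.0), np.ones(10))


class TestConstrainedPairFit:
    def test_identity_pair_preserves_parameters(self, noiseless_sweep):
        seg = sk.extract_decay_segment(noiseless_sweep)
        pair = sk.constrained_pair_fit(seg, seg)
        un = pair.unconstrained_baseline.components
        assert pair.tau_fast_mean == pytest.approx(un.tau_fast)
        assert pair.tau_slow_mean == pytest.approx(un.tau_slow)
        assert pair.baseline.a_fast == pytest.approx(un.a_fast, rel=1e-6)
        assert sk.component_block(pair) == pytest.approx((0.0, 0.0), abs=1e-6)

    def test_constrained_residual_not_below_unconstrained(self, control_decay):
        spec = sk.SweepSpec(decay=control_decay, duration=1.0,
                            baseline_noise_sd=5.0, stimulus_times=(0.1,))
        treated = sk.apply_drug(control_decay, sk.PTZ_EFFECT)
        sw_b = sk.gen_eipsc(spec, seed=0)
        sw_t = sk.gen_eipsc(dataclasses.replace(spec, decay=treated), seed=1)
        pair = sk.constrained_pair_fit(sk.extract_decay_segment(sw_b),
                                       sk.extract_decay_segment(sw_t))
        assert pair.sse_baseline >= pair.unconstrained_baseline.sse - 1e-6
        assert pair.sse_treated >= pair.unconstrained_treated.sse - 1e-6

    def test_swap_symmetry(self, control_decay):
        spec = sk.SweepSpec(decay=control_decay, duration=1.0, baseline_noise_sd=0.0,
                            stimulus_times=(0.1,))
        treated = sk.apply_drug(control_decay, sk.PTZ_EFFECT)
        seg_b = sk.extract_decay_segment(sk.gen_eipsc(spec, seed=0))
        seg_t = sk.extract_decay_segment(
            sk.gen_eipsc(dataclasses.replace(spec, decay=treated), seed=1))
        p1 = sk.constrained_pair_fit(seg_b, seg_t)
        p2 = sk.constrained_pair_fit(seg_t, seg_b)
        assert p1.tau_fast_mean == pytest.approx(p2.tau_fast_mean, rel=1e-6)
        assert p1.baseline.a_fast == pytest.approx(p2.treated.a_fast, rel=1e-6)

    def test_ptz_like_pair_recovers_component_blocks(self, control_decay):
        spec = sk.SweepSpec(decay=control_decay, duration=1.0, baseline_noise_sd=0.0,
                            stimulus_times=(0.1,))
        treated = sk.apply_drug(control_decay, sk.DrugEffect(0.23, 0.63))
        pair = sk.constrained_pair_fit(
            sk.extract_decay_segment(sk.gen_eipsc(spec, seed=0)),
            sk.extract_decay_segment(
                sk.gen_eipsc(dataclasses.replace(spec, decay=treated), seed=1)))
        fast, slow = sk.component_block(pair)
        assert fast == pytest.approx(23.0, abs=2.0)
        assert slow == pytest.approx(63.0, abs=2.0)

    def test_slow_potentiation_gives_negative_percent(self, control_decay):
        spec = sk.SweepSpec(decay=control_decay, duration=1.0, baseline_noise_sd=0.0,
                            stimulus_times=(0.1,))
        treated = sk.apply_drug(control_decay, sk.DrugEffect(0.0, -0.2))
        pair = sk.constrained_pair_fit(
            sk.extract_decay_segment(sk.gen_eipsc(spec, seed=0)),
            sk.extract_decay_segment(
                sk.gen_eipsc(dataclasses.replace(spec, decay=treated), seed=1)))
        _, slow = sk.component_block(pair)
        assert slow < -10.0


class TestWeightedTau:
    @pytest.mark.parametrize("decay,expected", [
        (sk.DecayComponents(300.0, 10.0, 0.0, 80.0), 10.0),
        (sk.DecayComponents(150.0, 10.0, 150.0, 80.0), 45.0),
        (sk.DecayComponents(300.0, 10.0, 100.0, 80.0), 27.5),
    ])
    def test_direct_values(self, decay, expected):
        assert sk.weighted_tau(decay) == pytest.approx(expected)

    def test_zero_total_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            sk.weighted_tau(sk.DecayComponents(0.0, 10.0, 0.0, 80.0))

    @given(af=st.floats(0.0, 1e3), asl=st.floats(0.01, 1e3),
           tf=st.floats(0.5, 50.0), ratio=st.floats(1.0, 50.0))
    def test_bounded_by_component_taus(self, af, asl, tf, ratio):
        d = sk.DecayComponents(af, tf, asl, tf * ratio)
        tw = sk.weighted_tau(d)
        assert d.tau_fast - 1e-9 <= tw <= d.tau_slow + 1e-9


class TestTrainProfile:
    def test_strong_slow_block_reduces_fifth_peak(self, control_decay):
        spec = sk.SweepSpec(decay=control_decay, duration=1.6, baseline_noise_sd=0.0,
                            stimulus_times=(0.1,))
        treated = sk.apply_drug(control_decay, sk.PTZ_EFFECT)
        p_ctrl = sk.train_profile(sk.gen_train(spec, 5, 100.0, seed=0), 5, 100.0)
        p_drug = sk.train_profile(
            sk.gen_train(dataclasses.replace(spec, decay=treated), 5, 100.0, seed=1),
            5, 100.0)
        assert p_ctrl[0] == 1.0 and p_drug[0] == 1.0
        assert p_drug[4] < p_ctrl[4]

    def test_missing_stimuli_rejected(self, noiseless_sweep):
        with pytest.raises(ValueError, match="stimuli"):
            sk.train_profile(noiseless_sweep, n_stimuli=5, isi_ms=100.0)


class TestAverages:
    def test_average_block_mean_and_sem(self):
        mean, sem = sk.average_block_over_cells([10.0, 20.0, 30.0])
        assert mean == pytest.approx(20.0)
        assert sem == pytest.approx(5.7735, abs=1e-3)

    def test_equal_values_zero_sem(self):
        assert sk.average_block_over_cells([7.0, 7.0, 7.0])[1] == 0.0

    def test_average_sweeps_reduces_noise(self, control_decay):
        spec = sk.SweepSpec(decay=control_decay, duration=0.5, baseline_noise_sd=10.0,
                            stimulus_times=(0.1,))
        sweeps = [sk.gen_eipsc(spec, seed=s) for s in range(16)]
        avg = average_sweeps(sweeps)
        pre = avg.values[: avg.index_at(0.09)]
        assert np.std(pre) == pytest.approx(10.0 / 4.0, rel=0.3)

    def test_average_sweeps_requires_alignment(self, noiseless_sweep):
        other = dataclasses.replace(noiseless_sweep, stimulus_times=(0.2,))
        with pytest.raises(ValueError, match="stimulus times"):
            average_sweeps([noiseless_sweep, other])
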