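"""Generators: determinism, closed-form agreement and staircase calibration."""

import dataclasses
import math

import numpy as np
import pytest

import seizurekit as sk
from seizurekit.synth import boltzmann_probability


class TestGenEipsc:
    def test_noiseless_trace_matches_closed_form_everywhere(self, noiseless_spec):
        sw = sk.gen_eipsc(noiseless_spec, seed=3)
        d = noiseless_spec.decay
        t = sw.times
        expected = np.zeros_like(t)
        m = t >= 0.1
        tm = (t[m] - 0.1) * 1000.0
        expected[m] = d.a_fast * np.exp(-tm / d.tau_fast) + d.a_slow * np.exp(-tm / d.tau_slow)
        assert np.allclose(sw.values, expected, rtol=1e-9, atol=1e-9)

    def test_instantaneous_rise_peak_is_total_amplitude(self, noiseless_sweep, simple_decay):
        assert noiseless_sweep.values.max() == pytest.approx(simple_decay.amplitude)

    def test_value_10ms_after_onset(self, noiseless_spec):
        sw = sk.gen_eipsc(noiseless_spec, seed=0)
        # direct evaluation of the waveform 10 ms after stimulus onset
        expected = 300.0 * math.exp(-10.0 / 10.0) + 100.0 * math.exp(-10.0 / 80.0)
        i = sw.index_at(0.1 + 0.010)
        assert sw.values[i] == pytest.approx(expected, rel=1e-9)

    def test_same_seed_bitwise_identical(self, control_decay):
        spec = sk.SweepSpec(decay=control_decay, baseline_noise_sd=5.0)
        a = sk.gen_eipsc(spec, seed=42)
        b = sk.gen_eipsc(spec, seed=42)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, sk.gen_eipsc(spec, seed=43).values)

    def test_inward_polarity_flips_sign(self, noiseless_spec):
        spec = dataclasses.replace(noiseless_spec, polarity="inward_negative")
        assert sk.gen_eipsc(spec, seed=0).values.min() == pytest.approx(
            -noiseless_spec.decay.amplitude)

    @pytest.mark.parametrize("field,kwargs", [
        ("sampling_rate", dict(sampling_rate=0.0)),
        ("duration", dict(duration=-1.0)),
        ("baseline_noise_sd", dict(baseline_noise_sd=-2.0)),
        ("stimulus_times", dict(stimulus_times=(5.0,))),
        ("polarity", dict(polarity="sideways")),
    ])
    def test_invalid_spec_rejected_naming_field(self, control_decay, field, kwargs):
        with pytest.raises(ValueError, match=field):
            sk.SweepSpec(decay=control_decay, **{"duration": 1.0, **kwargs})


class TestApplyDrug:
    def test_zero_effect_is_identity(self, control_decay):
        assert sk.apply_drug(control_decay, sk.DrugEffect(0.0, 0.0)) == control_decay

    def test_component_scaling_arithmetic(self):
        d = sk.DecayComponents(300.0, 10.0, 100.0, 80.0)
        out = sk.apply_drug(d, sk.DrugEffect(0.23, 0.63))
        assert out.a_fast == pytest.approx(231.0)
        assert out.a_slow == pytest.approx(37.0)

    def test_negative_slow_fraction_potentiates(self, control_decay):
        out = sk.apply_drug(control_decay, sk.DrugEffect(0.0, -0.1))
        assert out.a_slow == pytest.approx(1.1 * control_decay.a_slow)


class TestGenTrain:
    def test_single_stimulus_reduces_to_gen_eipsc(self, control_decay):
        spec = sk.SweepSpec(decay=control_decay, duration=1.0, baseline_noise_sd=3.0)
        a = sk.gen_train(spec, n_stimuli=1, isi_ms=100.0, seed=7)
        b = sk.gen_eipsc(spec, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_fast_decay_gives_equal_peaks(self):
        decay = sk.DecayComponents(300.0, 2.0, 100.0, 5.0)  # tau_slow << isi
        spec = sk.SweepSpec(decay=decay, duration=1.0, baseline_noise_sd=0.0,
                            rise_tau_ms=0.0, stimulus_times=(0.1,))
        sw = sk.gen_train(spec, n_stimuli=5, isi_ms=100.0, seed=0)
        prof = sk.train_profile(sw, n_stimuli=5, isi_ms=100.0)
        assert np.allclose(prof, 1.0, atol=1e-6)

    def test_slow_decay_summates_matching_superposition_oracle(self, control_decay):
        spec = sk.SweepSpec(decay=control_decay, duration=1.6, baseline_noise_sd=0.0,
                            rise_tau_ms=0.0, stimulus_times=(0.1,))
        sw = sk.gen_train(spec, n_stimuli=5, isi_ms=100.0, seed=0)
        # oracle: superpose the closed form densely and read window maxima
        t = sw.times
        y = np.zeros_like(t)
        for k in range(5):
            tm = (t - (0.1 + 0.1 * k)) * 1000.0
            m = tm >= -1e-6  # same stimulus-coincidence tolerance as the generator
            y[m] += control_decay.evaluate(np.clip(tm[m], 0.0, None))
        peaks = [y[(t >= 0.1 + 0.1 * k - 1e-9) & (t < 0.2 + 0.1 * k - 1e-9)].max()
                 for k in range(5)]
        prof = sk.train_profile(sw, n_stimuli=5, isi_ms=100.0)
        assert np.allclose(prof, np.asarray(peaks) / peaks[0], rtol=1e-9)
        assert prof[4] > 1.05  # temporal summation


class TestGenEpiform:
    def test_zero_rates_give_pure_noise_and_empty_table(self):
        spec = sk.EpiformSpec(duration=120.0, pid_rate=0.0, sle_rate=0.0,
                              baseline_noise_sd=2.0)
        sweep, truth = sk.gen_epiform_trace(spec, seed=1)
        assert truth.empty
        assert abs(np.mean(sweep.values)) < 1.0
        assert np.std(sweep.values) == pytest.approx(2.0, rel=0.1)

    def test_event_count_matches_seeded_poisson_draw(self):
        spec = sk.EpiformSpec(duration=1800.0, pid_rate=6.667, sle_rate=0.0)
        _, truth = sk.gen_epiform_trace(spec, seed=11)
        # oracle: replay the counting substream
        rng = np.random.default_rng(np.random.SeedSequence(entropy=11, spawn_key=(1,)))
        expected = rng.poisson(6.667 / 1000.0 * 1800.0)
        assert len(truth) == expected

    def test_polarity_convention(self):
        spec = sk.EpiformSpec(duration=300.0, pid_rate=10.0, sle_rate=3.0,
                              baseline_noise_sd=0.0)
        sweep, truth = sk.gen_epiform_trace(spec, seed=2)
        fs = sweep.sampling_rate
        for r in truth.itertuples():
            seg = sweep.values[int(r.onset_s * fs): int(r.offset_s * fs)]
            if r.type == "PID":
                assert seg.min() >= -1e-9 and seg.max() > 0
            else:
                assert seg.max() > 0 and seg.min() < 0

    def test_determinism(self):
        spec = sk.EpiformSpec(duration=300.0)
        s1, t1 = sk.gen_epiform_trace(spec, seed=9)
        s2, t2 = sk.gen_epiform_trace(spec, seed=9)
        assert np.array_equal(s1.values, s2.values)
        assert t1.equals(t2)

    def test_impossible_rates_rejected(self):
        spec = sk.EpiformSpec(duration=120.0, pid_rate=5.0, sle_rate=100.0)
        with pytest.raises(ValueError, match="too high"):
            sk.gen_epiform_trace(spec, seed=0)


class TestGenStaircase:
    def test_first_animal_receives_start_current(self):
        t = sk.gen_staircase_cohort(ec50=17.3, slope=1.2, n_animals=1, seed=0)
        assert t.records["current_ma"].iloc[0] == 27.0

    def test_second_animal_steps_down_after_extension(self):
        # ec50 far below the ladder: extension is near-certain
        t = sk.gen_staircase_cohort(ec50=5.0, slope=0.1, n_animals=2, seed=0)
        assert list(t.records["current_ma"]) == [27.0, 23.0]
        assert list(t.records["outcome"])[0] == "extension"

    def test_steep_slope_acts_as_step_function(self):
        t = sk.gen_staircase_cohort(ec50=18.0, slope=1e-9, n_animals=30, seed=4)
        for r in t.records.itertuples():
            assert r.outcome == ("extension" if r.current_ma > 18.0 else "no_extension")

    def test_pinned_extension_fraction_matches_boltzmann(self):
        # pin every animal at 20 mA by using single-animal cohorts
        ec50, slope, n = 19.0, 2.0, 4000
        start = sk.MEST_LADDER_MA.index(20.0)
        hits = sum(
            sk.gen_staircase_cohort(ec50, slope, n_animals=1, start_index=start,
                                    seed=s).records["outcome"].iloc[0] == "extension"
            for s in range(n)
        )
        p = float(boltzmann_probability(np.array([20.0]), ec50, slope)[0])
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_clipping_at_ladder_bottom_is_flagged(self):
        t = sk.gen_staircase_cohort(ec50=5.0, slope=0.1, n_animals=10, seed=0)
        assert t.records["clipped"].any()
        assert t.records["current_ma"].min() == 12.0


class TestGenScoreSeries:
    def test_empty_episodes(self):
        s = sk.gen_score_series([], window=1800.0)
        assert sk.latency_and_duration(s) == (None, 0.0)

    def test_long_score4_episode_flags_status_epilepticus(self):
        s = sk.gen_score_series([(60.0, 60.0 + 720.0, 4)], window=1800.0)
        assert sk.status_epilepticus(s)

    def test_overlap_merges_to_max_score_with_warning(self):
        with pytest.warns(UserWarning, match="maximum score"):
            s = sk.gen_score_series([(60.0, 120.0, 2), (90.0, 180.0, 3)])
        assert s.episodes == ((60.0, 180.0, 3),)

    def test_latency_shifts_episodes(self):
        s = sk.gen_score_series([(100.0, 160.0, 2)], latency=40.0)
        assert s.episodes[0][:2] == (40.0, 100.0)
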