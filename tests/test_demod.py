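import numpy as np
import pytest
from hypothesis import given, strategies as st

import amzi_twin as at
from amzi_twin import demod as dm
from amzi_twin import instrument as ins
from amzi_twin.assay import AnalyteState, FlowStep

from conftest import cosine_record, lsq_cosine_phase, smooth_step_state


def make_sensorgram(time_s, trace, fsr=1500.0):
    return dm.Sensorgram(
        time_s=np.asarray(time_s, float),
        shift_pm=np.asarray(trace, float)[None, :],
        fsr_pm=np.array([fsr]),
        channels=[0],
    )


class TestExtractPhase:
    @given(
        phase=st.floats(-3.1, 3.1),
        fringes=st.integers(1, 12),
    )
    def test_matches_least_squares_cosine_oracle(self, phase, fringes):
        rec = cosine_record(phase, fringes)
        result = dm.extract_phase(rec)
        oracle = lsq_cosine_phase(rec.samples[0], fringes)
        assert result.phase_rad[0] == pytest.approx(oracle, abs=1e-9)
        assert result.phase_rad[0] == pytest.approx(phase, abs=1e-9)
        assert result.dominant_bin[0] == fringes

    def test_one_fsr_shift_leaves_wrapped_phase_unchanged(self):
        a = dm.extract_phase(cosine_record(0.7, 3))
        b = dm.extract_phase(cosine_record(0.7 + 2 * np.pi, 3))
        assert a.phase_rad[0] == pytest.approx(b.phase_rad[0], abs=1e-12)

    def test_flat_trace_flags_low_contrast_without_raising(self):
        rec = at.RawSweepRecord(0, 0.0, np.full((1, 256), 0.6))
        result = dm.extract_phase(rec)
        assert bool(result.low_contrast[0])
        assert np.isfinite(result.phase_rad[0])

    def test_contrast_and_amplitude_reported(self):
        rec = cosine_record(0.0, 2, amplitude=0.3, offset=0.6)
        result = dm.extract_phase(rec)
        assert result.amplitude[0] == pytest.approx(0.3, rel=1e-9)
        assert result.contrast[0] == pytest.approx(0.5, rel=1e-9)

    def test_short_record_rejected(self):
        with pytest.raises(dm.DemodError):
            dm.extract_phase(at.RawSweepRecord(0, 0.0, np.zeros((1, 8))))


class TestTrackSensorgram:
    def test_static_zero_noise_gives_flat_zero(self, layout, sweep, zero_noise):
        recs = ins.simulate_cycles(layout, None, sweep, zero_noise, 50, seed=0)
        gram = dm.track_sensorgram(recs, sweep, layout, baseline_window_s=(0.0, 5.0))
        assert np.max(np.abs(gram.shift_pm)) < 1e-9

    def test_two_fsr_ramp_unwraps_through_wrapping(self, layout, sweep, zero_noise):
        t = np.arange(0.0, 30.0, 0.1)
        shift = np.zeros((6, len(t)))
        shift[0] = 3000.0 * np.clip(t / 20.0, 0.0, 1.0)  # 2 x FSR total
        state = AnalyteState(t, [1, 2, 3, 4, 5, 6], shift, np.zeros(len(t)))
        recs = ins.simulate_cycles(layout, state, sweep, zero_noise, 250, seed=0)
        gram = dm.track_sensorgram(recs, sweep, layout, baseline_window_s=(0.0, 0.0))
        assert gram.shift_pm[0, -1] == pytest.approx(3000.0, rel=1e-3)

    def test_imposed_step_recovered_within_noise(self, layout, sweep, budget_08pm):
        state = smooth_step_state(100.0 / 5000.0 / 1000.0)  # 100 pm on S = 5000 channels
        recs = ins.simulate_cycles(layout, state, sweep, budget_08pm, 600, seed=9)
        gram = dm.track_sensorgram(recs, sweep, layout, baseline_window_s=(0.0, 10.0))
        assert gram.shift_pm[0, -1] == pytest.approx(100.0, abs=2.0)

    def test_near_ambiguous_jump_recorded_as_warning(self, layout, sweep, zero_noise):
        t = np.arange(0.0, 10.0, 0.1)
        shift = np.zeros((6, len(t)))
        shift[0] = np.where(t > 5.0, 740.0, 0.0)  # just below FSR/2 per cycle
        state = AnalyteState(t, [1, 2, 3, 4, 5, 6], shift, np.zeros(len(t)))
        recs = ins.simulate_cycles(layout, state, sweep, zero_noise, 90, seed=0)
        gram = dm.track_sensorgram(recs, sweep, layout)
        assert any("ambiguity" in w for w in gram.warnings)

    def test_time_grid_must_increase(self):
        with pytest.raises(dm.DemodError):
            dm.Sensorgram(
                time_s=np.array([0.0, 0.0, 1.0]),
                shift_pm=np.zeros((1, 3)),
                fsr_pm=np.array([1500.0]),
                channels=[0],
            )


class TestDifferentialSignal:
    def test_identical_channels_cancel(self, layout, sweep, zero_noise):
        recs = ins.simulate_cycles(layout, None, sweep, zero_noise, 30, seed=0)
        gram = dm.track_sensorgram(recs, sweep, layout)
        diff = dm.differential_signal(gram, 0, 1)
        assert np.max(np.abs(diff.shift_pm)) < 1e-9
        assert diff.metadata["referencing"] == {"signal": 0, "reference": 1}

    def test_common_mode_bulk_step_cancels(self, layout, sweep, zero_noise):
        state = smooth_step_state(-4.08e-4)
        recs = ins.simulate_cycles(layout, state, sweep, zero_noise, 500, seed=0)
        gram = dm.track_sensorgram(recs, sweep, layout, baseline_window_s=(0.0, 10.0))
        assert abs(gram.shift_pm[0, -1]) > 1000.0  # raw channel sees the step
        diff = dm.differential_signal(gram, 0, 1)
        assert np.max(np.abs(diff.shift_pm)) < 1e-6

    def test_specific_signal_passes_through(self, layout, sweep, zero_noise):
        t = np.arange(0.0, 20.0, 0.1)
        shift = np.zeros((6, len(t)))
        shift[0] = 50.0 * np.clip((t - 5) / 10.0, 0.0, 1.0)
        state = AnalyteState(t, [1, 2, 3, 4, 5, 6], shift, np.zeros(len(t)))
        recs = ins.simulate_cycles(layout, state, sweep, zero_noise, 190, seed=0)
        gram = dm.track_sensorgram(recs, sweep, layout, baseline_window_s=(0.0, 4.0))
        diff = dm.differential_signal(gram, 0, 1)
        assert diff.shift_pm[0, -1] == pytest.approx(50.0, rel=1e-3)

    def test_missing_channel_rejected(self, layout, sweep, zero_noise):
        recs = ins.simulate_cycles(layout, None, sweep, zero_noise, 5, seed=0)
        gram = dm.track_sensorgram(recs, sweep, layout)
        with pytest.raises(dm.AlignmentError):
            dm.differential_signal(gram, 0, 99)


class TestResolutionAndLod:
    def test_noiseless_baseline_resolution_zero(self, layout, sweep, zero_noise):
        recs = ins.simulate_cycles(layout, None, sweep, zero_noise, 60, seed=0)
        gram = dm.track_sensorgram(recs, sweep, layout)
        assert dm.estimate_resolution(gram, (0.0, 6.0), channel=0) < 1e-9

    def test_injected_jitter_recovered_as_three_sigma(self, layout, sweep):
        budget = at.NoiseBudget(0.0, 0.25, 0.0)
        recs = ins.simulate_cycles(layout, None, sweep, budget, 400, seed=21)
        gram = dm.track_sensorgram(recs, sweep, layout, baseline_window_s=(0.0, 40.0))
        r = dm.estimate_resolution(gram, (0.0, 40.0), channel=0)
        assert r == pytest.approx(3 * 0.25, rel=0.2)

    def test_window_spanning_programmed_step_rejected(self):
        gram = make_sensorgram(np.arange(100) * 0.5, np.zeros(100))
        program = [FlowStep("a", 20.0, 60.0), FlowStep("b", 30.0, 60.0)]
        with pytest.raises(dm.PreconditionError):
            dm.estimate_resolution(gram, (10.0, 30.0), channel=0, program=program)

    def test_short_window_rejected(self):
        gram = make_sensorgram(np.arange(100) * 0.5, np.zeros(100))
        with pytest.raises(dm.PreconditionError):
            dm.estimate_resolution(gram, (0.0, 2.0), channel=0)

    def test_lod_from_estimated_resolution(self, layout, sweep, budget_08pm):
        recs = ins.simulate_cycles(layout, None, sweep, budget_08pm, 300, seed=2)
        gram = dm.track_sensorgram(recs, sweep, layout, baseline_window_s=(0.0, 30.0))
        lod = dm.estimate_lod(gram, (0.0, 30.0), 5000.0, channel=0)
        assert lod == pytest.approx(1.6e-7, rel=0.2)

    def test_lod_scales_with_noise(self, layout, sweep):
        lods = []
        for scale in (1.0, 2.0):
            s = scale * 0.8 / 3 / np.sqrt(3)
            recs = ins.simulate_cycles(layout, None, sweep, at.NoiseBudget(s, s, s), 400, seed=13)
            gram = dm.track_sensorgram(recs, sweep, layout, baseline_window_s=(0.0, 40.0))
            lods.append(dm.estimate_lod(gram, (0.0, 40.0), 5000.0, channel=0))
        assert lods[1] / lods[0] == pytest.approx(2.0, rel=0.25)


class TestAnalyzeSteps:
    def test_ideal_square_wave_levels(self):
        t = np.arange(0.0, 300.0, 0.5)
        program = [FlowStep(lbl, 100.0, 48.0) for lbl in ("a", "b", "c")]
        x = np.select([t < 100.0, t < 200.0], [0.0, 200.0], default=50.0)
        ana = dm.analyze_steps(make_sensorgram(t, x), program, channel=0)
        np.testing.assert_allclose(ana.plateau_levels, [0.0, 200.0, 50.0], atol=1e-9)
        np.testing.assert_allclose(ana.level_differences, [200.0, -150.0], atol=1e-9)
        assert ana.response_delays_s[0] == pytest.approx(0.0, abs=0.5)

    def test_zero_amplitude_steps_yield_no_detections(self):
        t = np.arange(0.0, 300.0, 0.5)
        program = [FlowStep(lbl, 100.0, 48.0) for lbl in ("a", "b", "c")]
        ana = dm.analyze_steps(make_sensorgram(t, np.zeros_like(t)), program, channel=0)
        assert ana.transition_times_s == [None, None]
        np.testing.assert_allclose(ana.level_differences, 0.0)

    @pytest.mark.parametrize("tau", [2.0, 8.0])
    def test_detection_delay_grows_with_edge_time_constant(self, tau):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 200.0, 0.5)
        x = np.where(t >= 100.0, 100.0 * (1 - np.exp(-(t - 100.0) / tau)), 0.0)
        x = x + rng.normal(0.0, 0.5, len(t))
        program = [FlowStep("a", 100.0, 48.0), FlowStep("b", 100.0, 48.0)]
        ana = dm.analyze_steps(make_sensorgram(t, x), program, channel=0)
        # analytic threshold crossing of the exponential edge
        sigma = ana.plateau_sigmas[0]
        expected = -tau * np.log(1 - 5.0 * sigma / 100.0)
        assert ana.response_delays_s[0] == pytest.approx(expected, abs=1.5)

    def test_short_steps_flagged_unsettled(self):
        t = np.arange(0.0, 40.0, 0.5)
        program = [FlowStep("a", 20.0, 48.0), FlowStep("b", 20.0, 48.0)]
        ana = dm.analyze_steps(make_sensorgram(t, np.zeros_like(t)), program, settle_guard_s=30.0)
        assert ana.unsettled == [True, True]


class TestQcChecks:
    def test_monitor_channels_flagged_on_drift(self, layout):
        t = np.arange(0.0, 50.0, 0.5)
        shifts = np.zeros((8, len(t)))
        shifts[6] = np.linspace(0.0, 120.0, len(t))  # drifting bulk monitor
        gram = dm.Sensorgram(t, shifts, np.full(8, 1500.0), list(range(8)))
        flags = dm.qc_reference_channels(gram, layout, max_drift_pm=50.0)
        assert flags[6] is True
        assert flags[7] is False
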