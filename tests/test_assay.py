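import numpy as np
import pytest
from hypothesis import given, strategies as st

from amzi_twin import assay as ay


@pytest.fixture
def models():
    return ay.default_binding_models()


@pytest.fixture
def channels():
    return ay.default_channel_layout()


class TestLangmuir:
    def test_no_analyte_no_binding(self, models):
        m = models["TGFBI"]
        t = np.linspace(0, 1e4, 50)
        assert np.all(ay.langmuir_occupancy(0.0, m, t, theta0=0.0) == 0.0)

    def test_equilibrium_isotherm(self, models):
        m = models["TGFBI"]
        c = 2e-9  # 2 nM vs KD = 1 nM -> theta_eq = 2/3
        theta = ay.langmuir_occupancy(c, m, 1e7)
        assert theta == pytest.approx(m.k_on * c / (m.k_on * c + m.k_off), rel=1e-6)

    def test_irreversible_binding_saturates(self):
        m = ay.BindingModel(k_on=1e5, k_off=0.0, surface_capacity_shift_pm=1000.0, molar_mass_g_mol=7e4)
        assert ay.langmuir_occupancy(1e-9, m, 1e8) == pytest.approx(1.0, rel=1e-4)

    def test_negative_concentration_rejected(self, models):
        with pytest.raises(ay.AssayConfigurationError):
            ay.langmuir_occupancy(-1e-9, models["TGFBI"], 10.0)

    @given(
        c=st.floats(0.0, 1e-6),
        t=st.floats(0.0, 1e5),
        theta0=st.floats(0.0, 1.0),
    )
    def test_occupancy_stays_in_unit_interval(self, c, t, theta0):
        m = ay.default_binding_models()["POSTN"]
        theta = ay.langmuir_occupancy(c, m, t, theta0=theta0)
        assert -1e-12 <= theta <= 1.0 + 1e-12

    @given(concs=st.lists(st.floats(1e-12, 1e-6), min_size=2, max_size=8))
    def test_isotherm_monotone_in_concentration(self, concs):
        m = ay.default_binding_models()["TGFBI"]
        eq = [m.k_on * c / (m.k_on * c + m.k_off) for c in sorted(concs)]
        assert all(a <= b + 1e-15 for a, b in zip(eq, eq[1:]))


class TestFlowStepValidation:
    def test_volume_bookkeeping_accepts_consistent_step(self):
        ay.FlowStep("PBS", duration_s=75.0, flow_rate_ul_min=48.0, volume_ul=60.0)

    def test_volume_bookkeeping_rejects_mismatch(self):
        with pytest.raises(ay.AssayConfigurationError):
            ay.FlowStep("PBS", duration_s=60.0, flow_rate_ul_min=48.0, volume_ul=60.0)

    def test_instrument_flow_range(self):
        ay.FlowStep("ok", 10.0, 48.0).validate_instrument_flow()
        with pytest.raises(ay.AssayConfigurationError):
            ay.FlowStep("fast", 10.0, 500.0).validate_instrument_flow()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"duration_s": 0.0, "flow_rate_ul_min": 48.0},
            {"duration_s": 10.0, "flow_rate_ul_min": -1.0},
            {"duration_s": 10.0, "flow_rate_ul_min": 48.0, "analyte_concentrations": {"TGFBI": -5.0}},
        ],
    )
    def test_invalid_steps_rejected(self, kwargs):
        with pytest.raises(ay.AssayConfigurationError):
            ay.FlowStep("bad", **kwargs)


class TestRunAssayProgram:
    def test_buffer_only_program_gives_zero_shifts(self, channels, models):
        steps = [
            ay.FlowStep("buffer", 30.0, 60.0),
            ay.FlowStep("buffer2", 30.0, 60.0, bulk_index_delta_riu=1e-4),
        ]
        state = ay.run_assay_program(steps, channels, models, dt=0.1, bulk_delay_s=0.0)
        assert np.all(state.surface_shift_pm == 0.0)
        assert state.bulk_index_riu[-1] == pytest.approx(1e-4 * (1 - np.exp(-30.0 / 5.0)), rel=1e-4)

    def test_cognate_channel_rises_monotonically_toward_capacity(self, channels, models):
        steps = [ay.FlowStep("sample", 600.0, 60.0, analyte_concentrations={"TGFBI": 2500.0})]
        state = ay.run_assay_program(steps, channels, models, dt=0.5)
        trace = state.shift_for(1)  # anti-TGFBI
        assert np.all(np.diff(trace) >= -1e-9)
        assert 0 < trace[-1] <= models["TGFBI"].surface_capacity_shift_pm

    def test_specificity_of_noncognate_channels(self, channels, models):
        steps = [ay.FlowStep("sample", 300.0, 60.0, analyte_concentrations={"TGFBI": 500.0})]
        state = ay.run_assay_program(steps, channels, models, dt=0.5)
        cognate = state.shift_for(1)[-1]
        noncognate = abs(state.shift_for(5)[-1])  # anti-POSTN channel
        assert cognate > 50.0
        assert noncognate < 0.05 * cognate

    def test_alternating_salt_steps_make_square_wave_with_exponential_edges(self, channels, models):
        delta = ay.nacl_bulk_index_delta(-0.040)
        steps = [ay.FlowStep("prime", 60.0, 48.0)]
        for _ in range(2):
            steps.append(ay.FlowStep("low", 75.0, 48.0, bulk_index_delta_riu=delta))
            steps.append(ay.FlowStep("pbs", 75.0, 48.0, bulk_index_delta_riu=0.0))
        tau, delay = 5.0, 15.0
        state = ay.run_assay_program(steps, channels, models, dt=0.1, bulk_tau_s=tau, bulk_delay_s=delay)
        t, b = state.time_s, state.bulk_index_riu
        # plateau before each change
        assert b[np.searchsorted(t, 135.0)] == pytest.approx(delta, rel=1e-3)
        assert b[np.searchsorted(t, 210.0)] == pytest.approx(0.0, abs=abs(delta) * 1e-3)
        # first-order edge: one tau past the lagged switch, 63% of the way
        i = np.searchsorted(t, 60.0 + delay + tau)
        assert b[i] == pytest.approx(delta * (1 - np.exp(-1)), rel=0.05)

    def test_nacl_increment_value(self):
        assert ay.nacl_bulk_index_delta(-0.040) == pytest.approx(-4.08e-4, rel=1e-6)

    def test_unknown_analyte_rejected(self, channels, models):
        steps = [ay.FlowStep("sample", 10.0, 60.0, analyte_concentrations={"CEA": 10.0})]
        with pytest.raises(ay.AssayConfigurationError):
            ay.run_assay_program(steps, channels, models)

    def test_dt_must_divide_durations(self, channels, models):
        steps = [ay.FlowStep("odd", 10.05, 60.0)]
        with pytest.raises(ay.AssayConfigurationError):
            ay.run_assay_program(steps, channels, models, dt=0.1)

    def test_exactly_six_channels_required(self, channels, models):
        with pytest.raises(ay.AssayConfigurationError):
            ay.run_assay_program([ay.FlowStep("b", 10.0, 60.0)], channels[:5], models)

    def test_crossreactivity_only_above_threshold(self, channels, models):
        low = ay.run_assay_program(
            [ay.FlowStep("s", 300.0, 60.0, analyte_concentrations={"POSTN": 500.0})],
            channels, models, dt=0.5,
        )
        high = ay.run_assay_program(
            [ay.FlowStep("s", 300.0, 60.0, analyte_concentrations={"POSTN": 2500.0})],
            channels, models, dt=0.5,
        )
        # nonspecific pickup on the anti-TGFBI channel appears only above 1 ug/mL
        assert abs(low.shift_for(1)[-1]) < 1.0
        assert high.shift_for(1)[-1] > 10.0


class TestSerum:
    def test_zero_serum_equals_buffer_run(self, channels, models):
        state = ay.serum_sample_state(0.0, {}, channels, models, dt=0.5)
        assert np.all(state.surface_shift_pm == 0.0)

    def test_unspotted_controls_drift_opposite(self, channels, models):
        state = ay.serum_sample_state(
            10.0, {"TGFBI": 500.0, "POSTN": 800.0}, channels, models, dt=0.5
        )
        for control in (2, 4):
            trace = state.shift_for(control)
            assert trace[-1] < 0.0
            assert np.all(np.diff(trace) <= 1e-9)

    def test_spotted_channels_exceed_controls(self, channels, models):
        state = ay.serum_sample_state(
            10.0, {"TGFBI": 500.0, "POSTN": 800.0}, channels, models, dt=0.5
        )
        for spotted in (1, 3, 5, 6):
            assert state.shift_for(spotted)[-1] > 0.0
            assert state.shift_for(spotted)[-1] > state.shift_for(2)[-1]

    def test_drift_scales_with_serum_fraction(self, channels, models):
        s10 = ay.serum_sample_state(10.0, {}, channels, models, dt=0.5)
        s20 = ay.serum_sample_state(20.0, {}, channels, models, dt=0.5)
        assert s20.shift_for(2)[-1] == pytest.approx(2 * s10.shift_for(2)[-1], rel=1e-6)


class TestAnalyteState:
    def test_tidy_frame_columns_and_edge_holding(self, channels, models):
        state = ay.run_assay_program([ay.FlowStep("b", 10.0, 60.0)], channels, models, dt=1.0)
        df = state.to_frame()
        assert set(df.columns) == {"time_s", "channel", "surface_shift_pm", "bulk_index_riu"}
        shifts, bulk = state.at_time(1e9)
        assert shifts.shape == (6,)
        np.testing.assert_allclose(shifts, state.surface_shift_pm[:, -1])
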