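"""Controller state machine: Ti/Te scheduling, phase sequencing with
plateau and PEEP termination, and the three alarms."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from ventsim import (
    AlarmKind,
    Controller,
    LungParams,
    Phase,
    VentSettings,
    check_alarms,
    extract_breath_metrics,
    rate_from_times,
    schedule_times,
    step_simulation,
)


class TestScheduleTimes:
    @pytest.mark.parametrize(
        "rate, ratio, expected",
        [
            (10, (1, 2), (2000, 4000)),
            (24, (1, 3), (625, 1875)),
            (22, (2, 1), (1818, 909)),
            (20, (1, 3), (750, 2250)),
        ],
    )
    def test_reference_anchors(self, rate, ratio, expected):
        assert schedule_times(rate, ratio) == expected

    @given(st.integers(min_value=1, max_value=60))
    @hyp_settings(max_examples=60, derandomize=True)
    def test_equal_ratio_gives_equal_times(self, rate):
        ti, te = schedule_times(rate, (1, 1))
        assert ti == te

    @given(
        st.integers(min_value=1, max_value=60),
        st.integers(min_value=1, max_value=5),
        st.integers(min_value=1, max_value=5),
    )
    @hyp_settings(max_examples=200, derandomize=True)
    def test_times_sum_to_cycle_period(self, rate, i, e):
        ti, te = schedule_times(rate, (i, e))
        assert abs(ti + te - 60000.0 / rate) <= 1.0

    @pytest.mark.parametrize("rate, ratio", [(0, (1, 2)), (61, (1, 2)), (10, (0, 2)), (10, (1, -1))])
    def test_invalid_inputs_rejected(self, rate, ratio):
        with pytest.raises(ValueError):
            schedule_times(rate, ratio)


class TestRateFromTimes:
    def test_examples(self):
        assert rate_from_times(2000, 4000) == pytest.approx(10.0)
        assert rate_from_times(750, 2200) == pytest.approx(20.339, abs=1e-3)
        assert round(rate_from_times(750, 2200)) == 20
        assert rate_from_times(1000, 1000) == pytest.approx(30.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            rate_from_times(0, 1000)


class TestSettingsValidation:
    def test_plateau_below_peep_rejected(self):
        with pytest.raises(ValueError, match="plateau_cmh2o"):
            VentSettings(peep_cmh2o=10, plateau_cmh2o=8)

    def test_pmax_below_plateau_rejected(self):
        with pytest.raises(ValueError, match="pmax_alarm_cmh2o"):
            VentSettings(plateau_cmh2o=30, pmax_alarm_cmh2o=25)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            VentSettings(ti_msec=500)


class TestPhaseSequencing:
    def test_delivery_and_bleed_never_both_open(self):
        """The delivery solenoid and the exhalation-bleed solenoid are
        mutually exclusive at every controller step."""
        ctrl = Controller(VentSettings(ti_ms=500, te_ms=700, flow_lpm=30, plateau_cmh2o=20))
        paw = 0.0
        for k in range(5000):
            phase, delivery, bleed = ctrl.step(0.001, paw, paw)
            assert not (delivery and bleed)
            paw = 25.0 if k > 2500 else 0.0  # force the plateau branch too

    def test_full_phase_cycle_order(self, normal_lung):
        settings = VentSettings(
            ti_ms=2000, te_ms=4000, flow_lpm=30, plateau_cmh2o=8.0, pmax_alarm_cmh2o=40
        )
        res = step_simulation(settings, normal_lung, duration_s=12.0)
        names = [n for _, n, _ in res.events if n.startswith("phase_")]
        # each breath passes INSPIRATION -> PLATEAU_HOLD -> EXPIRATION -> PEEP_HOLD
        cycle = names[:4]
        assert cycle == [
            "phase_INSPIRATION",
            "phase_PLATEAU_HOLD",
            "phase_EXPIRATION",
            "phase_PEEP_HOLD",
        ]
        assert names[4:8] == cycle

    def test_plateau_caps_pressure_and_latches(self, normal_lung):
        """Once the plateau pressure is reached, the delivery solenoid
        stays closed for the rest of Ti and pressure plateaus."""
        settings = VentSettings(
            ti_ms=2000, te_ms=4000, flow_lpm=30, plateau_cmh2o=8.0, pmax_alarm_cmh2o=40
        )
        res = step_simulation(settings, normal_lung, duration_s=6.0)
        wf = res.waveform
        # peak pressure is capped just at the plateau setting, and once flow
        # stops the pressure holds flat (the plateau) for the rest of Ti
        assert wf.paw_cmh2o.max() <= 8.0 + 0.2
        hold = (wf.time_s > 1.8) & (wf.time_s < 2.0)
        assert np.ptp(wf.paw_cmh2o[hold]) < 0.05
        names = [n for _, n, _ in res.events if n.startswith("phase_")]
        assert "phase_PLATEAU_HOLD" in names

    def test_cycle_period_matches_settings_within_one_step(self, nominal_run):
        starts = [t for t, n, _ in nominal_run.events if n == "phase_INSPIRATION"]
        periods = np.diff(starts)
        assert np.allclose(periods, 6.0, atol=0.0011)

    def test_end_expiratory_pressure_holds_peep(self):
        """With Te >= 3*R*C, end-expiratory airway pressure equals the PEEP
        setting within 0.5 cmH2O."""
        settings = VentSettings(ti_ms=2000, te_ms=4000, flow_lpm=30, peep_cmh2o=5.0)
        lung = LungParams()  # tau = 0.5 s, Te = 8 tau
        res = step_simulation(
            settings, lung, duration_s=30.0, initial_volume_ml=500.0
        )
        m = extract_breath_metrics(res.waveform)
        assert m.measured_peep_cmh2o == pytest.approx(5.0, abs=0.5)


class TestAlarms:
    def _settings(self):
        return VentSettings(ti_ms=2000, te_ms=4000, flow_lpm=30, pmax_alarm_cmh2o=40)

    def test_occlusion_raises_high_pressure(self):
        stiff = LungParams(compliance_ml_per_cmh2o=1.0)
        res = step_simulation(self._settings(), stiff, duration_s=12.0)
        kinds = {a.kind for a in check_alarms(res.waveform, self._settings())}
        assert AlarmKind.HIGH_PRESSURE in kinds

    def test_disconnect_raises_low_pressure(self):
        # disconnect: enormous compliance, near-zero resistance to ambient
        open_circuit = LungParams(
            compliance_ml_per_cmh2o=5e4, resistance_cmh2o_per_l_s=0.5
        )
        res = step_simulation(self._settings(), open_circuit, duration_s=12.0)
        kinds = {a.kind for a in check_alarms(res.waveform, self._settings())}
        assert AlarmKind.LOW_PRESSURE in kinds

    def test_nominal_run_is_alarm_free(self, nominal_run):
        assert check_alarms(nominal_run.waveform, self._settings()) == []

    def test_short_waveform_rejected(self, normal_lung):
        res = step_simulation(self._settings(), normal_lung, duration_s=3.0)
        with pytest.raises(ValueError, match="cycle"):
            check_alarms(res.waveform, self._settings())

    def test_insufficient_flow_detected(self, nominal_run):
        # pretend the dial was set far higher than what was delivered
        greedy = VentSettings(ti_ms=2000, te_ms=4000, flow_lpm=120, pmax_alarm_cmh2o=40)
        kinds = {a.kind for a in check_alarms(nominal_run.waveform, greedy)}
        assert AlarmKind.INSUFFICIENT_FLOW in kinds
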