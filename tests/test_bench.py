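"""Virtual bench: breath-metric extraction, the condition-sweep protocol,
and the flow-calibration loop."""

import numpy as np
import pytest

from ventsim import (
    BenchCondition,
    CircuitParams,
    LungParams,
    VentSettings,
    calibrate_flow,
    compliance_resistance_sweep,
    extract_breath_metrics,
    generate_fixture_waveform,
    rate_from_times,
    run_protocol,
    step_simulation,
)
from ventsim.bench import AnalysisError, CalibrationError


class TestBreathMetrics:
    def test_square_fixture_is_recovered_exactly(self):
        """Constant inspiratory flow integrates exactly under the
        trapezoid rule: VT 1000 mL at RR 10 comes back untouched."""
        wf = generate_fixture_waveform("square", vt_ml=1000, rr=10, pkp_cmh2o=15)
        m = extract_breath_metrics(wf)
        assert m.tidal_volume_ml == pytest.approx(1000.0, abs=1e-9)
        assert m.respiratory_rate == pytest.approx(10.0, abs=1e-9)
        assert m.peak_airway_pressure_cmh2o == pytest.approx(15.0)

    def test_triangular_fixture_within_trapezoid_error(self):
        wf = generate_fixture_waveform("triangular", vt_ml=500, rr=12)
        m = extract_breath_metrics(wf)
        assert m.tidal_volume_ml == pytest.approx(500.0, rel=0.005)

    def test_measured_like_fixture_peep_and_pkp(self):
        wf = generate_fixture_waveform(
            "measured-like", vt_ml=500, rr=15, pkp_cmh2o=22, peep_cmh2o=5
        )
        m = extract_breath_metrics(wf)
        assert m.peak_airway_pressure_cmh2o == pytest.approx(22.0, abs=0.01)
        assert m.measured_peep_cmh2o == pytest.approx(5.0, abs=0.2)
        assert m.respiratory_rate == pytest.approx(15.0, abs=0.01)

    def test_metrics_agree_with_simulator_volume_ledger(self, nominal_run):
        """Waveform-side tidal volume matches the integrator's own
        per-breath delivered-volume ledger within 1%."""
        m = extract_breath_metrics(nominal_run.waveform)
        ledger = np.mean(nominal_run.breath_volumes_ml[1:])
        assert m.tidal_volume_ml == pytest.approx(ledger, rel=0.01)

    def test_measured_ti_matches_setting(self, nominal_run):
        m = extract_breath_metrics(nominal_run.waveform)
        assert m.measured_ti_s == pytest.approx(2.0, abs=0.02)
        assert m.measured_te_s == pytest.approx(4.0, abs=0.02)

    def test_no_breaths_raises_analysis_error(self):
        from ventsim.core import WaveformRecord

        flat = WaveformRecord(
            time_s=np.arange(100) * 0.01,
            paw_cmh2o=np.zeros(100),
            flow_lpm=np.zeros(100),
            sample_interval_s=0.01,
        )
        with pytest.raises(AnalysisError, match="2.0 L/min"):
            extract_breath_metrics(flat, flow_onset_threshold_lpm=2.0)


@pytest.fixture(scope="module")
def sweep_table():
    """Noise-free single-replicate run of the standard C/R sweep."""
    return run_protocol(compliance_resistance_sweep(replicates=1))


class TestProtocol:
    def test_rate_column_matches_settings_everywhere(self, sweep_table):
        implied = rate_from_times(2000, 4000)
        assert np.allclose(sweep_table.rr_mean, implied, rtol=0.01)

    def test_vt_falls_and_pkp_rises_as_compliance_drops(self, sweep_table):
        comp = sweep_table.iloc[:5]  # C 100 -> 10 at R 5
        assert (np.diff(comp.vt_mean) < 0).all()
        assert (np.diff(comp.pkp) > 0).all()

    def test_vt_falls_and_pkp_rises_as_resistance_rises(self, sweep_table):
        res = sweep_table.iloc[5:]  # R 5 -> 50 at C 100
        assert (np.diff(res.vt_mean) < 0).all()
        assert (np.diff(res.pkp) > 0).all()

    def test_noise_free_replicates_have_zero_sd(self):
        table = run_protocol([BenchCondition(replicates=3)])
        assert table.vt_sd[0] == 0.0 and table.rr_sd[0] == 0.0

    def test_identical_seeds_identical_tables(self):
        circ = CircuitParams(sensor_noise_sd_cmh2o=0.2, flow_noise_sd_lpm=0.5)
        conds = [BenchCondition(replicates=3, n_cycles=4)]
        a = run_protocol(conds, circ, seed=42)
        b = run_protocol(conds, circ, seed=42)
        assert a.equals(b)

    def test_replicate_sd_scales_with_noise_level(self):
        """Doubling the sensor-noise sd doubles the replicate VT spread
        (same seed, so the noise realization is shared and scaled)."""

        def vt_sd(scale):
            circ = CircuitParams(
                sensor_noise_sd_cmh2o=0.1 * scale, flow_noise_sd_lpm=0.25 * scale
            )
            table = run_protocol(
                [BenchCondition(replicates=6, n_cycles=5)], circ, seed=11
            )
            return table.vt_sd[0]

        ratio = vt_sd(2.0) / vt_sd(1.0)
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_failing_condition_does_not_abort_sweep(self):
        bad = BenchCondition(flow_lpm=0.5, n_cycles=3, replicates=1)  # undetectable breaths
        good = BenchCondition(replicates=1)
        table = run_protocol([bad, good])
        assert np.isnan(table.vt_mean[0]) and table.error[0] != ""
        assert np.isfinite(table.vt_mean[1])


class TestCalibration:
    def _case(self):
        settings = VentSettings(ti_ms=750, te_ms=2200, flow_lpm=30, peep_cmh2o=5)
        lung = LungParams(compliance_ml_per_cmh2o=50, resistance_cmh2o_per_l_s=5)
        return settings, lung

    def test_reaches_target_within_tolerance(self):
        settings, lung = self._case()
        result = calibrate_flow(500.0, settings, lung)
        assert abs(result.achieved_vt_ml - 500.0) <= 0.01 * 500.0
        assert result.iterations <= 40

    def test_round_trip_resimulation_confirms(self):
        """An independent run with the returned dial setting delivers the
        target volume within tolerance."""
        settings, lung = self._case()
        result = calibrate_flow(500.0, settings, lung)
        tuned = settings.model_copy(update={"flow_lpm": result.setting_lpm})
        res = step_simulation(
            tuned, lung, duration_s=8 * tuned.cycle_s,
            initial_volume_ml=tuned.peep_cmh2o * lung.compliance_ml_per_cmh2o,
        )
        vt = extract_breath_metrics(res.waveform).tidal_volume_ml
        assert vt == pytest.approx(500.0, rel=0.011)

    def test_satisfied_target_returns_immediately(self):
        settings, lung = self._case()
        first = calibrate_flow(500.0, settings, lung)
        tuned = settings.model_copy(update={"flow_lpm": first.setting_lpm})
        again = calibrate_flow(first.achieved_vt_ml, tuned, lung)
        assert again.iterations <= 1
        assert again.setting_lpm == pytest.approx(first.setting_lpm)

    def test_unreachable_target_reports_max_achievable(self):
        settings, lung = self._case()
        stiff = LungParams(compliance_ml_per_cmh2o=10, resistance_cmh2o_per_l_s=5)
        with pytest.raises(CalibrationError, match="maximum achievable"):
            calibrate_flow(2000.0, settings, stiff)
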