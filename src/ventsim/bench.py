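"""Virtual lung-simulator bench.

Plays the role the physical breathing-simulator rig plays on a real test
bench: it treats the ventilator twin as a black box, looks only at the
sampled pressure/flow waveform at the patient port, and measures what a
respiratory therapist would read off the rig — tidal volume, rate, peak
pressure, PEEP, timing.  On top of the per-run metrics it provides the
condition-sweep protocol (varying compliance and resistance with
replicates) and the flow-calibration loop that tunes the needle valve until
a target tidal volume is delivered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .controller import VentSettings
from .core import LungParams, WaveformRecord
from .pneumatics import CircuitParams
from .simulate import SimResult, step_simulation

__all__ = [
    "BreathMetrics",
    "BenchCondition",
    "AnalysisError",
    "CalibrationError",
    "CalibrationResult",
    "extract_breath_metrics",
    "run_protocol",
    "calibrate_flow",
    "compliance_resistance_sweep",
]


class AnalysisError(ValueError):
    """Waveform analysis failed (e.g. no detectable breaths)."""


class CalibrationError(RuntimeError):
    """Flow calibration cannot reach the requested tidal volume."""


@dataclass
class BreathMetrics:
    """Per-breath quantities measured from a waveform, plus aggregates.

    Arrays are one entry per complete breath (first and last partial breaths
    are discarded).  Aggregate properties give the mean; ``*_sd`` the sample
    standard deviation across breaths.
    """

    tidal_volumes_ml: np.ndarray
    peak_pressures_cmh2o: np.ndarray
    peak_flows_lpm: np.ndarray
    peeps_cmh2o: np.ndarray
    ti_s: np.ndarray
    te_s: np.ndarray
    periods_s: np.ndarray

    @property
    def n_breaths(self) -> int:
        return len(self.tidal_volumes_ml)

    @property
    def tidal_volume_ml(self) -> float:
        return float(np.mean(self.tidal_volumes_ml))

    @property
    def tidal_volume_sd_ml(self) -> float:
        return float(np.std(self.tidal_volumes_ml, ddof=1)) if self.n_breaths > 1 else 0.0

    @property
    def respiratory_rate(self) -> float:
        return 60.0 / float(np.median(self.periods_s))

    @property
    def peak_airway_pressure_cmh2o(self) -> float:
        return float(np.mean(self.peak_pressures_cmh2o))

    @property
    def measured_peep_cmh2o(self) -> float:
        return float(np.mean(self.peeps_cmh2o))

    @property
    def measured_ti_s(self) -> float:
        return float(np.median(self.ti_s))

    @property
    def measured_te_s(self) -> float:
        return float(np.median(self.te_s))

    @property
    def peak_flow_lpm(self) -> float:
        return float(np.mean(self.peak_flows_lpm))


class BenchCondition(BaseModel):
    """One row of a bench protocol: ventilator timing/flow plus the passive
    R-C load, with a replicate count for mean ± SD reporting."""

    model_config = ConfigDict(extra="forbid")

    flow_lpm: float = 30.0
    ti_ms: float = 2000.0
    te_ms: float = 4000.0
    compliance_ml_per_cmh2o: float = 100.0
    resistance_cmh2o_per_l_s: float = 5.0
    peep_cmh2o: float = 0.0
    replicates: int = 5
    n_cycles: int = 8

    @model_validator(mode="after")
    def _check(self) -> "BenchCondition":
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_cycles < 3:
            raise ValueError("n_cycles must be >= 3 to measure full breaths")
        return self


def extract_breath_metrics(
    waveform: WaveformRecord,
    flow_onset_threshold_lpm: float = 2.0,
    end_expiratory_fraction: float = 0.1,
    min_onset_run: int = 3,
) -> BreathMetrics:
    """Segment a waveform into breaths and measure them.

    Breaths are delimited at inspiratory flow onset (flow rising through the
    threshold and staying above it for ``min_onset_run`` samples, so a
    single noisy sample cannot split a breath).  Tidal volume is the
    trapezoidal integral of positive flow per breath; PEEP is read as the
    mean pressure over the final fraction of each breath window (end of
    expiration).  Needs at least two complete breaths between the discarded
    leading/trailing partials.
    """
    t = waveform.time_s
    flow = waveform.flow_lpm
    paw = waveform.paw_cmh2o
    above = flow >= flow_onset_threshold_lpm
    candidates = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    onsets = np.array(
        [k for k in candidates if above[k : k + min_onset_run].all()], dtype=int
    )
    if len(onsets) < 3:
        raise AnalysisError(
            f"fewer than 2 complete breaths detected with onset threshold "
            f"{flow_onset_threshold_lpm} L/min"
        )
    vt, pkp, pkf, peep, ti, te, periods = ([] for _ in range(7))
    dt = waveform.sample_interval_s
    for a, b in zip(onsets[:-1], onsets[1:]):
        seg = slice(a, b + 1)  # include next onset so edge halves pair up
        pos_flow_ml_s = np.clip(flow[seg], 0.0, None) / 60.0 * 1000.0
        vt.append(float(np.trapezoid(pos_flow_ml_s, t[seg])))
        pkp.append(float(paw[a:b].max()))
        pkf.append(float(flow[a:b].max()))
        n_tail = max(1, int(round((b - a) * end_expiratory_fraction)))
        peep.append(float(paw[b - n_tail : b].mean()))
        n_insp = int(np.count_nonzero(flow[a:b] >= flow_onset_threshold_lpm))
        ti.append(n_insp * dt)
        period = float(t[b] - t[a])
        periods.append(period)
        te.append(period - n_insp * dt)
    return BreathMetrics(
        tidal_volumes_ml=np.array(vt),
        peak_pressures_cmh2o=np.array(pkp),
        peak_flows_lpm=np.array(pkf),
        peeps_cmh2o=np.array(peep),
        ti_s=np.array(ti),
        te_s=np.array(te),
        periods_s=np.array(periods),
    )


def _condition_run(
    cond: BenchCondition,
    circuit: CircuitParams,
    seed: int | None,
    dt_s: float,
) -> SimResult:
    settings = VentSettings(
        ti_ms=cond.ti_ms,
        te_ms=cond.te_ms,
        flow_lpm=cond.flow_lpm,
        peep_cmh2o=cond.peep_cmh2o,
    )
    lung = LungParams(
        compliance_ml_per_cmh2o=cond.compliance_ml_per_cmh2o,
        resistance_cmh2o_per_l_s=cond.resistance_cmh2o_per_l_s,
    )
    duration = cond.n_cycles * settings.cycle_s
    return step_simulation(
        settings,
        lung,
        circuit,
        duration_s=duration,
        dt_s=dt_s,
        seed=seed,
        initial_volume_ml=cond.peep_cmh2o * cond.compliance_ml_per_cmh2o,
    )


def run_protocol(
    conditions: list[BenchCondition],
    circuit: CircuitParams | None = None,
    seed: int | None = None,
    dt_s: float = 0.001,
) -> pd.DataFrame:
    """Run each bench condition with its replicates and tabulate mean ± SD.

    Replicate-to-replicate spread comes solely from the circuit's sensor
    noise; with noise disabled the SD columns are exactly zero.  The whole
    sweep is deterministic given ``seed`` (replicate seeds are spawned from
    it).  A failing condition yields a row with NaNs and an error message
    instead of aborting the sweep.
    """
    if circuit is None:
        circuit = CircuitParams()
    noisy = circuit.sensor_noise_sd_cmh2o > 0 or circuit.flow_noise_sd_lpm > 0
    if noisy and seed is None:
        raise ValueError("a seed is required when sensor noise is enabled")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rows = []
    for cond in conditions:
        children = ss.spawn(cond.replicates)
        rr, vt, pkp = [], [], []
        err = ""
        try:
            for child in children:
                rep_seed = int(child.generate_state(1)[0] % (2**31)) if noisy else None
                res = _condition_run(cond, circuit, rep_seed, dt_s)
                m = extract_breath_metrics(res.waveform)
                rr.append(m.respiratory_rate)
                vt.append(m.tidal_volume_ml)
                pkp.append(m.peak_airway_pressure_cmh2o)
        except (AnalysisError, ValueError, RuntimeError) as exc:  # keep sweeping
            err = str(exc)
        if err or not rr:
            vals = dict(
                pkp=np.nan, rr_mean=np.nan, rr_sd=np.nan,
                vt_mean=np.nan, vt_sd=np.nan,
            )
        else:
            sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            vals = dict(
                pkp=float(np.mean(pkp)),
                rr_mean=float(np.mean(rr)),
                rr_sd=sd(rr),
                vt_mean=float(np.mean(vt)),
                vt_sd=sd(vt),
            )
        rows.append(
            dict(
                flow_lpm=cond.flow_lpm,
                ti_ms=cond.ti_ms,
                te_ms=cond.te_ms,
                compliance=cond.compliance_ml_per_cmh2o,
                resistance=cond.resistance_cmh2o_per_l_s,
                **vals,
                error=err,
            )
        )
    return pd.DataFrame(rows)


def compliance_resistance_sweep(
    flow_lpm: float = 30.0,
    ti_ms: float = 2000.0,
    te_ms: float = 4000.0,
    compliances: tuple[float, ...] = (100.0, 75.0, 50.0, 25.0, 10.0),
    resistances: tuple[float, ...] = (5.0, 7.5, 10.0, 20.0, 50.0),
    replicates: int = 5,
) -> list[BenchCondition]:
    """The standard bench sweep: vary compliance at the first resistance,
    then resistance at the first compliance (10 conditions)."""
    conds = [
        BenchCondition(
            flow_lpm=flow_lpm, ti_ms=ti_ms, te_ms=te_ms,
            compliance_ml_per_cmh2o=c, resistance_cmh2o_per_l_s=resistances[0],
            replicates=replicates,
        )
        for c in compliances
    ]
    conds += [
        BenchCondition(
            flow_lpm=flow_lpm, ti_ms=ti_ms, te_ms=te_ms,
            compliance_ml_per_cmh2o=compliances[0], resistance_cmh2o_per_l_s=r,
            replicates=replicates,
        )
        for r in resistances
    ]
    return conds


@dataclass
class CalibrationResult:
    setting_lpm: float
    achieved_vt_ml: float
    iterations: int
    history: list[tuple[float, float]] = field(default_factory=list)


def _measured_vt(
    setting_lpm: float,
    settings: VentSettings,
    lung: LungParams,
    circuit: CircuitParams,
    n_cycles: int,
    dt_s: float,
) -> float:
    trial = settings.model_copy(update={"flow_lpm": setting_lpm})
    res = step_simulation(
        trial,
        lung,
        circuit,
        duration_s=n_cycles * trial.cycle_s,
        dt_s=dt_s,
        initial_volume_ml=trial.peep_cmh2o * lung.compliance_ml_per_cmh2o,
    )
    return extract_breath_metrics(res.waveform).tidal_volume_ml


def calibrate_flow(
    target_vt_ml: float,
    settings: VentSettings,
    lung: LungParams,
    circuit: CircuitParams | None = None,
    tolerance: float = 0.01,
    max_iterations: int = 40,
    max_setting_lpm: float = 150.0,
    n_cycles: int = 6,
    dt_s: float = 0.001,
) -> CalibrationResult:
    """Tune the needle-valve setting by bisection until the bench-measured
    tidal volume is within ``tolerance`` (fractional) of the target.

    The delivered volume is measured the way an inline volume meter would:
    a short run is simulated and the waveform integrated.  Calibration runs
    are noise-free, so the loop is deterministic.  If even the widest valve
    opening cannot deliver the target (e.g. the relief valve caps the
    achievable volume), a :class:`CalibrationError` reports the maximum
    achievable tidal volume.
    """
    if target_vt_ml <= 0 or tolerance <= 0:
        raise ValueError("target_vt_ml and tolerance must be > 0")
    if circuit is None:
        circuit = CircuitParams()
    circuit = circuit.model_copy(
        update={"sensor_noise_sd_cmh2o": 0.0, "flow_noise_sd_lpm": 0.0}
    )
    history: list[tuple[float, float]] = []

    def measure(setting: float) -> float:
        vt = _measured_vt(setting, settings, lung, circuit, n_cycles, dt_s)
        history.append((setting, vt))
        return vt

    current = settings.flow_lpm
    vt = measure(current)
    if abs(vt - target_vt_ml) <= tolerance * target_vt_ml:
        return CalibrationResult(current, vt, 0, history)

    lo, hi = 0.5, max_setting_lpm
    vt_hi = measure(hi)
    if vt_hi < target_vt_ml * (1.0 - tolerance):
        raise CalibrationError(
            f"target VT {target_vt_ml:.0f} mL unreachable: maximum achievable "
            f"is {vt_hi:.1f} mL at {hi:.0f} L/min"
        )
    best = (hi, vt_hi)
    for it in range(1, max_iterations + 1):
        mid = 0.5 * (lo + hi)
        vt = measure(mid)
        if abs(vt - target_vt_ml) < abs(best[1] - target_vt_ml):
            best = (mid, vt)
        if abs(vt - target_vt_ml) <= tolerance * target_vt_ml:
            return CalibrationResult(mid, vt, it, history)
        if vt < target_vt_ml:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(best[0], best[1], max_iterations, history)
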