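"""Fixed-step simulation loop advancing the pneumatic plant and the
controller together.

Integration is explicit Euler at ``dt`` (default 1 ms).  The plant is a
first-order linear system with time constant R*C (>= tens of milliseconds
for any physiologic parameter set), so the explicit scheme is stable and
its convergence is verified by a step-halving test in the suite.  Sensor
noise, when enabled, perturbs only the *recorded* samples; the plant and
controller themselves are deterministic, so identical seeds give
bit-identical runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .controller import Controller, VentSettings
from .core import (
    LPS_PER_LPM,
    ML_PER_L,
    LungParams,
    Phase,
    SimState,
    SimulationError,
    WaveformRecord,
)
from .pneumatics import CircuitParams

__all__ = ["SimResult", "step_simulation"]


@dataclass
class SimResult:
    """Everything a run produces: the sampled waveform, the event log,
    the per-breath delivered-volume ledger, and the final plant state."""

    waveform: WaveformRecord
    events: list[tuple[float, str, float]]
    breath_volumes_ml: list[float]
    final_state: SimState
    inflow_integral_ml: float
    outflow_integral_ml: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def volume_conservation_error_ml(self) -> float:
        """|net integrated flow - volume change|; ~0 by construction unless
        a safety clamp intervened."""
        dv = (
            self.final_state.lung_volume_above_rest
            - self.meta.get("initial_volume_ml", 0.0)
        )
        return abs(self.inflow_integral_ml - self.outflow_integral_ml - dv)


def step_simulation(
    settings: VentSettings,
    lung: LungParams,
    circuit: CircuitParams | None = None,
    duration_s: float = 60.0,
    dt_s: float = 0.001,
    seed: int | None = None,
    sample_interval_s: float = 0.01,
    initial_volume_ml: float = 0.0,
) -> SimResult:
    """Run the ventilator twin against a single-compartment lung.

    The delivery flow during inspiration solves the needle-valve/lung
    coupling implicitly each step (linear or orifice law), so delivered flow
    sags as alveolar pressure rises.  The overpressure relief valve caps the
    port pressure ideally; relief and anti-asphyxia openings are logged as
    events, as are phase transitions.

    Raises
    ------
    ValueError
        for non-physical duration/step sizes (dt must be <= 2 ms).
    SimulationError
        if the state becomes non-finite (message carries the step index).
    """
    if circuit is None:
        circuit = CircuitParams()
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if not 0 < dt_s <= 0.002:
        raise ValueError("dt_s must be in (0, 0.002] s")
    if sample_interval_s < dt_s:
        raise ValueError("sample_interval_s must be >= dt_s")

    rng = np.random.default_rng(seed)
    noisy = circuit.sensor_noise_sd_cmh2o > 0 or circuit.flow_noise_sd_lpm > 0
    if noisy and seed is None:
        raise ValueError("a seed is required when sensor noise is enabled")

    C = lung.compliance_ml_per_cmh2o
    R = lung.resistance_cmh2o_per_l_s
    preg = circuit.regulated_pressure_cmh2o
    setting_lps = settings.flow_lpm * LPS_PER_LPM
    g = setting_lps / preg  # linear conductance, (L/s)/cmH2O
    # orifice law: Q^2 + a^2 R Q - a^2 (Preg - Palv) = 0, a = setting/sqrt(Preg)
    a2 = setting_lps**2 / preg
    orifice = circuit.needle_valve_law == "orifice"
    peep = settings.peep_cmh2o
    relief = circuit.relief_pressure_cmh2o if circuit.relief_enabled else math.inf
    aa = -circuit.antiasphyxia_cmh2o
    delay_s = circuit.solenoid_delay_ms / 1000.0

    ctrl = Controller(settings)
    n_steps = int(round(duration_s / dt_s))
    k_sample = max(1, int(round(sample_interval_s / dt_s)))
    n_samples = (n_steps + k_sample - 1) // k_sample
    t_rec = np.empty(n_samples)
    paw_rec = np.empty(n_samples)
    flow_rec = np.empty(n_samples)
    if noisy:
        paw_noise = circuit.sensor_noise_sd_cmh2o * rng.standard_normal(n_samples)
        flow_noise = circuit.flow_noise_sd_lpm * rng.standard_normal(n_samples)
    events: list[tuple[float, str, float]] = []
    breath_volumes: list[float] = []

    v = float(initial_volume_ml)  # mL above rest
    inflow_ml = 0.0
    outflow_ml = 0.0
    breath_in_ml = 0.0
    last_phase: Phase | None = None
    relief_was_open = False
    aa_was_open = False
    # effective (post-actuation-delay) solenoid states
    eff_delivery = False
    eff_bleed = False
    pending: list[tuple[float, bool, bool]] = []

    isample = 0
    paw = initial_volume_ml / C  # port pressure seen by the controller (previous step)
    for i in range(n_steps):
        t = i * dt_s
        palv = v / C
        if not math.isfinite(palv):
            raise SimulationError(f"non-finite pressure at step {i} (t={t:.4f} s)")

        phase, want_delivery, want_bleed = ctrl.step(dt_s, paw, palv)
        if delay_s <= 0:
            eff_delivery, eff_bleed = want_delivery, want_bleed
        else:
            if not pending or pending[-1][1:] != (want_delivery, want_bleed):
                pending.append((t + delay_s, want_delivery, want_bleed))
            while pending and pending[0][0] <= t:
                _, eff_delivery, eff_bleed = pending.pop(0)

        if phase is not last_phase:
            events.append((t, f"phase_{phase.value}", palv))
            if phase is Phase.INSPIRATION and last_phase is not None:
                breath_volumes.append(breath_in_ml)
                breath_in_ml = 0.0
            last_phase = phase

        # flow through the switched gas path
        if eff_delivery:
            dp = preg - palv
            if dp <= 0:
                q = 0.0
            elif orifice:
                q = (-a2 * R + math.sqrt(a2 * a2 * R * R + 4 * a2 * dp)) / 2.0
            else:
                q = g * dp / (1.0 + g * R)
        elif eff_bleed:  # exhalation valve open, recoil against PEEP
            q = -(palv - peep) / R if palv > peep else 0.0
        else:
            q = 0.0

        paw = palv + R * q

        # mechanical safety envelope (ideal clamps)
        if paw > relief:
            q = max((relief - palv) / R, 0.0) if eff_delivery else q
            paw = relief
            if not relief_was_open:
                events.append((t, "relief_open", paw))
            relief_was_open = True
        else:
            relief_was_open = False
        if paw < aa:
            q = (aa - palv) / R
            paw = aa
            if not aa_was_open:
                events.append((t, "antiasphyxia_open", paw))
            aa_was_open = True
        else:
            aa_was_open = False

        if i % k_sample == 0:
            t_rec[isample] = t
            paw_rec[isample] = paw
            flow_rec[isample] = q / LPS_PER_LPM
            isample += 1

        dv = q * ML_PER_L * dt_s
        if dv >= 0:
            inflow_ml += dv
            breath_in_ml += dv
        else:
            outflow_ml -= dv
        v += dv
        if q < 0:  # recoil cannot undershoot the PEEP level nor empty below rest
            v = max(v, peep * C, 0.0)

    if noisy:
        paw_rec = paw_rec + paw_noise
        flow_rec = flow_rec + flow_noise

    final_palv = v / C
    final = SimState(
        time=n_steps * dt_s,
        lung_volume_above_rest=v,
        alveolar_pressure=final_palv,
        airway_pressure=final_palv,
        flow=0.0,
        phase=ctrl.phase,
    )
    wf = WaveformRecord(
        time_s=t_rec[:isample],
        paw_cmh2o=paw_rec[:isample],
        flow_lpm=flow_rec[:isample],
        sample_interval_s=sample_interval_s,
        meta={"seed": seed, "dt_s": dt_s},
    )
    return SimResult(
        waveform=wf,
        events=events,
        breath_volumes_ml=breath_volumes,
        final_state=final,
        inflow_integral_ml=inflow_ml,
        outflow_integral_ml=outflow_ml,
        seed=seed,
        meta={
            "initial_volume_ml": initial_volume_ml,
            "settings": settings.model_dump(),
            "lung": lung.model_dump(),
            "circuit": circuit.model_dump(),
            "duration_s": duration_s,
            "dt_s": dt_s,
        },
    )
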