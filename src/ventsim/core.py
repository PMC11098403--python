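"""Single-compartment lung mechanics and the simulation state containers.

The plant is the textbook linear equation of motion of respiratory mechanics,

    Paw(t) = V(t) / C + R * Q(t) + PEEP-side back-pressure terms,

with a single compliance ``C`` (mL/cmH2O) and a single resistance ``R``
(cmH2O per L/s) that lumps airway, endotracheal tube and circuit.  Only the
volume *above* the relaxation volume is tracked; absolute lung volume (FRC)
plays no role in the model.

Internal unit convention: cmH2O, L/s, mL, seconds.  Public interfaces accept
L/min and ms and convert at the boundary (see :mod:`ventsim.config`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "LungParams",
    "Phase",
    "SimState",
    "WaveformRecord",
    "SimulationError",
    "lung_derivative",
    "passive_exhalation_flow",
]

LPS_PER_LPM = 1.0 / 60.0
ML_PER_L = 1000.0


class SimulationError(RuntimeError):
    """Raised when the plant integration produces a non-finite state."""


class LungParams(BaseModel):
    """Passive single-compartment lung.

    Parameters
    ----------
    compliance_ml_per_cmh2o:
        Volume change per unit pressure, mL/cmH2O.  100 is a normal adult
        lung; 10 is a severely stiff one.
    resistance_cmh2o_per_l_s:
        Pressure drop per unit flow, cmH2O/(L/s), lumping airway, tube and
        circuit.  5 is normal, 50 severe obstruction.
    """

    model_config = ConfigDict(extra="forbid")

    compliance_ml_per_cmh2o: float = 100.0
    resistance_cmh2o_per_l_s: float = 5.0

    @model_validator(mode="after")
    def _positive(self) -> "LungParams":
        if self.compliance_ml_per_cmh2o <= 0:
            raise ValueError("compliance_ml_per_cmh2o must be > 0")
        if self.resistance_cmh2o_per_l_s <= 0:
            raise ValueError("resistance_cmh2o_per_l_s must be > 0")
        return self

    @property
    def time_constant_s(self) -> float:
        """Expiratory time constant tau = R*C in seconds."""
        return (
            self.resistance_cmh2o_per_l_s
            * self.compliance_ml_per_cmh2o
            / ML_PER_L
        )


class Phase(enum.Enum):
    INSPIRATION = "INSPIRATION"
    PLATEAU_HOLD = "PLATEAU_HOLD"
    EXPIRATION = "EXPIRATION"
    PEEP_HOLD = "PEEP_HOLD"


@dataclass
class SimState:
    """Instantaneous plant + controller state.

    ``alveolar_pressure`` is maintained as ``lung_volume_above_rest /
    compliance`` by construction at every step; ``flow`` is signed positive
    into the patient.
    """

    time: float = 0.0
    lung_volume_above_rest: float = 0.0  # mL
    alveolar_pressure: float = 0.0  # cmH2O
    airway_pressure: float = 0.0  # cmH2O at the patient port
    flow: float = 0.0  # L/s, positive into patient
    phase: Phase = Phase.PEEP_HOLD


@dataclass
class WaveformRecord:
    """Uniformly sampled pressure/flow trace at the patient port.

    ``flow_lpm`` is in L/min to match the convention of ventilator displays;
    pressure is cmH2O.  Sampling is strictly uniform at ``sample_interval_s``.
    """

    time_s: np.ndarray
    paw_cmh2o: np.ndarray
    flow_lpm: np.ndarray
    sample_interval_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.paw_cmh2o = np.asarray(self.paw_cmh2o, dtype=float)
        self.flow_lpm = np.asarray(self.flow_lpm, dtype=float)
        n = len(self.time_s)
        if len(self.paw_cmh2o) != n or len(self.flow_lpm) != n:
            raise ValueError("waveform series must have equal length")
        if n > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise ValueError("waveform time must be strictly increasing")
            if not np.allclose(dt, self.sample_interval_s, rtol=1e-6, atol=1e-9):
                raise ValueError("waveform sampling interval must be constant")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if len(self) else 0.0


def lung_derivative(
    state: SimState, inflow_l_s: float, params: LungParams
) -> tuple[float, float]:
    """Rate of lung-volume change and patient-port pressure for a given inflow.

    Returns ``(dV/dt in mL/s, airway pressure in cmH2O)`` where
    ``Paw = V/C + R*Q``.

    Raises
    ------
    SimulationError
        if the state or inflow is non-finite (carries the state time).
    """
    if not (math.isfinite(inflow_l_s) and math.isfinite(state.lung_volume_above_rest)):
        raise SimulationError(
            f"non-finite plant state at t={state.time:.6f} s "
            f"(V={state.lung_volume_above_rest}, Q={inflow_l_s})"
        )
    palv = state.lung_volume_above_rest / params.compliance_ml_per_cmh2o
    paw = palv + params.resistance_cmh2o_per_l_s * inflow_l_s
    dv_dt = inflow_l_s * ML_PER_L
    return dv_dt, paw


def passive_exhalation_flow(
    state: SimState, circuit_peep_cmh2o: float, params: LungParams
) -> float:
    """Expiratory flow (L/s, negative out of the patient) through the open
    exhalation valve against a PEEP back-pressure.

    Flow is driven by elastic recoil and clamps to zero once alveolar
    pressure has decayed to the PEEP level — the valve holds PEEP, it never
    sucks gas out of the lung.
    """
    palv = state.lung_volume_above_rest / params.compliance_ml_per_cmh2o
    if palv <= circuit_peep_cmh2o:
        return 0.0
    return -(palv - circuit_peep_cmh2o) / params.resistance_cmh2o_per_l_s
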