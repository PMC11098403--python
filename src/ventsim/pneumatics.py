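"""Gas-path component models: regulator/needle valve, flow-sensing
restriction, solenoid-piloted exhalation valve, and the two mechanical
safety valves (overpressure relief and anti-asphyxia).

The needle valve is modelled by default as a linear conductance calibrated
to its nameplate free flow: delivered flow equals the dial setting when the
downstream (patient-port) pressure is ambient and sags linearly as the
downstream pressure rises toward the regulated supply pressure.  This sag is
the mechanism by which delivered tidal volume falls on stiff lungs.  An
orifice (square-root) law is available as a configuration option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from pydantic import BaseModel, ConfigDict, model_validator

from .core import LPS_PER_LPM

__all__ = [
    "CircuitParams",
    "ValveState",
    "needle_valve_flow",
    "flow_from_restriction",
    "restriction_delta_p",
    "update_exhalation_valve",
    "apply_safety_valves",
]


class CircuitParams(BaseModel):
    """Pneumatic circuit constants.

    ``regulated_pressure_cmh2o`` is the supply after the inlet regulator
    (default 70 cmH2O, a typical regulator setting for such circuits and a
    free parameter of the twin).  ``relief_pressure_cmh2o`` is the mechanical
    pop-off limit; ``antiasphyxia_cmh2o`` the magnitude of negative
    patient-port pressure at which the ambient inlet opens.  Sensor noise is
    zero-mean Gaussian added per recorded sample (plant dynamics stay
    deterministic); 0 disables it.
    """

    model_config = ConfigDict(extra="forbid")

    regulated_pressure_cmh2o: float = 70.0
    restriction_cmh2o_per_lpm: float = 0.1
    relief_pressure_cmh2o: float = 60.0
    antiasphyxia_cmh2o: float = 2.0
    solenoid_delay_ms: float = 0.0
    sensor_noise_sd_cmh2o: float = 0.0
    flow_noise_sd_lpm: float = 0.0
    needle_valve_law: Literal["linear", "orifice"] = "linear"
    relief_enabled: bool = True

    @model_validator(mode="after")
    def _check(self) -> "CircuitParams":
        if not self.regulated_pressure_cmh2o > self.relief_pressure_cmh2o > 0:
            raise ValueError(
                "require regulated_pressure_cmh2o > relief_pressure_cmh2o > 0"
            )
        if self.restriction_cmh2o_per_lpm <= 0:
            raise ValueError("restriction_cmh2o_per_lpm must be > 0")
        for name in (
            "antiasphyxia_cmh2o",
            "solenoid_delay_ms",
            "sensor_noise_sd_cmh2o",
            "flow_noise_sd_lpm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self


@dataclass
class ValveState:
    """Open/closed flags of the switched gas path.

    ``exhalation_valve`` is pilot-derived: pressurizing the pilot line (from
    the delivery-solenoid outlet) closes it; bleeding the pilot opens it.
    """

    delivery_solenoid: bool = False
    exhalation_bleed_solenoid: bool = False
    exhalation_valve: bool = True
    relief_open: bool = False
    antiasphyxia_open: bool = False


def needle_valve_flow(
    regulated_pressure_cmh2o: float,
    downstream_pressure_cmh2o: float,
    setting_lpm: float,
    law: str = "linear",
) -> float:
    """Delivered flow (L/s) through the needle valve for a given downstream
    pressure.

    Calibrated so flow equals the nameplate ``setting_lpm`` at ambient
    downstream pressure, falling to zero when the gradient vanishes.  The
    linear law is ``Q = G * (P_reg - P_down)`` with conductance
    ``G = setting / P_reg``; the orifice law scales with the square root of
    the normalized gradient instead.
    """
    if setting_lpm <= 0:
        raise ValueError("needle valve setting must be > 0 L/min")
    dp = regulated_pressure_cmh2o - downstream_pressure_cmh2o
    if dp <= 0:
        return 0.0
    frac = dp / regulated_pressure_cmh2o
    if law == "orifice":
        frac = math.sqrt(frac)
    elif law != "linear":
        raise ValueError(f"unknown needle valve law: {law!r}")
    return setting_lpm * LPS_PER_LPM * frac


def flow_from_restriction(delta_p_cmh2o: float, coefficient_cmh2o_per_lpm: float) -> float:
    """Flow (L/min) inferred from the pressure drop across the fixed
    flow-sensing restriction, using its linear ("roughly proportional")
    characteristic."""
    if coefficient_cmh2o_per_lpm <= 0:
        raise ValueError("restriction coefficient must be > 0")
    return delta_p_cmh2o / coefficient_cmh2o_per_lpm


def restriction_delta_p(flow_lpm: float, coefficient_cmh2o_per_lpm: float) -> float:
    """Inverse of :func:`flow_from_restriction`; round-trips exactly."""
    if coefficient_cmh2o_per_lpm <= 0:
        raise ValueError("restriction coefficient must be > 0")
    return flow_lpm * coefficient_cmh2o_per_lpm


def update_exhalation_valve(
    valves: ValveState, delivery_path_pressurized: bool
) -> ValveState:
    """Resolve the pilot-operated exhalation valve position.

    The valve is held closed by pilot pressure from the delivery path; the
    bleed solenoid vents the pilot to open it.  Hence: open iff the bleed
    solenoid is open or the delivery path is unpressurized (no closing
    force).
    """
    valves.exhalation_valve = (
        valves.exhalation_bleed_solenoid or not delivery_path_pressurized
    )
    return valves


def apply_safety_valves(
    paw_cmh2o: float, circuit: CircuitParams
) -> tuple[float, bool, bool]:
    """Clamp the patient-port pressure to the mechanical safety envelope.

    Returns ``(clamped paw, relief_open, antiasphyxia_open)``.  The relief
    valve is ideal: it vents whatever flow is needed to cap the port at
    ``relief_pressure_cmh2o``.  The anti-asphyxia valve admits ambient gas so
    the port never falls below ``-antiasphyxia_cmh2o``.
    """
    relief_open = False
    aa_open = False
    if circuit.relief_enabled and paw_cmh2o > circuit.relief_pressure_cmh2o:
        paw_cmh2o = circuit.relief_pressure_cmh2o
        relief_open = True
    if paw_cmh2o < -circuit.antiasphyxia_cmh2o:
        paw_cmh2o = -circuit.antiasphyxia_cmh2o
        aa_open = True
    return paw_cmh2o, relief_open, aa_open
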