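"""Time-cycled control law of the solenoid-valve ventilator.

Breathing is mandatory time cycling (no patient trigger): the delivery
solenoid opens for the set inspiratory time Ti, or closes early once a set
plateau pressure is reached (constant flow with pressure plateau); the
exhalation-bleed solenoid then opens the exhalation valve for the expiratory
time Te, reclosing once the lung has recoiled to PEEP so PEEP is held until
the next breath.  Three alarms are monitored on the recorded waveform: high
pressure, low pressure (circuit disconnect) and insufficient flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .core import Phase, WaveformRecord

__all__ = [
    "VentSettings",
    "AlarmKind",
    "AlarmEvent",
    "schedule_times",
    "rate_from_times",
    "Controller",
    "check_alarms",
]


class VentSettings(BaseModel):
    """Operator-facing setpoints.

    ``plateau_cmh2o=None`` means pure time cycling (no early inspiratory
    termination).  Key names carry unit suffixes deliberately: the device's
    human interfaces mix ms/s and L/min, and a single explicit convention
    prevents silent unit errors.
    """

    model_config = ConfigDict(extra="forbid")

    ti_ms: float = 2000.0
    te_ms: float = 4000.0
    flow_lpm: float = 30.0
    peep_cmh2o: float = 0.0
    plateau_cmh2o: Optional[float] = None
    pmax_alarm_cmh2o: float = 40.0
    fio2: float = 0.21

    @model_validator(mode="after")
    def _check(self) -> "VentSettings":
        if self.ti_ms <= 0 or self.te_ms <= 0:
            raise ValueError("ti_ms and te_ms must be > 0")
        if self.flow_lpm <= 0:
            raise ValueError("flow_lpm must be > 0")
        if self.peep_cmh2o < 0:
            raise ValueError("peep_cmh2o must be >= 0")
        if self.plateau_cmh2o is not None:
            if self.plateau_cmh2o <= self.peep_cmh2o:
                raise ValueError("plateau_cmh2o must exceed peep_cmh2o")
            if self.pmax_alarm_cmh2o <= self.plateau_cmh2o:
                raise ValueError("pmax_alarm_cmh2o must exceed plateau_cmh2o")
        if not 0.21 <= self.fio2 <= 1.0:
            raise ValueError("fio2 must be in [0.21, 1.0]")
        return self

    @property
    def ti_s(self) -> float:
        return self.ti_ms / 1000.0

    @property
    def te_s(self) -> float:
        return self.te_ms / 1000.0

    @property
    def cycle_s(self) -> float:
        return (self.ti_ms + self.te_ms) / 1000.0


class AlarmKind(Enum):
    LOW_PRESSURE = "LOW_PRESSURE"
    HIGH_PRESSURE = "HIGH_PRESSURE"
    INSUFFICIENT_FLOW = "INSUFFICIENT_FLOW"


@dataclass
class AlarmEvent:
    kind: AlarmKind
    time_s: float
    observed_value: float
    units: str


def schedule_times(
    respiratory_rate: float, ie_ratio: tuple[int, int]
) -> tuple[int, int]:
    """Ti/Te (ms) for a target respiratory rate and I:E ratio.

    Ti = 60/rate * i/(i+e) * 1000 and Te = 60/rate * e/(i+e) * 1000, each
    rounded half-up to the nearest millisecond, so Ti + Te = 60000/rate
    within 1 ms.
    """
    i, e = ie_ratio
    if not (1 <= respiratory_rate <= 60):
        raise ValueError("respiratory rate must be in [1, 60] breaths/min")
    if i <= 0 or e <= 0:
        raise ValueError("I:E ratio parts must be positive")
    period_ms = 60.0 / respiratory_rate * 1000.0
    ti = int(np.floor(period_ms * i / (i + e) + 0.5))
    te = int(np.floor(period_ms * e / (i + e) + 0.5))
    return ti, te


def rate_from_times(ti_ms: float, te_ms: float) -> float:
    """Breaths/min implied by Ti + Te (unrounded; round for display)."""
    if ti_ms <= 0 or te_ms <= 0:
        raise ValueError("ti_ms and te_ms must be > 0")
    return 60000.0 / (ti_ms + te_ms)


class Controller:
    """Phase state machine stepped at the plant rate.

    Plateau termination uses a 2-sample debounce on the port pressure so a
    single noisy sample cannot end inspiration early, and latches: once the
    delivery solenoid closes for plateau it stays closed until Ti elapses
    (no valve chatter).  The expiration→PEEP-hold transition fires when the
    lung has recoiled to the PEEP level (expiratory flow ceased), at which
    point the bleed solenoid recloses the exhalation valve to hold PEEP.
    """

    PEEP_EPS_CMH2O = 0.1
    PLATEAU_DEBOUNCE = 2

    def __init__(self, settings: VentSettings):
        self.settings = settings
        self.phase = Phase.INSPIRATION
        self.phase_clock = 0.0  # since start of current breath half
        self._plateau_count = 0
        self._plateau_latched = False
        self.breath_index = 0

    def step(
        self, dt: float, paw_cmh2o: float, palv_cmh2o: float
    ) -> tuple[Phase, bool, bool]:
        """Advance the phase clock by ``dt`` and return
        ``(phase, delivery_solenoid_open, bleed_solenoid_open)``."""
        s = self.settings
        if self.phase in (Phase.INSPIRATION, Phase.PLATEAU_HOLD):
            if (
                self.phase is Phase.INSPIRATION
                and s.plateau_cmh2o is not None
                and not self._plateau_latched
            ):
                if paw_cmh2o >= s.plateau_cmh2o:
                    self._plateau_count += 1
                    if self._plateau_count >= self.PLATEAU_DEBOUNCE:
                        self._plateau_latched = True
                        self.phase = Phase.PLATEAU_HOLD
                else:
                    self._plateau_count = 0
            if self.phase_clock >= s.ti_s - 0.5 * dt:
                self.phase = Phase.EXPIRATION
                self.phase_clock = 0.0
        else:  # EXPIRATION / PEEP_HOLD
            if (
                self.phase is Phase.EXPIRATION
                and palv_cmh2o <= s.peep_cmh2o + self.PEEP_EPS_CMH2O
            ):
                self.phase = Phase.PEEP_HOLD
            if self.phase_clock >= s.te_s - 0.5 * dt:
                self.phase = Phase.INSPIRATION
                self.phase_clock = 0.0
                self._plateau_count = 0
                self._plateau_latched = False
                self.breath_index += 1
        delivery = self.phase is Phase.INSPIRATION
        bleed = self.phase is Phase.EXPIRATION
        self.phase_clock += dt
        return self.phase, delivery, bleed


def check_alarms(
    waveform: WaveformRecord,
    settings: VentSettings,
    disconnect_margin_cmh2o: float = 2.0,
    flow_fraction: float = 0.5,
) -> list[AlarmEvent]:
    """Scan a recorded waveform for the three alarm conditions.

    HIGH_PRESSURE: any sample above the Pmax alarm setting.  LOW_PRESSURE:
    a full cycle whose peak pressure never rises above PEEP plus the
    disconnect margin (the signature of a circuit disconnect).
    INSUFFICIENT_FLOW: mean delivered inspiratory flow below
    ``flow_fraction`` of the flow setpoint.  The evaluation window is one
    Ti+Te cycle.
    """
    cycle_s = settings.cycle_s
    if waveform.duration_s < cycle_s:
        raise ValueError(
            f"waveform covers {waveform.duration_s:.2f} s, "
            f"shorter than one {cycle_s:.2f} s cycle"
        )
    alarms: list[AlarmEvent] = []
    t = waveform.time_s
    paw = waveform.paw_cmh2o
    flow = waveform.flow_lpm

    hi = np.nonzero(paw > settings.pmax_alarm_cmh2o)[0]
    if hi.size:
        k = int(hi[0])
        alarms.append(
            AlarmEvent(AlarmKind.HIGH_PRESSURE, float(t[k]), float(paw[k]), "cmH2O")
        )

    n_per_cycle = max(1, int(round(cycle_s / waveform.sample_interval_s)))
    n_cycles = len(waveform) // n_per_cycle
    low_thresh = settings.peep_cmh2o + disconnect_margin_cmh2o
    for c in range(n_cycles):
        seg = slice(c * n_per_cycle, (c + 1) * n_per_cycle)
        peak = float(paw[seg].max())
        if peak < low_thresh:
            alarms.append(
                AlarmEvent(AlarmKind.LOW_PRESSURE, float(t[seg][0]), peak, "cmH2O")
            )
            break

    insp = flow > 1.0  # delivered-flow samples, L/min
    if insp.any():
        mean_insp = float(flow[insp].mean())
    else:
        mean_insp = 0.0
    if mean_insp < flow_fraction * settings.flow_lpm:
        alarms.append(
            AlarmEvent(
                AlarmKind.INSUFFICIENT_FLOW, float(t[0]), mean_insp, "L/min"
            )
        )
    return alarms
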