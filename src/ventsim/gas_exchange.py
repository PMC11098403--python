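"""Steady-state arterial blood-gas estimation from ventilator output.

Links the delivered minute ventilation (VT, RR) and FiO2 to an ABG-style
triple (pH, PaCO2, PaO2) through three classical relations:

* alveolar ventilation      VA = (VT - VD) * RR / 1000          [L/min]
* CO2 balance               PaCO2 = 0.863 * VCO2 / VA           [mmHg]
* Henderson-Hasselbalch     pH = 6.1 + log10(HCO3 / (0.03*PaCO2))
* alveolar gas equation     PAO2 = FiO2*(Pb - PH2O) - PaCO2/RQ,
                            PaO2 = PAO2 - (A-a gradient)

The contract is *consistency*, not prediction: given a measured ABG triple
one can invert these relations for subject parameters (dead space, CO2
production, bicarbonate, respiratory quotient, A-a gradient) and check that
they land in a physiologic range — see :func:`fit_subject_to_abg`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "SubjectParams",
    "ABGEstimate",
    "alveolar_ventilation",
    "predict_paco2",
    "predict_ph",
    "bicarbonate_from_ph",
    "predict_pao2",
    "estimate_abg",
    "fit_subject_to_abg",
]


class SubjectParams(BaseModel):
    """Physiologic constants of the (passive, anesthetized) subject.

    Defaults are textbook conventions: barometric pressure 760 mmHg, water
    vapor 47 mmHg at body temperature, respiratory quotient 0.8.
    """

    model_config = ConfigDict(extra="forbid")

    co2_production_ml_min: float = 200.0
    dead_space_ml: float = 150.0
    bicarbonate_mmol_l: float = 24.0
    barometric_pressure_mmhg: float = 760.0
    water_vapor_pressure_mmhg: float = 47.0
    respiratory_quotient: float = 0.8
    aa_gradient_mmhg: float = 10.0

    @model_validator(mode="after")
    def _check(self) -> "SubjectParams":
        for name in (
            "co2_production_ml_min",
            "dead_space_ml",
            "bicarbonate_mmol_l",
            "barometric_pressure_mmhg",
            "water_vapor_pressure_mmhg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.6 < self.respiratory_quotient < 1.2:
            raise ValueError("respiratory_quotient must be in (0.6, 1.2)")
        if self.aa_gradient_mmhg < 0:
            raise ValueError("aa_gradient_mmhg must be >= 0")
        return self


@dataclass
class ABGEstimate:
    ph: float
    paco2_mmhg: float
    pao2_mmhg: float
    alveolar_ventilation_l_min: float


def alveolar_ventilation(vt_ml: float, rr: float, dead_space_ml: float) -> float:
    """VA = (VT - VD) * RR / 1000, in L/min; errors if VT <= dead space."""
    if vt_ml <= dead_space_ml:
        raise ValueError(
            f"tidal volume {vt_ml} mL must exceed dead space {dead_space_ml} mL"
        )
    if rr <= 0:
        raise ValueError("respiratory rate must be > 0")
    return (vt_ml - dead_space_ml) * rr / 1000.0


def predict_paco2(va_l_min: float, co2_production_ml_min: float) -> float:
    """Steady-state PaCO2 (mmHg) from the CO2 balance 0.863 * VCO2 / VA."""
    if va_l_min <= 0:
        raise ValueError("alveolar ventilation must be > 0")
    return 0.863 * co2_production_ml_min / va_l_min


def predict_ph(paco2_mmhg: float, bicarbonate_mmol_l: float) -> float:
    """Henderson-Hasselbalch: pH = 6.1 + log10(HCO3 / (0.03 * PaCO2))."""
    if paco2_mmhg <= 0 or bicarbonate_mmol_l <= 0:
        raise ValueError("PaCO2 and bicarbonate must be > 0")
    return 6.1 + math.log10(bicarbonate_mmol_l / (0.03 * paco2_mmhg))


def bicarbonate_from_ph(ph: float, paco2_mmhg: float) -> float:
    """Algebraic inverse of :func:`predict_ph`; round-trips exactly."""
    if paco2_mmhg <= 0:
        raise ValueError("PaCO2 must be > 0")
    return 0.03 * paco2_mmhg * 10.0 ** (ph - 6.1)


def predict_pao2(fio2: float, paco2_mmhg: float, subject: SubjectParams) -> float:
    """Alveolar gas equation minus the A-a gradient, floored at 0 mmHg."""
    if not 0.21 <= fio2 <= 1.0:
        raise ValueError("fio2 must be in [0.21, 1.0]")
    pao2_alv = (
        fio2 * (subject.barometric_pressure_mmhg - subject.water_vapor_pressure_mmhg)
        - paco2_mmhg / subject.respiratory_quotient
    )
    return max(pao2_alv - subject.aa_gradient_mmhg, 0.0)


def estimate_abg(
    vt_ml: float, rr: float, fio2: float, subject: SubjectParams | None = None
) -> ABGEstimate:
    """Forward chain: ventilation -> PaCO2 -> pH and PaO2."""
    if subject is None:
        subject = SubjectParams()
    va = alveolar_ventilation(vt_ml, rr, subject.dead_space_ml)
    paco2 = predict_paco2(va, subject.co2_production_ml_min)
    ph = predict_ph(paco2, subject.bicarbonate_mmol_l)
    pao2 = predict_pao2(fio2, paco2, subject)
    return ABGEstimate(ph=ph, paco2_mmhg=paco2, pao2_mmhg=pao2, alveolar_ventilation_l_min=va)


def fit_subject_to_abg(
    ph: float,
    paco2_mmhg: float,
    pao2_mmhg: float,
    vt_ml: float,
    rr: float,
    fio2: float,
    dead_space_bounds_ml: tuple[float, float] = (100.0, 200.0),
    co2_production_bounds: tuple[float, float] = (150.0, 250.0),
    bicarbonate_bounds: tuple[float, float] = (24.0, 30.0),
) -> SubjectParams:
    """Invert the gas-exchange relations for subject parameters that
    reproduce a measured ABG triple at the given ventilator output.

    Dead space and CO2 production trade off along VCO2 = PaCO2*VA/0.863;
    the dead space is chosen (within bounds) to centre VCO2 in its bounds.
    Bicarbonate follows algebraically from (pH, PaCO2).  The A-a gradient
    absorbs the PaO2 residual at RQ 0.8; if the measured PaO2 exceeds the
    alveolar PO2 at RQ 0.8 the respiratory quotient is raised (toward its
    physiologic ceiling) instead and the gradient pinned near zero.
    The returned parameters are a *consistency witness* — forward-checking
    them through :func:`estimate_abg` is the caller's test.
    """
    ds_lo, ds_hi = dead_space_bounds_ml
    vco2_lo, vco2_hi = co2_production_bounds

    def vco2_for(ds: float) -> float:
        return paco2_mmhg * alveolar_ventilation(vt_ml, rr, ds) / 0.863

    # VCO2(ds) is decreasing in ds; aim for the centre of the VCO2 bounds
    target_vco2 = 0.5 * (vco2_lo + vco2_hi)
    # invert: VA = 0.863*VCO2/PaCO2, ds = VT - 1000*VA/RR
    va_needed = 0.863 * target_vco2 / paco2_mmhg
    ds = vt_ml - 1000.0 * va_needed / rr
    ds = min(max(ds, ds_lo), ds_hi)
    vco2 = vco2_for(ds)

    hco3 = bicarbonate_from_ph(ph, paco2_mmhg)
    hco3 = min(max(hco3, bicarbonate_bounds[0]), bicarbonate_bounds[1])

    pb, ph2o = 760.0, 47.0
    rq = 0.8
    pao2_alv = fio2 * (pb - ph2o) - paco2_mmhg / rq
    aa = pao2_alv - pao2_mmhg
    if aa < 0.0:
        # measured PaO2 above the RQ-0.8 alveolar PO2: push RQ up (less CO2
        # displacement of alveolar O2) and pin the gradient near zero
        denom = fio2 * (pb - ph2o) - pao2_mmhg
        rq = paco2_mmhg / denom if denom > 0 else 1.199
        rq = min(max(rq, 0.601), 1.199)
        aa = max(fio2 * (pb - ph2o) - paco2_mmhg / rq - pao2_mmhg, 0.0)

    return SubjectParams(
        co2_production_ml_min=vco2,
        dead_space_ml=ds,
        bicarbonate_mmol_l=hco3,
        barometric_pressure_mmhg=pb,
        water_vapor_pressure_mmhg=ph2o,
        respiratory_quotient=rq,
        aa_gradient_mmhg=aa,
    )
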