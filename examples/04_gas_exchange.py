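"""Steady-state ABG estimation: forward prediction for a delivered
VT/RR/FiO2, and the consistency inversion that recovers physiologic subject
parameters from a measured ABG triple.

Run:  python examples/04_gas_exchange.py
"""

from ventsim import SubjectParams, estimate_abg, fit_subject_to_abg

# forward: what ABG does VT 500 / RR 20 / room air imply for a 60 kg subject?
subject = SubjectParams(co2_production_ml_min=200, dead_space_ml=150,
                        bicarbonate_mmol_l=26, aa_gradient_mmhg=12)
est = estimate_abg(vt_ml=500, rr=20, fio2=0.21, subject=subject)
print(f"forward estimate : pH {est.ph:.3f}  PaCO2 {est.paco2_mmhg:.1f} mmHg  "
      f"PaO2 {est.pao2_mmhg:.1f} mmHg  (VA {est.alveolar_ventilation_l_min:.1f} L/min)")

# inverse: which subject is consistent with a measured triple at the same vent output?
measured = (7.538, 34.5, 91.7)
fit = fit_subject_to_abg(*measured, vt_ml=500, rr=20, fio2=0.21)
back = estimate_abg(500, 20, 0.21, fit)
print(f"measured ABG     : pH {measured[0]}  PaCO2 {measured[1]}  PaO2 {measured[2]}")
print(f"fitted subject   : VD {fit.dead_space_ml:.0f} mL  VCO2 {fit.co2_production_ml_min:.0f} mL/min  "
      f"HCO3 {fit.bicarbonate_mmol_l:.1f} mmol/L  A-a {fit.aa_gradient_mmhg:.1f} mmHg")
print(f"forward check    : pH {back.ph:.3f}  PaCO2 {back.paco2_mmhg:.1f}  PaO2 {back.pao2_mmhg:.1f}")
# The fitted parameters land in normal ranges: the ventilator output and the
# measured blood gases are mutually consistent.
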