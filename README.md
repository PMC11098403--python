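# ventsim

A desk-scale digital twin of a solenoid-valve, time-cycled, constant-flow
emergency ventilator — the class of low-cost device built during ventilator
shortages from a pressure regulator, a needle valve, two fast solenoid
valves and a pilot-operated exhalation valve — coupled to a passive
single-compartment lung, with a virtual test bench and a steady-state
gas-exchange estimator.

It is written for people who design, review or teach about such devices and
want to interrogate the control law and pneumatics without a gas supply or
a physical breathing simulator: respiratory-care engineers, medical-device
reviewers, and students of respiratory mechanics.

## The model

The plant is the linear equation of motion of respiratory mechanics for a
passive patient,

    Paw(t) = V(t)/C + R·Q(t),        dV/dt = 1000·Q(t),

with compliance `C` (mL/cmH2O) and a lumped resistance `R` (cmH2O/(L/s));
only volume above the relaxation volume is tracked. Inspiratory flow comes
from a needle valve fed by a regulated supply, modelled as a calibrated
conductance, so delivered flow sags as airway pressure rises — the
mechanism by which delivered tidal volume falls on stiff or obstructed
lungs. Expiration is passive recoil through the exhalation valve against
the PEEP back-pressure, `Q = −(Palv − PEEP)/R`, giving the classic
exponential decay with time constant `τ = R·C`.

The controller is mandatory time cycling: the delivery solenoid opens for
`Ti` (or until an optional plateau pressure is reached), the
exhalation-bleed solenoid opens the exhalation valve for `Te` and recloses
it once the lung has recoiled to PEEP. Ti/Te follow the standard schedule
`Ti = 60/RR × i/(i+e) × 1000` ms for an I:E ratio `i:e`. A mechanical
relief valve caps the port pressure, an anti-asphyxia valve floors it, and
three alarms (high pressure, low pressure/disconnect, insufficient flow)
are scanned on the recorded waveform.

The gas-exchange module chains alveolar ventilation
`VA = (VT − VD)·RR/1000`, the CO2 balance `PaCO2 = 0.863·VCO2/VA`,
Henderson–Hasselbalch `pH = 6.1 + log10(HCO3/(0.03·PaCO2))` and the
alveolar gas equation `PAO2 = FiO2·(Pb − PH2O) − PaCO2/RQ` to turn a
delivered VT/RR/FiO2 into an ABG-style triple, and can invert the chain to
check a measured ABG for consistency with physiologic subject parameters.

## Worked example

```python
from ventsim import LungParams, VentSettings, extract_breath_metrics, step_simulation

settings = VentSettings(ti_ms=2000, te_ms=4000, flow_lpm=30, peep_cmh2o=5)
lung = LungParams(compliance_ml_per_cmh2o=100, resistance_cmh2o_per_l_s=5)
result = step_simulation(settings, lung, duration_s=60.0,
                         initial_volume_ml=settings.peep_cmh2o * lung.compliance_ml_per_cmh2o)
m = extract_breath_metrics(result.waveform)
print(round(m.respiratory_rate, 1), round(m.tidal_volume_ml, 1),
      round(m.peak_airway_pressure_cmh2o, 1), round(m.measured_peep_cmh2o, 1))
```

prints

```
10.0 836.5 15.4 5.1
```

— ten breaths per minute (60000/(2000+4000) ms), ~836 mL delivered per
breath (below the naive 30 L/min × 2 s = 1000 mL because the needle-valve
flow sags as pressure rises), a peak pressure of ~15 cmH2O and an
end-expiratory pressure holding the 5 cmH2O PEEP setting.

The `examples/` directory holds one short script per capability: breath
simulation and metrics, the compliance/resistance bench sweep, needle-valve
calibration to a target VT, gas-exchange estimation/consistency, and
Ti/Te scheduling with alarm scans. A thin CLI wraps the same functions:
`ventsim simulate|bench|calibrate|gasx|fixtures --help`.

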