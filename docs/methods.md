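# Methods

## Plant model

The patient and circuit are lumped into a passive single-compartment lung:
one compliance `C` (mL/cmH2O) and one resistance `R` (cmH2O/(L/s)) that
absorbs airway, endotracheal tube and circuit losses. The state variable is
the volume above the relaxation volume; absolute lung volume (FRC) is not
modelled because nothing in the twin depends on it. Alveolar pressure is
`Palv = V/C` by construction at every step, and the patient-port pressure is
`Paw = Palv + R·Q` with flow `Q` signed positive into the patient.

Assumptions: linear, volume-independent compliance and resistance; no
spontaneous respiratory effort (the device is strictly time-cycled and the
modelled patient passive); incompressible gas and rigid tubing, so flow is
algebraic in the pressures and the only state is lung volume.

During expiration the full resistive drop sits between the alveoli and the
exhalation valve, so the recorded port pressure falls to the PEEP
back-pressure essentially at valve opening — as on real machines, where the
gradual expiratory decay is visible in the *flow* trace, not the pressure
trace. Checks of the expiratory time constant therefore fit
`log(−flow)` against time; alveolar pressure and volume decay with the same
`τ = R·C`.

## Pneumatics

* **Needle valve / regulator.** Default is a linear conductance calibrated
  to the nameplate dial: `Q = (setting/P_reg)·(P_reg − P_down)`, so the dial
  value is delivered into an unpressurized circuit and flow sags linearly
  as port pressure approaches the regulated supply (default 70 cmH2O — a
  typical regulator setting for this kind of circuit, exposed in the
  config). The sag is what makes delivered VT fall on stiff/obstructed
  lungs while the time-cycled rate stays fixed. An orifice (√ΔP) law is
  available (`needle_valve_law: orifice`); the linear default keeps the
  plant analytically checkable. During inspiration the valve–lung coupling
  is solved implicitly each step (closed form for both laws).
* **Flow sensing.** The fixed restriction is linear: `Q = ΔP/k` with
  `k = 0.1 cmH2O/(L/min)` by default; the inverse round-trips exactly.
* **Exhalation valve.** Pilot-operated: pressurizing the pilot from the
  delivery path closes it, venting the pilot through the bleed solenoid
  opens it. The pure truth table (`open ⇔ bleed open ∨ pilot
  unpressurized`) is exposed as `update_exhalation_valve`; inside the
  simulation loop the pilot is treated as pressurized whenever the bleed
  solenoid is closed (regulator-side gas stays trapped), which is what lets
  the controller reclose the valve to hold PEEP.
* **Safety valves.** Ideal clamps: the relief valve vents whatever flow is
  needed to cap the port at `relief_pressure` (default 60 cmH2O, below the
  regulated supply), the anti-asphyxia valve admits ambient gas below
  −2 cmH2O. Openings are logged as timestamped events.
* **Sensor noise.** Optional zero-mean Gaussian noise is added to the
  *recorded* samples only (defaults 0; the bench examples use
  0.2 cmH2O / 0.5 L/min to emulate replicate scatter of the order seen on a
  physical rig). The plant and controller are deterministic, so noise-free
  runs are bit-identical and seeded runs exactly reproducible; because
  noise enters as `sd × standard normal`, replicate SDs scale linearly
  with the configured sd.

## Controller

Four phases per breath: INSPIRATION (delivery solenoid open),
PLATEAU_HOLD (delivery closed early once port pressure reaches the optional
plateau setting, with a 2-sample debounce, latched until Ti elapses — no
valve chatter), EXPIRATION (bleed solenoid opens the exhalation valve), and
PEEP_HOLD. The expiration→PEEP-hold transition fires when alveolar
pressure has recoiled to within 0.1 cmH2O of PEEP, i.e. when expiratory
flow has ceased; the port-pressure sensor cannot serve here because it
reads the PEEP back-pressure throughout expiration in this lumped plant.
Ti/Te scheduling uses `Ti = 60/RR·i/(i+e)·1000` ms rounded half-up to the
nearest millisecond — one consistent rule; the published timing chart mixes
truncation and rounding, which a ±1 ms tolerance absorbs.

Alarms are scanned on the recorded waveform per Ti+Te cycle: HIGH_PRESSURE
above the Pmax setting, LOW_PRESSURE when a whole cycle's peak stays below
PEEP + 2 cmH2O (disconnect signature), INSUFFICIENT_FLOW when mean
delivered inspiratory flow is below half the dial setting. The margin,
fraction and window are conventions of this twin, all configurable.

## Integration scheme

Fixed-step explicit Euler at `dt = 1 ms` (capped at 2 ms). The plant is a
first-order linear system whose smallest physiologic time constant
(C 10 mL/cmH2O, R 5 ⇒ τ = 50 ms) is far above the step, so the explicit
scheme is stable; the suite verifies convergence by step halving
(end-of-cycle volume moves < 0.05%), agreement with the constant-flow
closed form within 0.5%, and volume conservation (net integrated flow
equals the volume change to well under 0.1% of a breath — exact by
construction unless a safety clamp intervenes). Waveforms are sampled at
10 ms by default. A guard keeps recoil from undershooting the PEEP level
within a step; volume is floored at zero.

## Virtual bench

Breath detection on the sampled waveform: inspiratory onset where flow
rises through 2 L/min and stays above it for 3 samples (the run-length
requirement keeps single noisy samples from splitting a breath); first and
last partial breaths discarded. VT is the trapezoidal integral of positive
flow per breath (exact for square profiles with shared edge halves), Pkp
the per-breath pressure maximum, PEEP the mean pressure over the last 10%
of each breath window, RR `60/median(period)`. The onset threshold and
end-expiratory window are measurement conventions, configurable. With flow
noise enabled, positive-clipping rectifies a few mL of noise into VT — the
same bias an integrating flow meter with a one-way pickup would show —
which is why quantitative checks use noise-free runs.

The protocol sweep runs each condition `replicates` times (seeds spawned
from one master seed) for 8 cycles each and reports mean ± SD. The sweep's
published counterpart reports VT/Pkp magnitudes that are inconsistent with
the nameplate dial × Ti product (the physical device's effective delivered
flow was uncharacterized), so magnitudes are treated as qualitative trend
anchors only — the twin reproduces the *directions* (VT falls, Pkp rises as
C drops or R rises) and the rate column exactly, and the calibration loop
below reproduces the tuned-VT protocol quantitatively. The bench defaults
to PEEP 0 since the published sweep does not state the applied PEEP.

Flow calibration bisects the dial setting (bracket 0.5–150 L/min, ≤ 40
iterations) until the bench-measured VT is within 1% of target, short
noise-free runs of 6 cycles each starting from the end-expiratory
equilibrium volume; the returned setting is confirmed by an independent
re-simulation. An unreachable target (e.g. relief-capped) raises an error
reporting the maximum achievable volume.

## Gas exchange

Forward chain: `VA = (VT − VD)·RR/1000`; `PaCO2 = 0.863·VCO2/VA`;
`pH = 6.1 + log10(HCO3/(0.03·PaCO2))`; `PAO2 = FiO2·(Pb − PH2O) − PaCO2/RQ`
with `PaO2 = PAO2 − AaDO2`, floored at 0. Conventions: Pb 760 mmHg, PH2O
47 mmHg, RQ 0.8, FiO2 0.21 for room air. The module's contract is
*consistency*, not prediction: measured ABG triples are inverted for a
subject-parameter witness (dead space chosen within 100–200 mL to centre
VCO2 in 150–250 mL/min; bicarbonate algebraic from pH/PaCO2; the A–a
gradient absorbing the PaO2 residual at RQ 0.8) and forward-checked. One
of the anchored triples has a PaO2 above the alveolar PO2 reachable at
RQ 0.8; the fitter then raises RQ toward its physiologic ceiling (< 1.2)
with the gradient pinned near zero, which is the only consistent
physiologic reading of such a value under this model. Dynamic CO2
kinetics, shunt/V̇–Q̇ heterogeneity and hemoglobin chemistry are out of
scope.

## Synthetic fixtures

`generate_fixture_waveform` builds square, triangular and measured-like
traces with analytically known VT/RR/Pkp/PEEP so the metrics module is
testable standalone; the square profile is constructed to integrate exactly
under the trapezoid rule, the triangle to within 0.5%. These fixtures are
synthetic constructions and emulate none of the interactive dynamics of a
real rig — passing metrics tests on them shows the *measurement* chain is
correct, not that the plant is realistic; plant realism is covered by the
closed-form and trend checks above.

## Problem sizes

Default analyses use 60 s runs (10 breaths) for rate/volume measurement,
8-cycle runs per bench replicate, 6-cycle runs inside the calibration
loop, and 2-cycle runs across the 100-condition randomized safety scan —
sizes at which every quantity reported here is converged (doubling run
lengths changes measured VT/RR by far less than the stated tolerances).

## Known limitations

Single linear compartment only (no pressure-dependent compliance, no
multi-compartment heterogeneity); no spontaneous effort or triggering; no
gas compressibility, tubing compliance or humidification; FiO2 is carried
as metadata into gas exchange, not blended pneumatically; solenoid
actuation delay is modelled as a pure command delay (default 0); the
gas-exchange module is steady-state only.
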