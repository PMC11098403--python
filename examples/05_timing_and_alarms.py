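"""Ti/Te scheduling for a target rate, and the alarm scan on fault
scenarios (occlusion and circuit disconnect).

Run:  python examples/05_timing_and_alarms.py
"""

from ventsim import (
    LungParams,
    VentSettings,
    check_alarms,
    rate_from_times,
    schedule_times,
    step_simulation,
)

for rate, ratio in [(10, (1, 2)), (20, (1, 3)), (24, (1, 3))]:
    ti, te = schedule_times(rate, ratio)
    print(f"rate {rate:2d} I:E {ratio[0]}:{ratio[1]} -> Ti {ti:4d} ms  Te {te:4d} ms "
          f"(implied rate {rate_from_times(ti, te):.1f})")

settings = VentSettings(ti_ms=2000, te_ms=4000, flow_lpm=30, pmax_alarm_cmh2o=40)
scenarios = {
    "nominal": LungParams(),
    "occlusion (C=1)": LungParams(compliance_ml_per_cmh2o=1.0),
    "disconnect": LungParams(compliance_ml_per_cmh2o=5e4, resistance_cmh2o_per_l_s=0.5),
}
for name, lung in scenarios.items():
    res = step_simulation(settings, lung, duration_s=12.0)
    alarms = sorted({a.kind.value for a in check_alarms(res.waveform, settings)})
    print(f"{name:16s} -> alarms: {alarms or 'none'}  "
          f"(peak {res.waveform.paw_cmh2o.max():.1f} cmH2O)")
# Occlusion drives pressure into the relief cap and trips HIGH_PRESSURE;
# a disconnect leaves the circuit unpressurized and trips LOW_PRESSURE.
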