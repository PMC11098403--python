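import pytest

from ventsim import CircuitParams, LungParams, VentSettings, step_simulation


@pytest.fixture
def normal_lung() -> LungParams:
    """Normal adult mechanics: C 100 mL/cmH2O, R 5 cmH2O/(L/s)."""
    return LungParams(compliance_ml_per_cmh2o=100.0, resistance_cmh2o_per_l_s=5.0)


@pytest.fixture
def nominal_settings() -> VentSettings:
    """Rate-10 timing at I:E 1:2 with a 30 L/min flow dial."""
    return VentSettings(ti_ms=2000, te_ms=4000, flow_lpm=30)


@pytest.fixture
def ideal_circuit() -> CircuitParams:
    """Near-infinite supply pressure: the needle valve delivers its
    nameplate flow with negligible sag, so constant-flow closed forms
    apply."""
    return CircuitParams(
        regulated_pressure_cmh2o=1e6, relief_pressure_cmh2o=1e5
    )


@pytest.fixture(scope="session")
def nominal_run():
    """One shared noise-free 30 s run at the nominal bench condition."""
    settings = VentSettings(ti_ms=2000, te_ms=4000, flow_lpm=30)
    lung = LungParams()
    return step_simulation(settings, lung, duration_s=30.0)
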