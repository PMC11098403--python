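"""Synthetic waveform generator for standalone testing of the breath-metric
analysis: traces with analytically known VT/RR/Pkp/PEEP that the metrics
module must recover.  All fixtures produced here are synthetic constructions,
not recordings.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .core import WaveformRecord

__all__ = ["generate_fixture_waveform"]

Shape = Literal["square", "triangular", "measured-like"]


def generate_fixture_waveform(
    shape: Shape = "square",
    vt_ml: float = 500.0,
    rr: float = 10.0,
    pkp_cmh2o: float = 15.0,
    peep_cmh2o: float = 0.0,
    n_breaths: int = 6,
    ti_fraction: float = 1.0 / 3.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sample_interval_s: float = 0.01,
) -> WaveformRecord:
    """Build a waveform with known ground truth.

    ``square`` delivers a constant inspiratory flow sized so the trapezoidal
    integral per breath is exactly ``vt_ml``; ``triangular`` ramps flow up
    and back down (same analytic area); ``measured-like`` adds an
    exponential expiratory flow tail and a rounded pressure rise.  Pressure
    ramps from PEEP to ``pkp_cmh2o`` during inspiration and sits at PEEP
    through expiration.  ``noise_sd`` adds per-sample Gaussian noise (cmH2O
    on pressure, L/min on flow); identical seeds give identical records.

    A short zero-flow lead-in is prepended and the record ends mid-breath,
    so the analysis module's discard-partials rule is exercised.
    """
    if vt_ml <= 0 or rr <= 0 or not 0 < ti_fraction < 1:
        raise ValueError("fixture parameters must be physiologic")
    if pkp_cmh2o < peep_cmh2o:
        raise ValueError("pkp_cmh2o must be >= peep_cmh2o")
    dt = sample_interval_s
    period_s = 60.0 / rr
    n_per = int(round(period_s / dt))
    n_on = max(2, int(round(period_s * ti_fraction / dt)))
    ti_eff = n_on * dt

    flow_one = np.zeros(n_per)
    if shape == "square":
        q_lpm = vt_ml / 1000.0 / ti_eff * 60.0
        flow_one[:n_on] = q_lpm
    elif shape == "triangular":
        peak_lpm = 2.0 * vt_ml / 1000.0 / ti_eff * 60.0
        half = n_on // 2
        flow_one[: half + 1] = np.linspace(0.0, peak_lpm, half + 1)
        flow_one[half : n_on + 1] = np.linspace(peak_lpm, 0.0, n_on - half + 1)
    elif shape == "measured-like":
        q_lpm = vt_ml / 1000.0 / ti_eff * 60.0
        flow_one[:n_on] = q_lpm
        n_exp = n_per - n_on
        tau = max(period_s * 0.08, 2 * dt)
        texp = np.arange(n_exp) * dt
        flow_one[n_on:] = -q_lpm * 0.8 * np.exp(-texp / tau)
    else:
        raise ValueError(f"unknown fixture shape: {shape!r}")

    paw_one = np.full(n_per, float(peep_cmh2o))
    if shape == "measured-like":
        rise = 1.0 - np.exp(-np.arange(n_on) / max(n_on / 4.0, 1.0))
        paw_one[:n_on] = peep_cmh2o + (pkp_cmh2o - peep_cmh2o) * rise / rise.max()
    else:
        paw_one[:n_on] = np.linspace(peep_cmh2o, pkp_cmh2o, n_on)

    lead = n_per // 4
    tail = n_on // 2  # ends mid-inspiration: a trailing partial breath
    flow = np.concatenate([np.zeros(lead), np.tile(flow_one, n_breaths), flow_one[:tail]])
    paw = np.concatenate(
        [np.full(lead, peep_cmh2o), np.tile(paw_one, n_breaths), paw_one[:tail]]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        paw = paw + noise_sd * rng.standard_normal(len(paw))
        flow = flow + noise_sd * rng.standard_normal(len(flow))
    t = np.arange(len(flow)) * dt
    return WaveformRecord(
        time_s=t,
        paw_cmh2o=paw,
        flow_lpm=flow,
        sample_interval_s=dt,
        meta={
            "shape": shape,
            "vt_ml": vt_ml,
            "rr": rr,
            "pkp_cmh2o": pkp_cmh2o,
            "peep_cmh2o": peep_cmh2o,
            "seed": seed,
        },
    )
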