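"""Delimited-text I/O for waveforms, bench tables and event/alarm logs.

All writers embed the configuration echo and seed as ``#``-prefixed header
lines, so any output file carries what is needed to reproduce it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .controller import AlarmEvent
from .core import WaveformRecord

__all__ = [
    "write_waveform",
    "read_waveform",
    "write_bench_table",
    "write_events",
    "write_alarms",
]

WAVEFORM_COLUMNS = ["time_s", "paw_cmh2o", "flow_lpm"]


def _write_header(fh, echo: str | None, seed: int | None) -> None:
    if echo is not None:
        fh.write(f"# config: {echo}\n")
    if seed is not None:
        fh.write(f"# seed: {seed}\n")


def write_waveform(
    waveform: WaveformRecord,
    path: str | Path,
    echo: str | None = None,
    seed: int | None = None,
) -> None:
    df = pd.DataFrame(
        {
            "time_s": waveform.time_s,
            "paw_cmh2o": waveform.paw_cmh2o,
            "flow_lpm": waveform.flow_lpm,
        }
    )
    with open(path, "w") as fh:
        _write_header(fh, echo, seed)
        df.to_csv(fh, index=False, float_format="%.6g")


def read_waveform(path: str | Path) -> WaveformRecord:
    """Read a waveform table (``time_s,paw_cmh2o,flow_lpm``), skipping
    ``#`` header lines; the sample interval is recovered from the time
    column."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in WAVEFORM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"waveform file {path} lacks columns: {missing}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("waveform file must contain at least two samples")
    interval = float(np.median(np.diff(t)))
    return WaveformRecord(
        time_s=t,
        paw_cmh2o=df["paw_cmh2o"].to_numpy(float),
        flow_lpm=df["flow_lpm"].to_numpy(float),
        sample_interval_s=interval,
    )


def write_bench_table(
    table: pd.DataFrame,
    path: str | Path,
    echo: str | None = None,
    seed: int | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, echo, seed)
        table.to_csv(fh, index=False, float_format="%.6g")


def write_events(
    events: list[tuple[float, str, float]],
    path: str | Path,
    echo: str | None = None,
    seed: int | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, echo, seed)
        fh.write("time_s,event,value\n")
        for t, name, value in events:
            fh.write(f"{t:.6g},{name},{value:.6g}\n")


def write_alarms(
    alarms: list[AlarmEvent],
    path: str | Path,
    echo: str | None = None,
    seed: int | None = None,
) -> None:
    with open(path, "w") as fh:
        _write_header(fh, echo, seed)
        fh.write("time_s,alarm,observed_value,units\n")
        for a in alarms:
            fh.write(f"{a.time_s:.6g},{a.kind.value},{a.observed_value:.6g},{a.units}\n")
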