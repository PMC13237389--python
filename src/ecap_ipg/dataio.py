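"""Plain-text persistence for sweep sets and I/O functions.

Sweep sets travel as a CSV matrix (rows = sweeps, columns = samples) plus
a JSON sidecar carrying sampling metadata; I/O functions as a tidy CSV
with one row per measured point (subject, electrode, ipg_us, level_cl,
amplitude_uv, c_level, phase_us).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import IOFunction, SweepSet

__all__ = ["write_sweeps", "read_sweeps", "write_io_functions", "read_io_functions"]


def write_sweeps(sweeps: SweepSet, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    np.savetxt(csv_path, sweeps.data, delimiter=",", fmt="%.10g")
    meta = {
        "sampling_rate_hz": sweeps.sampling_rate,
        "t0_offset_us": sweeps.t0_offset_us,
        "n_sweeps": sweeps.n_sweeps,
        "n_samples": sweeps.n_samples,
    }
    extra = {k: v for k, v in sweeps.metadata.items() if isinstance(v, (str, int, float))}
    sidecar_path.write_text(json.dumps({**meta, **extra}, indent=2, sort_keys=True))


def read_sweeps(csv_path, sidecar_path=None) -> SweepSet:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    data = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    return SweepSet(
        data=data,
        sampling_rate=meta["sampling_rate_hz"],
        t0_offset_us=meta.get("t0_offset_us", 0.0),
        metadata=meta,
    )


def write_io_functions(functions, path) -> None:
    rows = []
    for io in functions:
        for lvl, amp in zip(io.levels, io.amplitudes):
            rows.append({
                "subject": io.subject,
                "electrode": io.electrode,
                "ipg_us": io.ipg,
                "level_cl": lvl,
                "amplitude_uv": amp,
                "c_level": io.c_level,
                "phase_us": io.phase_duration,
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_io_functions(path) -> list:
    df = pd.read_csv(path)
    out = []
    keys = ["subject", "electrode", "ipg_us"]
    for (subject, electrode, ipg), sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("level_cl")
        out.append(IOFunction(
            levels=sub["level_cl"].to_numpy(),
            amplitudes=sub["amplitude_uv"].to_numpy(),
            c_level=float(sub["c_level"].iloc[0]),
            phase_duration=float(sub["phase_us"].iloc[0]),
            ipg=float(ipg),
            subject=str(subject),
            electrode=str(electrode),
        ))
    return out
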