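#!/usr/bin/env python
"""Amplitude-growth-function features for every simulated I/O function.

For each (scenario, electrode position, IPG) function written by
01_simulate_data.py: the 5-µV eCAP threshold (nC and dB re 1 nC), the
maximum amplitude (µV and dB re 1 µV), the dynamic range (CL), the
overall linear slope and the window-method maximum slope on the three
analysis scales, the sigmoid fit's goodness, and the log/log shape
classification.  Writes results/features.csv.

Finding to look for: maximum slope ≥ overall slope on every scale (the
window method isolates the steepest region), and the CND-like scenario
shows lower maximum amplitudes and shallower slopes than the others.
"""

from pathlib import Path

import pandas as pd

from ecap_ipg.dataio import read_io_functions
from ecap_ipg.io_features import (
    classify_shape,
    detect_threshold,
    dynamic_range,
    fit_sigmoid,
    max_amplitude,
    max_slope_window,
    overall_linear_slope,
)
from ecap_ipg.scales import ALL_SCALES, transform_io

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    functions = read_io_functions(ROOT / "data" / "io_functions.csv")
    rows = []
    for io in functions:
        th = detect_threshold(io)
        amp_uv, amp_db = max_amplitude(io)
        row = {
            "subject": io.subject,
            "electrode": io.electrode,
            "ipg_us": io.ipg,
            "threshold_nc": th.charge_nc,
            "threshold_db": th.charge_db,
            "max_amplitude_uv": amp_uv,
            "max_amplitude_db": amp_db,
            "dynamic_range_cl": dynamic_range(io, th),
            "shape": classify_shape(io).label,
        }
        for key, spec in ALL_SCALES.items():
            sio = transform_io(io, spec)
            row[f"overall_slope_{key}"] = (
                overall_linear_slope(sio, th.level_cl, io.c_level)
                if th.found else None
            )
            row[f"max_slope_{key}"] = max_slope_window(sio)
        row["sigmoid_adj_r2_S1"] = fit_sigmoid(transform_io(io, ALL_SCALES["S1"])).adj_r2
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "features.csv", index=False, float_format="%.6g")

    with pd.option_context("display.width", 160):
        cols = ["subject", "electrode", "ipg_us", "threshold_nc",
                "max_amplitude_uv", "overall_slope_S1", "max_slope_S1", "shape"]
        print(df[cols].to_string(index=False))

    for key in ALL_SCALES:
        ok = df.dropna(subset=[f"max_slope_{key}", f"overall_slope_{key}"])
        frac = (ok[f"max_slope_{key}"] >= ok[f"overall_slope_{key}"]).mean()
        print(f"max slope ≥ overall slope on {key}: {frac:.0%} of functions")
    grp = df.groupby(df.subject.str[:-2])["max_amplitude_uv"].mean()
    print("\nmean maximum amplitude by scenario (µV):")
    print(grp.to_string())


if __name__ == "__main__":
    main()
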