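#!/usr/bin/env python
"""Generate the synthetic datasets the downstream analyses consume.

Writes, under results/data/:
  * sweeps_jitter<sd>.csv/.json — 400-sweep eCAP recordings at several
    per-sweep latency-jitter levels (0, 5, 20, 50 µs) with the 5-µV noise
    floor of newer recording hardware;
  * io_functions.csv — paired IPG-7/IPG-42 amplitude-growth functions for
    the three scenario presets at basal/middle/apical electrode positions.
"""

from pathlib import Path

import ecap_ipg as eig
from ecap_ipg.dataio import write_io_functions, write_sweeps

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    jitters = (0.0, 5.0, 20.0, 50.0)
    for jit in jitters:
        cfg = eig.SweepSimConfig(latency_jitter_sd=jit, seed=SEED + int(jit))
        sweeps = eig.simulate_sweeps(cfg)
        write_sweeps(sweeps, OUT / f"sweeps_jitter{int(jit)}.csv")
    print(f"wrote {len(jitters)} sweep sets (400 × 128 samples) to {OUT}")

    functions = []
    for gi, scenario in enumerate(("CND", "NSCN", "GJB2")):
        for ei, pos in enumerate(("basal", "middle", "apical")):
            cfg = eig.scenario_config(
                scenario, pos, seed=SEED + 10 * gi + ei,
                subject=f"{scenario}01",
            )
            functions.extend(eig.simulate_io_pair(cfg))
    write_io_functions(functions, OUT / "io_functions.csv")
    print(f"wrote {len(functions)} I/O functions "
          f"(3 scenarios × 3 positions × 2 IPGs) to {OUT/'io_functions.csv'}")


if __name__ == "__main__":
    main()
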