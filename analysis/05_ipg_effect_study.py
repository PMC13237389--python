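#!/usr/bin/env python
"""Full demo study: IPG effects across groups, electrodes and scales.

Runs the end-to-end pipeline (simulate → PLV → features → offsets →
effects → nonparametric stats) for 10 subjects per scenario group × 3
electrode positions, and writes the tidy long-format tables —
effects.csv is ready for external mixed-model tooling — plus the
sensitivity report under results/study/.

Findings to look for in the report: the stimulation level offset
separates the CND-like group from the other two on every scale, with the
linear-scale offset also resolving the apical-ward gradient the CND
presets encode; the NSCN-like and GJB2-like groups are indistinguishable.
"""

from pathlib import Path

import ecap_ipg as eig

ROOT = Path(__file__).resolve().parents[1] / "results" / "study"
SEED = 2026


def main() -> None:
    table = eig.run_study(eig.StudyConfig(n_per_group=10, seed=SEED), out_dir=ROOT)
    print(table.summary)
    print()

    offsets = table.effects.query("parameter == 'level_offset'")
    print("mean level offset by scale and group:")
    print(offsets.groupby(["scale", "group"]).effect.mean()
          .unstack().to_string(float_format="%.3f"))
    print()
    cnd = offsets.query("group == 'CND' and scale == 'nC'")
    print("CND-like mean nC offset by electrode position:")
    print(cnd.groupby("electrode").effect.mean()
          .reindex(["basal", "middle", "apical"]).to_string(float_format="%.3f"))
    print(f"\ntables written to {ROOT}")


if __name__ == "__main__":
    main()
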