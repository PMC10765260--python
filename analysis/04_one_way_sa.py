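#!/usr/bin/env python
"""Step 4 — one-way sensitivity analysis (tornado).

Moves each model input to its range bounds with everything else at base
case and records the resulting ICER; bars are ranked by the largest swing
away from the base ICER.  Writes results/tornado.csv and a tornado plot.
"""

from pathlib import Path
import importlib.util

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from olaparib_cea import one_way_sa
from olaparib_cea.io import load_config

_spec = importlib.util.spec_from_file_location(
    "base_case_step", Path(__file__).with_name("02_base_case.py")
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = load_config()
    lt = cfg.resolve_life_table()
    pair = _mod.calibrated_pair(cfg, lt)
    entries = one_way_sa(pair, lt, cfg.sensitivity.ranges)

    df = pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "low_icer": round(e.icer_at_low),
                "high_icer": round(e.icer_at_high),
                "width": round(e.width),
            }
            for e in entries
        ]
    )
    print(df.to_string(index=False))
    top = [e.parameter for e in entries[:3]]
    print(f"\nThe ICER is most sensitive to: {', '.join(top)}.")

    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "tornado.csv", index=False)

    fig, ax = plt.subplots(figsize=(8, 5))
    base = entries[0].base_icer
    names = [e.parameter for e in entries][::-1]
    for i, e in enumerate(entries[::-1]):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, color="#777777")
    ax.axvline(base, color="black", lw=1, label=f"base ICER ${base:,.0f}/QALY")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("ICER, $ per QALY gained")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "tornado.png", dpi=150)
    print(f"\nwrote {OUT / 'tornado.csv'} and tornado.png")


if __name__ == "__main__":
    main()
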