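#!/usr/bin/env python
"""Step 5 — threshold analysis at $150,000 per QALY.

For the three most influential inputs, finds the value at which the ICER
crosses the willingness-to-pay threshold, holding everything else at base
case.  Writes results/thresholds.json.
"""

import json
from pathlib import Path
import importlib.util

from olaparib_cea import threshold_search
from olaparib_cea.io import load_config

_spec = importlib.util.spec_from_file_location(
    "base_case_step", Path(__file__).with_name("02_base_case.py")
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)

OUT = Path(__file__).resolve().parent.parent / "results"
WTP = 150_000.0


def main() -> None:
    cfg = load_config()
    lt = cfg.resolve_life_table()
    pair = _mod.calibrated_pair(cfg, lt)

    payload = {"wtp_per_qaly": WTP, "thresholds": {}}
    for param in ("hazard_ratio", "annual_discount_rate", "utility_no_recurrence"):
        bounds = cfg.sensitivity.ranges[param]
        value = threshold_search(param, WTP, tuple(bounds), pair, lt)
        payload["thresholds"][param] = value
        print(f"{param:<28} crosses ${WTP:,.0f}/QALY at {value:.4f}")

    OUT.mkdir(exist_ok=True)
    (OUT / "thresholds.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"\nwrote {OUT / 'thresholds.json'}")


if __name__ == "__main__":
    main()
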