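#!/usr/bin/env python
"""Step 1 — calibrate year-specific recurrence rates to the trial survival.

Fits each arm's year-1..4 monthly metastatic-recurrence rates (grid
increments of 0.0001/month) so the cohort model reproduces the printed
12/24/36/48-month DDFS, then reports the residual OS deviations, which are
not separately adjustable.  Writes results/calibration.json.
"""

import json
from pathlib import Path

from olaparib_cea import calibrate_arm
from olaparib_cea.io import load_config

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = load_config()
    lt = cfg.resolve_life_table()
    base = cfg.strategy_pair().no_olaparib

    payload = {}
    for arm in ("no_olaparib", "olaparib"):
        rep = calibrate_arm(cfg.targets(arm), base, lt)
        payload[arm] = rep.to_dict()
        rates = ", ".join(f"{r:.5f}" for r in rep.schedule.monthly_rates_years1to4)
        print(f"{arm}: monthly rates years 1-4 = {rates}")
        print(
            f"  DDFS matched to {rep.max_abs_ddfs_deviation * 100:.3f} pp; "
            "OS deviations (pp): "
            + ", ".join(f"m{m}: {d * 100:+.2f}" for m, d in rep.os_deviations.items())
        )

    print(
        "\nNote: with the 0.052/month metastatic death rate fixed, the printed"
        " DDFS and OS targets are not jointly attainable for the no-olaparib"
        " arm; DDFS is fitted exactly and the OS shortfall at months 36-48 is"
        " reported above."
    )
    OUT.mkdir(exist_ok=True)
    (OUT / "calibration.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"\nwrote {OUT / 'calibration.json'}")


if __name__ == "__main__":
    main()
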