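#!/usr/bin/env python
"""Step 2 — lifetime base case: discounted cost, life-years, QALYs, ICERs.

Runs both calibrated strategies from age 42 to cohort extinction and
tabulates the incremental comparison.  Writes results/base_case.json and
results/base_case.csv.
"""

import json
from pathlib import Path

import pandas as pd

from olaparib_cea import calibrate_arm, evaluate_pair, StrategyPair
from olaparib_cea.io import load_config

OUT = Path(__file__).resolve().parent.parent / "results"


def calibrated_pair(cfg, lt) -> StrategyPair:
    pair = cfg.strategy_pair()
    rep = {
        arm: calibrate_arm(cfg.targets(arm), pair.no_olaparib, lt)
        for arm in ("no_olaparib", "olaparib")
    }
    return StrategyPair(
        no_olaparib=pair.no_olaparib.with_(schedule=rep["no_olaparib"].schedule),
        olaparib=pair.olaparib.with_(schedule=rep["olaparib"].schedule),
    )


def main() -> None:
    cfg = load_config()
    lt = cfg.resolve_life_table()
    res = evaluate_pair(calibrated_pair(cfg, lt), lt)

    rows = [
        {
            "strategy": t.label,
            "cost": round(t.cost),
            "life_years": round(t.life_years, 2),
            "qalys": round(t.qalys, 2),
        }
        for t in (res.intervention, res.comparator)
    ]
    df = pd.DataFrame(rows)
    print(df.to_string(index=False))
    print(
        f"\nincremental: ${res.incremental_cost:,.0f}, "
        f"{res.incremental_life_years:.2f} life-years, "
        f"{res.incremental_qalys:.2f} QALYs"
    )
    print(
        f"ICER: ${res.icer_per_life_year:,.0f}/life-year, "
        f"${res.icer_per_qaly:,.0f}/QALY"
    )

    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "base_case.csv", index=False)
    (OUT / "base_case.json").write_text(json.dumps(res.to_dict(), indent=2) + "\n")
    print(f"\nwrote {OUT / 'base_case.csv'} and base_case.json")


if __name__ == "__main__":
    main()
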