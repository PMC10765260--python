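#!/usr/bin/env python
"""Step 6 — probabilistic sensitivity analysis (10,000 draws).

Samples all stochastic inputs from their fitted distributions, re-runs both
arms per draw, and summarises the cloud of incremental outcomes as a
CE-plane scatter (with 95% confidence ellipse) and a cost-effectiveness
acceptability curve.  Writes results/psa_draws.csv, results/ceac.csv,
results/psa_summary.json and two figures.
"""

import argparse
import json
import math
import time
from pathlib import Path
import importlib.util

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from olaparib_cea import run_psa
from olaparib_cea.io import load_config

_spec = importlib.util.spec_from_file_location(
    "base_case_step", Path(__file__).with_name("02_base_case.py")
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--n", type=int, default=None)
    parser.add_argument("--seed", type=int, default=None)
    args = parser.parse_args()

    cfg = load_config()
    n = cfg.sensitivity.n_psa if args.n is None else args.n
    seed = cfg.sensitivity.seed if args.seed is None else args.seed
    lt = cfg.resolve_life_table()
    pair = _mod.calibrated_pair(cfg, lt)

    t0 = time.time()
    psa = run_psa(pair, lt, n=n, seed=seed)
    print(f"{n} draws in {time.time() - t0:.1f}s (seed {seed})")

    quad = psa.quadrant_fractions()
    prop150 = psa.acceptability_at(150_000.0)
    cross50 = psa.ceac_crossing(0.5)
    cross80 = psa.ceac_crossing(0.8)
    print(
        f"more costly & more effective in {quad['more_costly_more_effective']:.1%}"
        " of draws"
    )
    print(f"cost-effective at $150k/QALY in {prop150:.1%} of draws")
    print(
        "CEAC crosses 50% at "
        + (f"${cross50:,.0f}" if cross50 else "n/a")
        + " and 80% at "
        + (f"${cross80:,.0f}" if cross80 else "n/a")
    )

    OUT.mkdir(exist_ok=True)
    psa.draws.to_csv(OUT / "psa_draws.csv", index=False)
    psa.ceac_frame().to_csv(OUT / "ceac.csv", index=False)
    summary = {
        "seed": seed,
        "n_draws": n,
        "quadrants": quad,
        "prop_olaparib_at_150k": prop150,
        "ceac_crossing_0.5": cross50,
        "ceac_crossing_0.8": cross80,
    }
    (OUT / "psa_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    # CE plane with confidence ellipse
    fig, ax = plt.subplots(figsize=(7, 6))
    ax.scatter(psa.draws["d_qaly"], psa.draws["d_cost"], s=3, alpha=0.2,
               color="#336699")
    ell = psa.confidence_ellipse()
    theta = np.linspace(0, 2 * math.pi, 200)
    a, b = ell["semi_axes"]
    ang = math.radians(ell["angle_deg"])
    x = ell["mean"][0] + a * np.cos(theta) * math.cos(ang) - b * np.sin(theta) * math.sin(ang)
    y = ell["mean"][1] + a * np.cos(theta) * math.sin(ang) + b * np.sin(theta) * math.cos(ang)
    ax.plot(x, y, color="black", lw=1)
    grid = np.linspace(0, psa.draws["d_qaly"].max() * 1.05, 50)
    ax.plot(grid, 150_000 * grid, ls="--", color="grey",
            label="WTP $150,000/QALY")
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost, $")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "ce_plane.png", dpi=150)

    # CEAC
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(psa.wtp_grid / 1000, psa.prop_olaparib, label="adjuvant olaparib")
    ax.plot(psa.wtp_grid / 1000, psa.prop_no_olaparib, label="no olaparib")
    ax.set_xlabel("willingness to pay, $1000 per QALY")
    ax.set_ylabel("proportion of draws preferred")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "ceac.png", dpi=150)
    print(f"\nwrote PSA artifacts under {OUT}")


if __name__ == "__main__":
    main()
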