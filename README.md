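# olaparib-cea

A Markov cohort cost-effectiveness model of **adjuvant olaparib versus no
olaparib** for patients with germline *BRCA1/2*-mutated, high-risk,
*ERBB2*-negative early breast cancer, written for health-economics and
outcomes researchers who want the published decision model as tested,
configurable, scriptable code rather than a proprietary model file.

## The model

Four health states — no recurrence (`NR`), metastatic recurrence (`M`),
death from breast cancer (`D_bc`), death from other causes (`D_o`) — with
1-month cycles. The whole cohort enters `NR` at age 42 (scenarios: 50, 60)
after definitive local therapy and (neo)adjuvant chemotherapy.

* **Transitions.** During model year *y*, `NR` occupants face a constant
  monthly recurrence rate *r_y* competing with age-specific background
  mortality *h(a)* from a life table; cause-specific cycle probabilities
  use the piecewise-exponential split
  `p_k = r_k/Σr · (1 − e^(−Σr))`. `M` occupants face a constant
  breast-cancer death rate `d = ln 2 / 13.3 = 0.052` per month (13.3-month
  median survival in metastatic triple-negative disease) competing with
  the same background mortality. Breast-cancer death is only reachable
  from `M`.
* **Calibration.** The year-1..4 monthly rates *r_1..r_4* are fitted — in
  0.0001 increments, or by bisection — so the model's distant
  disease-free survival (DDFS, the `NR` occupancy) reproduces the trial's
  printed 12/24/36/48-month DDFS per arm. Overall survival is a reported
  validation output, not a fitted one. Beyond month 48 both arms share
  fixed annual recurrence probabilities (0.0156 in years 5–9, 0.0078 from
  year 10), i.e. no treatment effect after 4 years.
* **Rewards.** Discounted (3%/year) costs, life-years and QALYs accrue on
  state occupancy: olaparib drug cost for treatment months 1–12 while in
  `NR`; arm-specific oncologist-visit and annual-imaging schedules; an
  all-inclusive monthly metastatic care cost; utilities 0.98 (`NR`), 0.55
  (`M`), with a 0.90 multiplier on `NR` utility during olaparib
  treatment.
* **Decision outputs.** ICER = ΔC/ΔE between the two strategies; one-way
  sensitivity (tornado) and $150,000/QALY threshold analysis; 10,000-draw
  probabilistic sensitivity analysis (gamma costs, beta utilities and
  metastatic death rate, lognormal hazard ratio) summarised as a CE plane
  and a cost-effectiveness acceptability curve.

The trial effect size is the stratified hazard ratio for distant disease
or death, HR 0.61 (95% CI 0.48–0.77), applied multiplicatively to the
placebo recurrence rates in sensitivity analyses.

Background mortality ships as a **synthetic** reconstruction of the 2018
US female life table (monotone log-hazard interpolation through published
anchor values — see the CSV header); the `synthetic` module can also
generate Gompertz–Makeham tables with known parameters for testing.

## Worked example

```python
from olaparib_cea import calibrate_arm, evaluate_pair, StrategyPair
from olaparib_cea.io import load_config

cfg = load_config()                      # bundled base case (Table-1 inputs)
lt = cfg.resolve_life_table()
pair = cfg.strategy_pair()
sched = {arm: calibrate_arm(cfg.targets(arm), pair.no_olaparib, lt).schedule
         for arm in ("no_olaparib", "olaparib")}
pair = StrategyPair(
    no_olaparib=pair.no_olaparib.with_(schedule=sched["no_olaparib"]),
    olaparib=pair.olaparib.with_(schedule=sched["olaparib"]),
)
res = evaluate_pair(pair, lt)
print(f"{res.incremental_qalys:.2f} QALYs for ${res.incremental_cost:,.0f} "
      f"-> ${res.icer_per_qaly:,.0f}/QALY")
```

prints

```
1.23 QALYs for $151,324 -> $123,067/QALY
```

i.e. adjuvant olaparib buys 1.23 discounted quality-adjusted life-years at
an incremental lifetime cost of $151k, an ICER of about $123,000 per QALY —
cost-effective at a willingness-to-pay of $150,000/QALY. The published
model reports a somewhat lower ICER (≈$111,000/QALY); the deviation and
its source (the comparator arm's metastatic-care costs, see
`docs/methods.md`) are quantified by the analysis scripts.

The full analysis is scripted:

```bash
python analysis/01_calibrate.py      # fit recurrence rates to trial survival
python analysis/02_base_case.py      # lifetime cost/LY/QALY per strategy, ICER
python analysis/03_age_scenarios.py  # starting ages 42 / 50 / 60
python analysis/04_one_way_sa.py     # tornado diagram
python analysis/05_thresholds.py     # $150k/QALY threshold values
python analysis/06_psa.py            # 10,000-draw PSA, CE plane, CEAC
```

Each step prints what it found and writes tables under `results/`. The
same operations are available as a CLI (`olaparib-cea run`, `owsa`,
`threshold`, `psa`, ...), configured by a single validated YAML file
(`src/olaparib_cea/data/base_case.yaml`).

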