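# Methods

## Model structure and assumptions

The model is a deterministic Markov cohort simulation with four states —
no recurrence, metastatic recurrence, death from breast cancer, death from
other causes — and 1-month cycles, run from the starting age until age 110
(by which point the alive fraction is negligible). Local/regional
recurrences, second primaries, adverse events and treatment
discontinuation are intentionally outside the model, matching its source
scope. Breast-cancer death is reachable only from the metastatic state.

Within-cycle competing risks use the piecewise-constant-hazard
("exponential") apportionment: with cause rates `r_k` and total `R = Σ r_k`,
the per-cycle probability of any exit is `1 − e^(−R)` and cause `k`
receives the share `r_k / R`. This treatment is order-independent, which a
sequential application of per-cause probabilities would not be.

Age advances continuously (`starting_age + month/12`); background
mortality is looked up by completed years of age and converted to a
constant monthly rate within each year of age, `h = −ln(1 − q)/12`.

State occupancy under piecewise-constant monthly hazards has a closed-form
recursion (cumulative products of stay probabilities, cumulative sums of
inflows), so the engine is fully vectorised; a lifetime run costs a few
hundred microseconds, which is what makes the 10,000-draw PSA (two runs
per draw) take seconds rather than hours. The vectorised path is
cross-checked in the test suite against a naive month-by-month matrix
iteration written independently.

## Calibration

Distant disease-free survival in this model equals the no-recurrence
occupancy (its decrements are exactly distant recurrence and death). DDFS
at month `12k` depends only on the rates of years `≤ k`, so the four
year-specific monthly recurrence rates are fitted sequentially, each
holding the earlier ones fixed. Two modes:

* **grid** (default): walk the rate in fixed 0.0001/month increments from
  the closed-form start `−ln(S_k/S_{k−1})/12` until the model DDFS
  brackets the target, keep the closer grid point. One grid step moves
  12-month survival by about 0.12 percentage points, so the fit resolves
  DDFS to ~0.05 pp.
* **bisect**: Brent root-finding to floating-point tolerance; used by the
  property tests (parameter recovery to 1e-8) because it has no grid
  artifacts.

Overall survival is *not* separately fittable: once DDFS pins the
recurrence inflow, OS is determined by the fixed metastatic death rate and
the life table. The calibration report therefore carries OS deviations as
a validation output. This is a real constraint, not an implementation
shortcut: with the 0.052/month metastatic death rate, the maximum
attainable no-olaparib metastatic occupancy at month 48 is about 5 pp,
while the printed OS−DDFS gap is 7.3 pp — the published DDFS targets, OS
targets and metastatic survival input are mutually inconsistent under this
state structure. Fitting DDFS exactly, the no-olaparib arm's model OS runs
+0.6/−0.3/−1.4/−2.4 pp against its targets at months 12/24/36/48 (the
olaparib arm stays within ±0.6 pp throughout); `analysis/01_calibrate.py`
prints these numbers.

The base-case olaparib arm uses its *own* DDFS-calibrated rates. Analyses
that vary the hazard ratio (tornado, thresholds, PSA) instead rebuild the
treated arm as placebo rates × HR for years 1–4, so the treatment effect
stays a live parameter; at HR 0.61 the two constructions differ by
< 0.3 pp in DDFS.

## Parameters

| input | base (range) | units | note |
|---|---|---|---|
| starting age | 42 (50, 60 scenarios) | years | trial median age |
| monthly olaparib cost | 14,523 (10,892–18,154) | 2021 USD | 300 mg b.i.d. |
| oncologist visit | 867 (650–1,084) | USD/visit | |
| mammogram + breast MRI | 540 (405–675) | USD/year | × 53.5% of cohort |
| metastatic care | 23,599 (17,699–29,499) | USD/month | all-inclusive |
| utility, no recurrence | 0.98 (0.735–1) | — | |
| utility, metastatic | 0.55 (0.413–0.688) | — | |
| olaparib utility multiplier | 0.90 (0.80–1) | — | months 1–12 only |
| HR, distant disease or death | 0.61 (0.48–0.77) | — | years 1–4 only |
| metastatic death rate | 0.052 (0.039–0.065) | month⁻¹ | ln 2 / 13.3-month median |
| recurrence, years 5–9 | 0.0156 | year⁻¹ prob. | both arms, fixed |
| recurrence, years ≥10 | 0.0078 | year⁻¹ prob. | both arms, fixed |
| discount rate | 0.03 (0–0.06 in OWSA) | year⁻¹ | costs and outcomes |

Cost schedule: olaparib — drug cost in months 1–12 paid by the
no-recurrence occupancy (treatment stops at recurrence or 12 months,
whichever first); monthly oncologist visits during treatment, 6-monthly
through month 72 (five years after completing systemic therapy), annual
thereafter. No olaparib — 6-monthly visits through month 60, annual
thereafter. Both arms: annual surveillance imaging for the 53.5% of the
cohort with at least one breast, while recurrence-free; metastatic monthly
cost on the metastatic occupancy, assumed to include all routine care; no
terminal-care cost. Month-m accruals are discounted by
`1.03^(−m/12)`; no half-cycle correction (with monthly cycles the
correction is well under 1% of lifetime totals). Visit schedules during
year 1 of the olaparib arm are read as monthly visits *replacing* the
6-monthly pattern.

## Sensitivity analyses

One-way analysis re-runs both arms with a single input at its low/high
bound. Tornado bars are **ranked by the largest one-sided swing of the
ICER away from its base value**, not by the low-to-high span: the ICER
responds hyperbolically to the no-recurrence utility (which scales the
QALY denominator), so a symmetric span understates inputs whose influence
is strongly one-sided.

Threshold analysis inverts the ICER with Brent bisection until the ICER is
within $1 of the willingness-to-pay level (or the parameter interval
collapses below 1e-6).

PSA distributions are moment-matched to mean = base case with
SE = (base − lower bound)/1.96: gamma for costs, beta for utilities and
the metastatic death rate, a beta rescaled to [0.80, 1] for the utility
multiplier (draws are additionally capped at 1 so treated utility never
exceeds untreated), and a lognormal for the hazard ratio with
μ = ln 0.61, σ = (ln 0.77 − ln 0.48)/(2·1.96) ≈ 0.1206. Draws are
independent across parameters (no correlation structure is published).
The post-trial recurrence probabilities, the life table and the discount
rate are fixed in the PSA. Preference uses the sign of net monetary
benefit `WTP·ΔQALY − ΔC`, ties counted for the comparator; the CEAC grid
is $0–300,000 in $5,000 steps. The lower-bound SE rule makes the
no-recurrence-utility beta extremely skewed (α ≈ 0.25, β ≈ 0.005), which
occasionally produces very low utility draws in which the intervention
loses QALYs; about 1% of draws therefore fall outside the
more-costly/more-effective quadrant.

## Synthetic inputs

The bundled background-mortality table is a **synthetic reconstruction**
of the 2018 US female all-cause life table: monotone PCHIP interpolation
of log annual hazard through published anchor values at ages 30–100,
log-linear hazard extrapolation to 110, hand-set knots below age 30 (which
the model, starting at ≥ 42, never touches). Its life expectancy at 42 is
40.2 years. It reproduces the *shape* of US female mortality but not the
exact published single-year values; female all-cause mortality is used
unadjusted as "non-breast-cancer" mortality, since breast-cancer deaths
are a small share of female all-cause mortality at these ages.

For property tests, Gompertz–Makeham tables (`h(x) = a·e^{bx} + c`) with
known parameters are generated on the fly, and trial-style calibration
targets are produced by running the engine with a known schedule — so
calibration is tested as exact parameter recovery, with no external data.
What passing those tests shows is that the machinery is self-consistent;
they cannot certify the unpublished implementation details of the original
model (see below) or the realism of the fixed extrapolation inputs.

## Reproduction fidelity and limitations

With the bundled life table the model reproduces the published per-arm
life-years and QALYs to better than 1% and the olaparib arm's lifetime
cost to 0.05%. The no-olaparib arm's cost comes out ≈10% lower than
published, which propagates to the incremental cost (+14%) and ICER
(≈+11%, $123k vs $111k per QALY). The discrepancy is not resolvable from
the published description: the printed comparator cost exceeds what the
printed comparator LY/QALYs imply under the documented utilities and cost
schedule (the utility identity implies ≈0.36 discounted metastatic years,
the cost identity ≈0.57), so some reward-accrual detail of the original
TreeAge implementation is not recoverable from its description. We
verified that the obvious candidates — OS-driven calibration, a lower
effective metastatic death rate, altered post-trial recurrence,
alternative discount conventions — each move other reproduced quantities
*away* from their published values, and kept the documented structure.
Qualitative results are unaffected: olaparib buys ≈1.2–1.3 QALYs at an
ICER below a $150,000/QALY threshold, the tornado's top three inputs
(hazard ratio, discount rate, no-recurrence utility) match, and the CEAC's
50% crossing sits at the base-case ICER.

Other limitations: no microsimulation-level heterogeneity; no tunnel
states (metastatic utility and cost are time-invariant within the state);
the treatment effect is assumed absent after month 48, so any longer-term
benefit would make the intervention look better than modelled here.
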