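"""Incremental cost-effectiveness, one-way/threshold sensitivity, and PSA.

The decision problem compares two strategies — adjuvant olaparib versus no
olaparib — on discounted lifetime cost, life-years and QALYs.  One-way
sensitivity re-runs both arms with a single input moved to its range
bounds; threshold search inverts the ICER for the input value that hits a
willingness-to-pay level; probabilistic sensitivity analysis propagates
second-order parameter distributions (gamma for costs, beta for utilities
and the metastatic death rate, lognormal for the hazard ratio) through the
model by Monte Carlo and summarises the draws as a cost-effectiveness
acceptability curve (CEAC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .engine import CohortTrace, run_cohort
from .lifetable import LifeTable
from .params import ModelParams

__all__ = [
    "StrategyTotals",
    "StrategyPair",
    "CEResult",
    "TornadoEntry",
    "DistributionSpec",
    "PSAResult",
    "NoCrossingError",
    "compare_strategies",
    "evaluate_pair",
    "one_way_sa",
    "threshold_search",
    "fit_distribution",
    "run_psa",
    "DEFAULT_OWSA_RANGES",
    "DEFAULT_PSA_FAMILIES",
    "default_wtp_grid",
]

# Table-style one-way ranges: published bounds where they exist, otherwise
# +/-25% of the base-case value; the discount rate spans the conventional
# 0-6% band used in US health-economic guidance.
DEFAULT_OWSA_RANGES: dict[str, tuple[float, float]] = {
    "hazard_ratio": (0.48, 0.77),
    "annual_discount_rate": (0.0, 0.06),
    "utility_no_recurrence": (0.735, 1.0),
    "utility_metastatic": (0.413, 0.688),
    "olaparib_utility_multiplier": (0.80, 1.0),
    "monthly_drug_cost": (10_892.0, 18_154.0),
    "oncologist_visit_cost": (650.0, 1_084.0),
    "imaging_cost": (405.0, 675.0),
    "monthly_metastatic_cost": (17_699.0, 29_499.0),
    "monthly_metastatic_death_rate": (0.039, 0.065),
}

DEFAULT_PSA_FAMILIES: dict[str, str] = {
    "utility_no_recurrence": "beta",
    "utility_metastatic": "beta",
    "olaparib_utility_multiplier": "scaled-beta",
    "monthly_drug_cost": "gamma",
    "oncologist_visit_cost": "gamma",
    "imaging_cost": "gamma",
    "monthly_metastatic_cost": "gamma",
    "monthly_metastatic_death_rate": "beta",
    "hazard_ratio": "lognormal",
}


def default_wtp_grid() -> np.ndarray:
    """Willingness-to-pay grid $0-300,000/QALY in $5,000 steps."""
    return np.arange(0, 300_001, 5_000, dtype=float)


@dataclass(frozen=True)
class StrategyTotals:
    label: str
    cost: float
    life_years: float
    qalys: float

    @classmethod
    def from_trace(cls, trace: CohortTrace) -> "StrategyTotals":
        return cls(
            label=trace.params.label,
            cost=trace.total_cost,
            life_years=trace.total_life_years,
            qalys=trace.total_qalys,
        )


@dataclass(frozen=True)
class StrategyPair:
    """The two strategies of the decision problem, sharing every input that
    is not treatment-specific."""

    no_olaparib: ModelParams
    olaparib: ModelParams

    def with_param(self, name: str, value: float) -> "StrategyPair":
        """Move one named input to ``value`` in both arms.

        ``hazard_ratio`` is special: it rebuilds the olaparib arm's
        trial-window recurrence rates from the placebo schedule, keeping
        the treatment effect a live parameter.
        """
        if name == "hazard_ratio":
            sched = self.no_olaparib.schedule.with_hazard_ratio(value)
            return StrategyPair(
                no_olaparib=self.no_olaparib,
                olaparib=self.olaparib.with_(schedule=sched),
            )
        if not hasattr(self.no_olaparib, name):
            raise KeyError(f"unknown model parameter {name!r}")
        return StrategyPair(
            no_olaparib=self.no_olaparib.with_(**{name: value}),
            olaparib=self.olaparib.with_(**{name: value}),
        )

    def base_value(self, name: str) -> float:
        if name == "hazard_ratio":
            return self.olaparib.hazard_ratio.point
        return getattr(self.no_olaparib, name)


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of the olaparib strategy against no olaparib."""

    intervention: StrategyTotals
    comparator: StrategyTotals
    incremental_cost: float
    incremental_life_years: float
    incremental_qalys: float
    icer_per_life_year: float | None
    icer_per_qaly: float | None
    dominance: str  # "", "intervention_dominant", "intervention_dominated"

    def to_dict(self) -> dict:
        return {
            "strategies": {
                t.label: {"cost": t.cost, "life_years": t.life_years, "qalys": t.qalys}
                for t in (self.intervention, self.comparator)
            },
            "incremental_cost": self.incremental_cost,
            "incremental_life_years": self.incremental_life_years,
            "incremental_qalys": self.incremental_qalys,
            "icer_per_life_year": self.icer_per_life_year,
            "icer_per_qaly": self.icer_per_qaly,
            "dominance": self.dominance,
        }


def compare_strategies(a: StrategyTotals, b: StrategyTotals) -> CEResult:
    """Incremental cost-effectiveness of strategy ``a`` over comparator ``b``.

    ICERs are reported only when the effect difference is positive; a
    cheaper-and-better or costlier-and-worse configuration is flagged as
    dominance instead of dividing.
    """
    d_cost = a.cost - b.cost
    d_ly = a.life_years - b.life_years
    d_qaly = a.qalys - b.qalys
    dominance = ""
    if d_cost <= 0 and d_qaly >= 0 and (d_cost < 0 or d_qaly > 0):
        dominance = "intervention_dominant"
    elif d_cost >= 0 and d_qaly <= 0 and (d_cost > 0 or d_qaly < 0):
        dominance = "intervention_dominated"
    icer_ly = d_cost / d_ly if d_ly > 0 else None
    icer_qaly = d_cost / d_qaly if d_qaly > 0 else None
    return CEResult(
        intervention=a,
        comparator=b,
        incremental_cost=d_cost,
        incremental_life_years=d_ly,
        incremental_qalys=d_qaly,
        icer_per_life_year=icer_ly,
        icer_per_qaly=icer_qaly,
        dominance=dominance,
    )


def evaluate_pair(pair: StrategyPair, lt: LifeTable) -> CEResult:
    """Run both arms and compare them."""
    t_no = StrategyTotals.from_trace(run_cohort(pair.no_olaparib, lt))
    t_ol = StrategyTotals.from_trace(run_cohort(pair.olaparib, lt))
    return compare_strategies(t_ol, t_no)


def _icer(pair: StrategyPair, lt: LifeTable) -> float:
    res = evaluate_pair(pair, lt)
    if res.icer_per_qaly is None:
        return math.inf if res.incremental_cost > 0 else -math.inf
    return res.icer_per_qaly


# --------------------------------------------------------------------------
# one-way sensitivity analysis


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float
    base_icer: float

    @property
    def width(self) -> float:
        """Bar size used for ranking: largest swing away from the base ICER.

        The ICER responds hyperbolically to utility inputs, so the maximum
        one-sided deviation ranks influence more faithfully than the plain
        low-to-high span.
        """
        return max(
            abs(self.icer_at_low - self.base_icer),
            abs(self.icer_at_high - self.base_icer),
        )


def one_way_sa(
    pair: StrategyPair,
    lt: LifeTable,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> list[TornadoEntry]:
    """ICER at each input's low and high bound, everything else at base.

    Returns entries sorted by bar width, widest first.
    """
    ranges = DEFAULT_OWSA_RANGES if ranges is None else ranges
    base_icer = _icer(pair, lt)
    entries = []
    for name, (low, high) in ranges.items():
        if low > high:
            raise ValueError(f"range for {name} has low > high: ({low}, {high})")
        entries.append(
            TornadoEntry(
                parameter=name,
                low_value=low,
                high_value=high,
                icer_at_low=_icer(pair.with_param(name, low), lt),
                icer_at_high=_icer(pair.with_param(name, high), lt),
                base_icer=base_icer,
            )
        )
    return sorted(entries, key=lambda e: e.width, reverse=True)


class NoCrossingError(RuntimeError):
    """The ICER does not cross the requested WTP inside the given bounds."""


def threshold_search(
    param: str,
    wtp: float,
    bounds: tuple[float, float],
    pair: StrategyPair,
    lt: LifeTable,
    *,
    icer_tol: float = 1.0,
    x_tol: float = 1e-6,
) -> float:
    """Input value at which the ICER equals the willingness-to-pay level.

    Bisection (Brent) on the ICER-minus-WTP residual; converges to within
    ``icer_tol`` dollars of the WTP or ``x_tol`` on the parameter.
    """

    def f(x: float) -> float:
        return _icer(pair.with_param(param, x), lt) - wtp

    lo, hi = bounds
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        raise NoCrossingError(
            f"ICER stays on one side of WTP {wtp:,.0f} over {param} in "
            f"[{lo}, {hi}] (residuals {f_lo:,.0f} and {f_hi:,.0f})"
        )
    x = brentq(f, lo, hi, xtol=x_tol, rtol=4 * np.finfo(float).eps)
    # tighten until the ICER itself is within icer_tol, if the parameter
    # resolution allows it
    if abs(f(x)) > icer_tol:
        x = brentq(f, lo, hi, xtol=1e-12, rtol=4 * np.finfo(float).eps)
    return float(x)


# --------------------------------------------------------------------------
# distributions and probabilistic sensitivity analysis


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted second-order distribution for one model input.

    Moment-matched so the distribution mean equals the base-case value,
    with the standard error taken from the lower range bound,
    ``SE = (base - low) / 1.96``; the hazard ratio instead uses a lognormal
    with ``sigma`` recovered from its 95% CI.
    """

    name: str
    family: str
    base: float
    low: float
    high: float
    params: dict = field(default_factory=dict)

    def mean(self) -> float:
        if self.family == "point":
            return self.base
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        if self.family == "beta":
            a, b = self.params["a"], self.params["b"]
            return a / (a + b)
        if self.family == "scaled-beta":
            a, b = self.params["a"], self.params["b"]
            return self.low + (self.high - self.low) * a / (a + b)
        if self.family == "lognormal":
            # median-parameterised: mu = ln(base); the mean carries the
            # usual exp(sigma^2/2) factor
            return math.exp(self.params["mu"] + self.params["sigma"] ** 2 / 2)
        raise ValueError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point":
            return np.full(size, self.base)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size)
        if self.family == "beta":
            return rng.beta(self.params["a"], self.params["b"], size)
        if self.family == "scaled-beta":
            raw = rng.beta(self.params["a"], self.params["b"], size)
            return self.low + (self.high - self.low) * raw
        if self.family == "lognormal":
            return rng.lognormal(self.params["mu"], self.params["sigma"], size)
        raise ValueError(f"unknown family {self.family!r}")


def fit_distribution(
    base: float, low: float, high: float, family: str, name: str = ""
) -> DistributionSpec:
    """Fit a PSA distribution to a base-case value and its range."""
    if not low <= base <= high:
        raise ValueError(f"need low <= base <= high, got ({low}, {base}, {high})")
    if low == high:
        return DistributionSpec(name, "point", base, low, high)
    se = (base - low) / 1.96
    if family == "gamma":
        if se == 0:
            return DistributionSpec(name, "point", base, low, high)
        shape = (base / se) ** 2
        scale = se**2 / base
        params = {"shape": shape, "scale": scale}
    elif family == "beta":
        var = se**2
        if var >= base * (1 - base):
            raise ValueError(
                f"beta infeasible for mean {base}, SE {se:.4g}: variance "
                f"exceeds mean*(1-mean)"
            )
        nu = base * (1 - base) / var - 1
        params = {"a": base * nu, "b": (1 - base) * nu}
    elif family == "scaled-beta":
        m = (base - low) / (high - low)
        s = se / (high - low)
        var = s**2
        if var >= m * (1 - m):
            raise ValueError(f"scaled beta infeasible for {name}")
        nu = m * (1 - m) / var - 1
        params = {"a": m * nu, "b": (1 - m) * nu}
    elif family == "lognormal":
        if low <= 0:
            raise ValueError("lognormal needs positive bounds")
        params = {
            "mu": math.log(base),
            "sigma": (math.log(high) - math.log(low)) / (2 * 1.96),
        }
    else:
        raise ValueError(f"unknown family {family!r}")
    return DistributionSpec(name, family, base, low, high, params)


def default_psa_specs(
    pair: StrategyPair,
    ranges: dict[str, tuple[float, float]] | None = None,
    families: dict[str, str] | None = None,
) -> dict[str, DistributionSpec]:
    """Fitted distributions for every stochastic PSA input.

    The post-trial recurrence probabilities and the background life table
    are fixed inputs and are not varied; the discount rate is a policy
    choice and is likewise excluded from the PSA.
    """
    ranges = DEFAULT_OWSA_RANGES if ranges is None else ranges
    families = DEFAULT_PSA_FAMILIES if families is None else families
    specs = {}
    for name, family in families.items():
        low, high = ranges[name]
        specs[name] = fit_distribution(
            pair.base_value(name), low, high, family, name=name
        )
    return specs


@dataclass
class PSAResult:
    """Second-order Monte Carlo output: per-draw incrementals and the CEAC."""

    seed: int
    n_draws: int
    draws: pd.DataFrame  # columns: draw, d_cost, d_qaly, d_ly
    wtp_grid: np.ndarray
    prop_olaparib: np.ndarray  # P(NMB > 0) at each WTP
    specs: dict[str, DistributionSpec]

    @property
    def prop_no_olaparib(self) -> np.ndarray:
        return 1.0 - self.prop_olaparib

    def quadrant_fractions(self) -> dict[str, float]:
        dc = self.draws["d_cost"].to_numpy()
        dq = self.draws["d_qaly"].to_numpy()
        return {
            "more_costly_more_effective": float(np.mean((dc > 0) & (dq > 0))),
            "more_costly_less_effective": float(np.mean((dc > 0) & (dq <= 0))),
            "less_costly_more_effective": float(np.mean((dc <= 0) & (dq > 0))),
            "less_costly_less_effective": float(np.mean((dc <= 0) & (dq <= 0))),
        }

    def acceptability_at(self, wtp: float) -> float:
        dc = self.draws["d_cost"].to_numpy()
        dq = self.draws["d_qaly"].to_numpy()
        return float(np.mean(wtp * dq - dc > 0))

    def ceac_crossing(self, level: float) -> float | None:
        """WTP at which the CEAC first reaches ``level`` (linear interpolation)."""
        p = self.prop_olaparib
        above = np.nonzero(p >= level)[0]
        if above.size == 0:
            return None
        i = int(above[0])
        if i == 0:
            return float(self.wtp_grid[0])
        w0, w1 = self.wtp_grid[i - 1], self.wtp_grid[i]
        p0, p1 = p[i - 1], p[i]
        if p1 == p0:
            return float(w1)
        return float(w0 + (level - p0) / (p1 - p0) * (w1 - w0))

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wtp": self.wtp_grid,
                "prop_olaparib": self.prop_olaparib,
                "prop_no_olaparib": self.prop_no_olaparib,
            }
        )

    def confidence_ellipse(self, level: float = 0.95) -> dict:
        """Mean and covariance-ellipse geometry of the (dQALY, dCost) cloud."""
        pts = self.draws[["d_qaly", "d_cost"]].to_numpy()
        mean = pts.mean(axis=0)
        cov = np.cov(pts.T)
        vals, vecs = np.linalg.eigh(cov)
        k = math.sqrt(stats.chi2.ppf(level, df=2))
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        return {
            "mean": mean.tolist(),
            "semi_axes": (k * np.sqrt(vals)).tolist(),
            "angle_deg": math.degrees(math.atan2(vecs[1, 0], vecs[0, 0])),
        }


def run_psa(
    pair: StrategyPair,
    lt: LifeTable,
    *,
    n: int = 10_000,
    seed: int = 20_240_103,
    specs: dict[str, DistributionSpec] | None = None,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Second-order Monte Carlo over all stochastic model inputs.

    Each draw samples every input independently from its fitted
    distribution, rebuilds the olaparib arm's trial-window recurrence rates
    from the placebo schedule and the drawn hazard ratio, runs both arms,
    and records the incremental cost and effect.  The CEAC reports, at each
    willingness-to-pay level, the fraction of draws whose net monetary
    benefit ``wtp * dQALY - dCost`` is positive (ties prefer the
    comparator).
    """
    if n < 1:
        raise ValueError(f"need n >= 1 draws, got {n}")
    specs = default_psa_specs(pair) if specs is None else specs
    wtp = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    for name, spec in specs.items():
        if name != "hazard_ratio" and not hasattr(pair.no_olaparib, name):
            raise KeyError(f"spec for unknown parameter {name!r}")
        if spec.family not in ("point", "gamma", "beta", "scaled-beta", "lognormal"):
            raise ValueError(f"invalid family for {name}: {spec.family!r}")

    rng = np.random.default_rng(seed)
    names = list(specs)
    samples = {name: specs[name].sample(rng, n) for name in names}
    # treated utility must never exceed untreated: cap the multiplier at 1
    if "olaparib_utility_multiplier" in samples:
        np.clip(samples["olaparib_utility_multiplier"], None, 1.0,
                out=samples["olaparib_utility_multiplier"])

    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    d_ly = np.empty(n)
    for i in range(n):
        draw_pair = pair
        shared = {
            name: samples[name][i] for name in names if name != "hazard_ratio"
        }
        draw_pair = StrategyPair(
            no_olaparib=pair.no_olaparib.with_(**shared),
            olaparib=pair.olaparib.with_(**shared),
        )
        if "hazard_ratio" in samples:
            draw_pair = draw_pair.with_param(
                "hazard_ratio", samples["hazard_ratio"][i]
            )
        tr_no = run_cohort(draw_pair.no_olaparib, lt)
        tr_ol = run_cohort(draw_pair.olaparib, lt)
        d_cost[i] = tr_ol.total_cost - tr_no.total_cost
        d_qaly[i] = tr_ol.total_qalys - tr_no.total_qalys
        d_ly[i] = tr_ol.total_life_years - tr_no.total_life_years

    nmb = wtp[:, None] * d_qaly[None, :] - d_cost[None, :]
    prop = (nmb > 0).mean(axis=1)
    draws = pd.DataFrame(
        {"draw": np.arange(n), "d_cost": d_cost, "d_qaly": d_qaly, "d_ly": d_ly}
    )
    return PSAResult(
        seed=seed,
        n_draws=n,
        draws=draws,
        wtp_grid=wtp,
        prop_olaparib=prop,
        specs=specs,
    )
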