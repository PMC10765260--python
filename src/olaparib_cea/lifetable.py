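"""Age-indexed background-mortality life tables.

A life table is a sequence of one-year age classes with the annual
probability of death ``q(x)``.  The cohort engine looks mortality up by
completed years of age and converts the annual probability to a constant
monthly rate within the year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import prob_to_rate

__all__ = ["LifeTable", "load_life_table"]

# Annual death probabilities of exactly 1 would imply an infinite monthly
# rate; clip just below 1 so terminal open-ended age classes stay usable.
_Q_CAP = 1.0 - 1e-12


@dataclass
class LifeTable:
    """One-year age classes with annual death probabilities.

    Ages must be contiguous integers and probabilities must lie in [0, 1].
    """

    ages: np.ndarray
    annual_death_probs: np.ndarray
    source: str = ""
    _monthly_rate_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.annual_death_probs = np.asarray(self.annual_death_probs, dtype=float)
        if self.ages.size == 0 or self.ages.size != self.annual_death_probs.size:
            raise ValueError("ages and annual_death_probs must be equal-length, non-empty")
        if not np.array_equal(np.diff(self.ages), np.ones(self.ages.size - 1, dtype=int)):
            raise ValueError("ages must be contiguous integers")
        q = self.annual_death_probs
        if np.any(q < 0) or np.any(q > 1) or not np.all(np.isfinite(q)):
            raise ValueError("annual death probabilities must be in [0, 1]")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_prob(self, age: float) -> float:
        """Annual death probability for the age class containing ``age``."""
        idx = int(np.floor(age)) - self.min_age
        if idx < 0 or idx >= self.ages.size:
            raise ValueError(
                f"age {age} outside life-table coverage "
                f"[{self.min_age}, {self.max_age}]; refusing to extrapolate"
            )
        return float(self.annual_death_probs[idx])

    def monthly_death_prob(self, age: float) -> float:
        """Constant monthly death probability within the year of age ``age``."""
        q = min(self.annual_prob(age), _Q_CAP)
        return 1.0 - (1.0 - q) ** (1.0 / 12.0)

    def monthly_rates(self, starting_age: float, n_months: int) -> np.ndarray:
        """Monthly background death rates for months 1..n_months of a cohort.

        Month ``m`` uses the age class of ``starting_age + (m - 1)/12``.
        Cached per (starting_age, n_months) because the engine reuses the
        same vector across thousands of sensitivity-analysis runs.
        """
        key = (float(starting_age), int(n_months))
        hit = self._monthly_rate_cache.get(key)
        if hit is not None:
            return hit
        ages = starting_age + np.arange(n_months) / 12.0
        if np.floor(ages[-1]) > self.max_age or np.floor(ages[0]) < self.min_age:
            raise ValueError(
                f"horizon needs ages up to {np.floor(ages[-1]):.0f} but table "
                f"covers [{self.min_age}, {self.max_age}]"
            )
        idx = np.floor(ages).astype(int) - self.min_age
        q = np.minimum(self.annual_death_probs[idx], _Q_CAP)
        rates = -np.log1p(-q) / 12.0
        self._monthly_rate_cache[key] = rates
        return rates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "annual_death_prob": self.annual_death_probs}
        )

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if self.source:
                for line in self.source.splitlines():
                    fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.8g")


def monthly_background_death_prob(lt: LifeTable, age: float) -> float:
    """Monthly probability of non-breast-cancer death at continuous ``age``."""
    return lt.monthly_death_prob(age)


def load_life_table(path: str | Path) -> LifeTable:
    """Read a life table CSV with columns ``age,annual_death_prob``.

    Lines starting with ``#`` are treated as provenance comments and kept
    on the returned object.
    """
    path = Path(path)
    comments: list[str] = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                comments.append(line.lstrip("# ").rstrip("\n"))
            else:
                break
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse life table {path}: {exc}") from exc
    expected = {"age", "annual_death_prob"}
    if not expected.issubset(df.columns):
        raise ValueError(
            f"life table {path} must have columns {sorted(expected)}, "
            f"got {list(df.columns)}"
        )
    bad = df[(df.annual_death_prob < 0) | (df.annual_death_prob > 1)]
    if len(bad):
        raise ValueError(
            f"life table {path}: probabilities outside [0,1] at rows "
            f"{[int(i) + 2 for i in bad.index[:5]]}"
        )
    return LifeTable(
        ages=df["age"].to_numpy(),
        annual_death_probs=df["annual_death_prob"].to_numpy(),
        source="\n".join(comments),
    )
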