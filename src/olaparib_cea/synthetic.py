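"""Synthetic inputs: parametric life tables and engine-generated trial targets.

Everything the test-suite needs is generated here without any download:

* Gompertz–Makeham life tables — smooth, monotone adult mortality with
  known parameters, for property tests of the engine and calibration;
* trial-style DDFS/OS targets produced by running the cohort engine with a
  *known* recurrence schedule, closing the loop for parameter-recovery
  tests of the calibration routine;
* the bundled background-mortality fixture used for reproducing the
  published numbers — a synthetic Gompertz–Makeham reconstruction
  calibrated to 2018 US female life-table anchor values (see the CSV
  header for the anchors), not a verbatim transcription.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .calibration import TARGET_MONTHS, CalibrationTargets
from .engine import run_cohort
from .lifetable import LifeTable, load_life_table
from .params import ModelParams, RecurrenceSchedule

__all__ = [
    "GompertzParams",
    "gompertz_life_table",
    "simulate_trial_targets",
    "bundled_us2018_female_life_table",
]

_BUNDLED_NAME = "life_table_us2018_female_synthetic.csv"


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz–Makeham hazard ``h(x) = a * exp(b x) + c`` (per year)."""

    a: float
    b: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.c < 0:
            raise ValueError(f"need a > 0, b > 0, c >= 0, got {self}")

    def annual_death_prob(self, age: float) -> float:
        """1 - exp(-integral of the hazard over [age, age+1])."""
        cum = self.a * (math.exp(self.b * (age + 1)) - math.exp(self.b * age)) / self.b
        cum += self.c
        return -math.expm1(-cum)


def gompertz_life_table(gp: GompertzParams, max_age: int = 110) -> LifeTable:
    """Life table with ages 0..max_age from a Gompertz–Makeham hazard.

    Probabilities reaching 1 before ``max_age`` are capped with a warning.
    """
    if max_age > 120:
        raise ValueError(f"max_age must be <= 120, got {max_age}")
    ages = np.arange(max_age + 1)
    q = np.array([gp.annual_death_prob(x) for x in ages])
    if np.any(q >= 1.0):
        warnings.warn("Gompertz hazard saturates q=1 before max_age; capping")
        q = np.minimum(q, 1.0)
    return LifeTable(
        ages=ages,
        annual_death_probs=q,
        source=f"synthetic Gompertz-Makeham life table a={gp.a} b={gp.b} c={gp.c}",
    )


def simulate_trial_targets(
    schedule: RecurrenceSchedule, p: ModelParams, lt: LifeTable, arm: str = "synthetic"
) -> CalibrationTargets:
    """Deterministic 12/24/36/48-month DDFS/OS from a known schedule.

    Runs the cohort engine and reads the survival fractions off the trace;
    feeding these targets back to the calibrator should recover the
    schedule, which is the core oracle for the calibration tests.
    """
    trace = run_cohort(p.with_(schedule=schedule), lt, horizon_months=48)
    ddfs = {m: trace.ddfs(m) for m in TARGET_MONTHS}
    os_ = {m: trace.os(m) for m in TARGET_MONTHS}
    return CalibrationTargets(arm=arm, ddfs_by_month=ddfs, os_by_month=os_)


def bundled_us2018_female_life_table() -> LifeTable:
    """The packaged synthetic 2018-US-female background-mortality table."""
    ref = resources.files("olaparib_cea.data") / _BUNDLED_NAME
    with resources.as_file(ref) as path:
        if not path.exists():  # pragma: no cover - packaging error
            raise FileNotFoundError(f"bundled life table {_BUNDLED_NAME} missing")
        return load_life_table(path)
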