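"""Run configuration, artifact output, and the reproducibility manifest.

A single YAML file carries every model input (costs, utilities, hazard
ratio, recurrence extrapolation, calibration targets) plus the sensitivity
settings; the schema is validated strictly (unknown keys rejected, ranges
checked) so the config is the one source of truth for a run.
"""

from __future__ import annotations

import hashlib
import json
import time
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .calibration import CalibrationTargets
from .cea import DEFAULT_OWSA_RANGES, StrategyPair
from .lifetable import LifeTable, load_life_table
from .params import BASE_HAZARD_RATIO, ModelParams, RecurrenceSchedule
from .survival import HazardRatio

__all__ = [
    "RunConfig",
    "load_config",
    "load_life_table",
    "bundled_config_path",
    "config_json_schema",
    "RunManifest",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CostsBlock(_Strict):
    monthly_drug: float = Field(ge=0)
    oncologist_visit: float = Field(ge=0)
    imaging: float = Field(ge=0)
    monthly_metastatic: float = Field(ge=0)


class UtilitiesBlock(_Strict):
    no_recurrence: float = Field(ge=0, le=1)
    metastatic: float = Field(ge=0, le=1)
    olaparib_multiplier: float = Field(ge=0, le=1)


class HazardRatioBlock(_Strict):
    point: float = Field(gt=0)
    ci_low: float = Field(gt=0)
    ci_high: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self):
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("need ci_low <= point <= ci_high")
        return self


class RecurrenceBlock(_Strict):
    annual_prob_years5to9: float = Field(ge=0, lt=1)
    annual_prob_years10plus: float = Field(ge=0, lt=1)


class TargetsBlock(_Strict):
    ddfs: dict[int, float]
    os: dict[int, float]


class WtpGridBlock(_Strict):
    start: float = 0.0
    stop: float = 300_000.0
    step: float = 5_000.0


class SensitivityBlock(_Strict):
    n_psa: int = Field(default=10_000, ge=1)
    seed: int = 20_240_103
    wtp_grid: WtpGridBlock = WtpGridBlock()
    ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_OWSA_RANGES)
    )


class RunConfig(_Strict):
    """Validated model configuration (see ``data/base_case.yaml``)."""

    scenario: str = "base-case"
    starting_age: float = Field(default=42.0, gt=0, lt=110)
    max_age: float = Field(default=110.0, gt=0, le=120)
    annual_discount_rate: float = Field(default=0.03, ge=0)
    costs: CostsBlock
    utilities: UtilitiesBlock
    hazard_ratio: HazardRatioBlock
    recurrence: RecurrenceBlock
    monthly_metastatic_death_rate: float = Field(ge=0)
    imaging_fraction: float = Field(default=0.535, ge=0, le=1)
    treatment_duration_months: int = Field(default=12, gt=0)
    calibration_targets: dict[Literal["olaparib", "no_olaparib"], TargetsBlock]
    sensitivity: SensitivityBlock = SensitivityBlock()
    life_table: str | None = None  # path; None = bundled synthetic table

    @model_validator(mode="after")
    def _ages(self):
        if self.max_age <= self.starting_age:
            raise ValueError("max_age must exceed starting_age")
        return self

    # -- conversion to domain objects -------------------------------------

    def model_params(self, olaparib: bool) -> ModelParams:
        return ModelParams(
            label="olaparib" if olaparib else "no olaparib",
            olaparib=olaparib,
            starting_age=self.starting_age,
            monthly_drug_cost=self.costs.monthly_drug,
            oncologist_visit_cost=self.costs.oncologist_visit,
            imaging_cost=self.costs.imaging,
            monthly_metastatic_cost=self.costs.monthly_metastatic,
            utility_no_recurrence=self.utilities.no_recurrence,
            utility_metastatic=self.utilities.metastatic,
            olaparib_utility_multiplier=self.utilities.olaparib_multiplier,
            hazard_ratio=HazardRatio(
                self.hazard_ratio.point,
                self.hazard_ratio.ci_low,
                self.hazard_ratio.ci_high,
            ),
            schedule=RecurrenceSchedule(
                (0.0, 0.0, 0.0, 0.0),
                annual_prob_years5to9=self.recurrence.annual_prob_years5to9,
                annual_prob_years10plus=self.recurrence.annual_prob_years10plus,
            ),
            monthly_metastatic_death_rate=self.monthly_metastatic_death_rate,
            annual_discount_rate=self.annual_discount_rate,
            imaging_fraction=self.imaging_fraction,
            treatment_duration_months=self.treatment_duration_months,
            max_age=self.max_age,
        )

    def strategy_pair(self) -> StrategyPair:
        """Both arms with empty (pre-calibration) recurrence schedules."""
        return StrategyPair(
            no_olaparib=self.model_params(False), olaparib=self.model_params(True)
        )

    def targets(self, arm: Literal["olaparib", "no_olaparib"]) -> CalibrationTargets:
        block = self.calibration_targets[arm]
        return CalibrationTargets(
            arm=arm, ddfs_by_month=dict(block.ddfs), os_by_month=dict(block.os)
        )

    def resolve_life_table(self) -> LifeTable:
        if self.life_table is None:
            from .synthetic import bundled_us2018_female_life_table

            return bundled_us2018_female_life_table()
        return load_life_table(self.life_table)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def bundled_config_path() -> Path:
    ref = resources.files("olaparib_cea.data") / "base_case.yaml"
    with resources.as_file(ref) as path:
        return path


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``path=None`` loads the bundled base case.  Validation failures raise
    pydantic errors naming the offending field path.
    """
    path = bundled_config_path() if path is None else Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} not found")
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return RunConfig.model_validate(raw)


def config_json_schema() -> dict:
    """JSON schema of the run-config format (for editors and docs)."""
    return RunConfig.model_json_schema()


class RunManifest:
    """Per-run provenance: seed, config hash, version, wall time."""

    def __init__(self, command: str, config: RunConfig, seed: int | None = None):
        self.command = command
        self.config_hash = config.config_hash()
        self.scenario = config.scenario
        self.seed = seed
        self._t0 = time.time()

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "scenario": self.scenario,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "package_version": __version__,
            "wall_time_s": round(time.time() - self._t0, 3),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
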