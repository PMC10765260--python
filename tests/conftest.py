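import numpy as np
import pytest

from olaparib_cea import (
    CalibrationTargets,
    GompertzParams,
    LifeTable,
    ModelParams,
    StrategyPair,
    bundled_us2018_female_life_table,
    calibrate_arm,
    gompertz_life_table,
)
from olaparib_cea.io import load_config


@pytest.fixture(scope="session")
def bundled_lt() -> LifeTable:
    return bundled_us2018_female_life_table()


@pytest.fixture(scope="session")
def zero_lt() -> LifeTable:
    """No background mortality: isolates the disease process."""
    return LifeTable(ages=np.arange(121), annual_death_probs=np.zeros(121))


@pytest.fixture(scope="session")
def gompertz_lt() -> LifeTable:
    return gompertz_life_table(GompertzParams(a=2e-5, b=0.1, c=4e-4), max_age=120)


@pytest.fixture(scope="session")
def base_config():
    return load_config()


@pytest.fixture(scope="session")
def calibrated_pair(base_config, bundled_lt) -> StrategyPair:
    """Both arms with grid-calibrated (step 0.0001) recurrence schedules."""
    pair = base_config.strategy_pair()
    rep_no = calibrate_arm(
        base_config.targets("no_olaparib"), pair.no_olaparib, bundled_lt
    )
    rep_ol = calibrate_arm(
        base_config.targets("olaparib"), pair.no_olaparib, bundled_lt
    )
    return StrategyPair(
        no_olaparib=pair.no_olaparib.with_(schedule=rep_no.schedule),
        olaparib=pair.olaparib.with_(schedule=rep_ol.schedule),
    )


@pytest.fixture(scope="session")
def placebo_targets(base_config) -> CalibrationTargets:
    return base_config.targets("no_olaparib")


@pytest.fixture(scope="session")
def olaparib_targets(base_config) -> CalibrationTargets:
    return base_config.targets("olaparib")


@pytest.fixture()
def base_params() -> ModelParams:
    return ModelParams()
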