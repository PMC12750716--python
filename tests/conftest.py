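import json
from pathlib import Path

import pandas as pd
import pytest

from gmediate import MediationConfig
from gmediate.simulate import (
    RECOVERY_ADJUSTMENT_MEDIATOR,
    RECOVERY_ADJUSTMENT_OUTCOME,
    recovery_config,
)

FIXTURES = Path(__file__).parent / "fixtures"
EXAMPLES = Path(__file__).parent.parent / "examples"


@pytest.fixture(scope="session")
def fixtures_dir() -> Path:
    return FIXTURES


@pytest.fixture(scope="session")
def examples_dir() -> Path:
    return EXAMPLES


@pytest.fixture(scope="session")
def cohort_raw() -> pd.DataFrame:
    return pd.read_csv(FIXTURES / "cohort_n40_raw.csv")


@pytest.fixture(scope="session")
def cohort_derived() -> pd.DataFrame:
    return pd.read_csv(FIXTURES / "cohort_n40_derived.csv")


@pytest.fixture(scope="session")
def recovery_truth_fixture() -> dict:
    return json.loads((FIXTURES / "recovery_truth.json").read_text())


@pytest.fixture(scope="session")
def study_dag_text() -> str:
    return (EXAMPLES / "study_reconstructed.dag").read_text()


@pytest.fixture()
def recovery_dgp():
    return recovery_config()


@pytest.fixture()
def recovery_mediation_config() -> MediationConfig:
    """Mediation config whose fitted equations match the true recovery DGP."""
    return MediationConfig(
        adjustment_outcome=RECOVERY_ADJUSTMENT_OUTCOME,
        adjustment_mediator=RECOVERY_ADJUSTMENT_MEDIATOR,
    )
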