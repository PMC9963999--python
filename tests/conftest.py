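import numpy as np
import pytest
from hypothesis import settings

from paedz import SimulationConfig, default_true_models, simulate_cohort

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def truth():
    return default_true_models()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic screening cohort (n = 417, seed 1)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def ivsd_model(truth):
    return truth["IVSd"]


@pytest.fixture(scope="session")
def ee_model(truth):
    return truth["average E/e'"]


@pytest.fixture()
def tiny_csv(tmp_path):
    path = tmp_path / "cohort.csv"
    path.write_text(
        "athlete_id,ethnicity,chronological_age,height,weight,IVSd,average E/e'\n"
        "a1,arab,13.0,172.0,62.0,8.5,6.1\n"
        "a2,arab,15.5,180.0,72.0,9.1,5.8\n"
        "b1,black,16.0,178.0,70.0,9.4,6.4\n"
    )
    return path
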