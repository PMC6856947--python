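import pandas as pd
import pytest

from plurhom import SimulationConfig, simulate_cohort

# Canonical child group mixtures for noiseless recovery fixtures.
EXP1_WEIGHTS = {"hom/-si": 6 / 24, "hom/+si": 10 / 24, "exi/-si": 7 / 24, "exi/+si": 1 / 24}
EXP2_WEIGHTS = {"hom/-si": 0.2, "hom/+si": 0.3, "exi/-si": 0.3, "ws/-si": 0.1, "sa/-si": 0.1}


def true_groups(records: pd.DataFrame) -> pd.Series:
    return records.drop_duplicates("subject_id").set_index("subject_id")["true_group"]


@pytest.fixture(scope="session")
def exp1_noiseless() -> pd.DataFrame:
    config = SimulationConfig(
        experiment="EXP1", n_subjects=24, group_weights=EXP1_WEIGHTS, lapse_rate=0.0, seed=11
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def exp2_noiseless() -> pd.DataFrame:
    config = SimulationConfig(
        experiment="EXP2", n_subjects=24, group_weights=EXP2_WEIGHTS, lapse_rate=0.0, seed=12
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def exp1_noisy() -> pd.DataFrame:
    config = SimulationConfig(
        experiment="EXP1", n_subjects=24, group_weights=EXP1_WEIGHTS, lapse_rate=0.1, seed=13
    )
    return simulate_cohort(config)
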