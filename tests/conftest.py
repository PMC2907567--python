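import numpy as np
import pytest

from famscore.panels import autism_four_snp_panel
from famscore.pseudocontrol import build_matched_sets
from famscore.qc import select_index_cases
from famscore.scoring import ScoreModel
from famscore.simulate import SimConfig, simulate_families


@pytest.fixture(scope="session")
def agre_model() -> ScoreModel:
    return ScoreModel(tuple(autism_four_snp_panel("agre")))


@pytest.fixture(scope="session")
def seattle_dataset(agre_model):
    """Seattle-style multiplex families with genotyped sibling controls."""
    ds = simulate_families(
        SimConfig(n_families=200, ascertainment="seattle_like", seed=42)
    )
    return select_index_cases(ds)


@pytest.fixture(scope="session")
def agre_dataset():
    """AGRE-style multiplex families: >=2 affected, unaffected sibs masked."""
    ds = simulate_families(
        SimConfig(n_families=150, ascertainment="agre_like", seed=43)
    )
    return select_index_cases(ds)


@pytest.fixture(scope="session")
def agre_matched_sets(agre_dataset, agre_model):
    return build_matched_sets(agre_dataset, agre_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
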