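import numpy as np
import pandas as pd
import pytest

from beetlecomp import MCMCConfig, SimulationConfig
from beetlecomp.simulate import simulate_study


@pytest.fixture(scope="session")
def light_mcmc():
    """Small but adequate sampler budget for unit tests."""
    return MCMCConfig(chains=4, draws=500, warmup=400, seed=42)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared by read-only tests."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture()
def three_tip_tree():
    from beetlecomp import Phylogeny

    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


def make_dispersal_table(rows):
    return pd.DataFrame(rows, columns=["group", "trial_id", "sex", "distance", "died"])


def make_cross_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "block",
            "maternal_family",
            "paternal_family",
            "cross_type",
            "offspring_count",
        ],
    )
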