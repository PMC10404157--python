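"""Shared fixtures: synthetic ground truth, screens, and priors."""

import numpy as np
import pandas as pd
import pytest

from fcmix import simulate as sim
from fcmix.priors import build_priors


def single_subclass_design(design: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated pure-composition conditions (one row per receptor,
    valency, subclass)."""
    pure = design[(design["frac1"] == 1.0) | (design["frac1"] == 0.0)].copy()
    pure["sub"] = np.where(pure["frac1"] == 1.0, pure["subclass1"], pure["subclass2"])
    pure = pure.drop_duplicates(subset=["receptor", "valency", "sub"])
    return pure.drop(columns="sub").reset_index(drop=True)


@pytest.fixture(scope="session")
def truth():
    return sim.default_truth(seed=11)


@pytest.fixture(scope="session")
def design():
    return sim.generate_design()


@pytest.fixture(scope="session")
def pure_screen(truth, design):
    """Noisy single-subclass screen: 6 receptors x 2 valencies x 4 subclasses
    x 3 replicates at 20% CV."""
    return sim.simulate_binding_screen(truth, single_subclass_design(design), replicates=3)


@pytest.fixture(scope="session")
def screen_priors(truth):
    return build_priors(
        sim.documented_affinity_table(), sim.simulate_expression_replicates(truth)
    )
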