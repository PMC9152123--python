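import numpy as np
import pytest

from cpmnet import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-node cohort with planted signal, small but realistic groups."""
    cfg = synthetic.SimulationConfig(
        n_nodes=30,
        n_per_group={"FES": 20, "GHR": 12, "HC": 14},
        n_signal_pos=4,
        n_signal_neg=4,
        effect_size=0.25,
        seed=7,
    )
    return synthetic.generate_cohort(cfg)


@pytest.fixture(scope="session")
def fes_data(small_cohort):
    """(edge_matrix, scores) for the symptomatic group of small_cohort."""
    mask = small_cohort.group_mask("FES")
    return (
        small_cohort.edge_matrix[mask],
        small_cohort.cohort.loc[mask, "score"].to_numpy(),
    )
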