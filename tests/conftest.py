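import numpy as np
import pytest
from hypothesis import settings

from trxscore import (
    GridSpec,
    SimulationSpec,
    make_dataset,
    make_toy_structure,
    make_truth_conformer,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix10():
    """10-residue ideal poly-alanine helix."""
    return make_toy_structure(10, "helix", seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Small noise-free two-state dataset (8 residues, q=0.25)."""
    spec = SimulationSpec(
        n_residues=8, q_true=0.25, noise=0.0, n_decoys=6, n_near=2, seed=7,
        spacing=0.8,
    )
    return spec, make_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
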