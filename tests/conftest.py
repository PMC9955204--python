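import numpy as np
import pytest

from casdyn.synthetic import (
    MarkovChainSpec,
    ToyChainSpec,
    block_transition_matrix,
    markov_backbone_trajectory,
    simulate_markov_chain,
)


@pytest.fixture(scope="session")
def block_chain():
    """4-state chain of two weakly coupled 2-state blocks + a long sample."""
    t = block_transition_matrix(n_blocks=2, block_size=2, intra=0.1, inter=1e-3)
    spec = MarkovChainSpec(transition_matrix=t, initial_state=0, seed=11)
    seq = simulate_markov_chain(spec, 100_000)
    return t, seq


@pytest.fixture(scope="session")
def peptide_trajectory():
    """Small peptide trajectory whose torsions encode a known 4-state chain."""
    t = block_transition_matrix(n_blocks=2, block_size=2, intra=0.08, inter=0.02)
    spec = MarkovChainSpec(transition_matrix=t, initial_state=0, seed=5)
    traj, states = markov_backbone_trajectory(spec, 300, n_residues=5)
    return traj, states, t


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
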