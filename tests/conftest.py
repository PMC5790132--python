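"""Shared fixtures.

The expensive fixtures are session-scoped so that simulation, surface
fitting and MCMC work is shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from clockpart.experiment import ExperimentConfig, simulate_replicate
from clockpart.ml import SubstModelConfig, fit_branch_lengths
from clockpart.trees import build_reference_timetree


@pytest.fixture(scope="session")
def tree():
    return build_reference_timetree()


@pytest.fixture(scope="session")
def small_config():
    """Reduced simulation design used by unit tests."""
    return ExperimentConfig(n_genes=8, n_codons=120, master_seed=20)


@pytest.fixture(scope="session")
def small_replicate(tree, small_config):
    """One reduced replicate: (nucleotide alignment, gene realizations)."""
    return simulate_replicate(small_config, 0, tree=tree)


@pytest.fixture(scope="session")
def small_surface(tree, small_replicate):
    """Concatenated approximate-likelihood surface of the reduced replicate."""
    aln, _ = small_replicate
    return fit_branch_lengths(aln, tree, SubstModelConfig(), partition=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
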