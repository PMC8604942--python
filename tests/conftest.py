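"""Shared fixtures: small parameter sets, trees and random sources."""

import numpy as np
import pytest

from tswitch.codon_model import CodonModelParams, PhyloTree
from tswitch.core_seq import SENSE_CODONS


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250917)


@pytest.fixture(scope="session")
def small_params(rng):
    freqs = rng.dirichlet(np.ones(61) * 5.0)
    return CodonModelParams(
        kappa=2.0,
        omega_shape=0.8,
        omega_rate=3.0,
        n_categories=4,
        codon_freqs=freqs,
    )


@pytest.fixture(scope="session")
def quartet_tree():
    return PhyloTree.from_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.08);")


def random_codon_seq(rng, n_codons):
    return "".join(rng.choice(SENSE_CODONS, size=n_codons))
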