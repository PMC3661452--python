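import numpy as np
import pytest

from bovigh.repertoire import ExpressedSequence
from bovigh.synthetic import (GermlineSimSpec, RepertoireSimSpec,
                              simulate_germline, simulate_repertoire)


@pytest.fixture(scope="session")
def small_locus():
    """A 10-V two-family locus: 4 F, 2 ORF, 4 Psi (one fragment)."""
    return simulate_germline(GermlineSimSpec(
        n_v=10, n_functional=4, pseudogene_fraction=0.4,
        fragment_fraction=0.1, seed=11))


@pytest.fixture(scope="session")
def small_repertoire(small_locus):
    reads, truth = simulate_repertoire(
        small_locus,
        RepertoireSimSpec(per_isotype={"IgM": 10, "IgG": 10},
                          shm_rate=0.02, seed=5))
    return reads, truth


@pytest.fixture(scope="session")
def clean_repertoire(small_locus):
    """Unmutated reads: recovery must be exact."""
    reads, truth = simulate_repertoire(
        small_locus,
        RepertoireSimSpec(per_isotype={"IgM": 15, "IgA": 15},
                          shm_rate=0.0, seed=8))
    return reads, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def as_expressed(reads):
    return [ExpressedSequence(rid, nt) for rid, nt in reads]
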