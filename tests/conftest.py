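import numpy as np
import pytest

import tunnelseq as tq
from tunnelseq.chain import ChainHamiltonian, NucleotideSequence
from tunnelseq.fragments import DNA_ALPHABET, FragmentParameterSet


@pytest.fixture(scope="session")
def dna_params():
    return tq.generate_parameter_set("DNA", 5, seed=1)


@pytest.fixture(scope="session")
def rna_params():
    return tq.generate_parameter_set("RNA", 5, seed=1)


def make_m1_params(onsite: dict[str, float] | None = None,
                   coupling: float = 0.05) -> FragmentParameterSet:
    """Hand-built single-orbital parameter set with closed-form spectra."""
    onsite = onsite or {"A": -5.5, "C": -5.6, "G": -5.3, "T": -5.8}
    blocks = {b: np.array([[onsite[b]]]) for b in DNA_ALPHABET}
    couplings = {(x, y): np.array([[coupling]])
                 for x in DNA_ALPHABET for y in DNA_ALPHABET}
    return FragmentParameterSet(DNA_ALPHABET, "DNA", 1, blocks, couplings,
                                {"seed": -1, "regime": "analytic",
                                 "schema": "tunnelseq-params-1"})


@pytest.fixture()
def m1_params():
    return make_m1_params()


def single_site_chain(eps: float) -> ChainHamiltonian:
    """One site, one orbital at energy ``eps`` (scalar closed forms)."""
    return ChainHamiltonian([np.array([[eps]])], [],
                            NucleotideSequence("A"), 1)
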