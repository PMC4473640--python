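"""Block-tridiagonal chain Hamiltonians for concrete DNA/RNA sequences.

A sequence X_1 … X_n maps to an (n·m)×(n·m) Hermitian tight-binding
Hamiltonian with one m-orbital block per nucleotide.  The onsite block of
site i is the isolated-fragment block plus the two-center renormalization
contributed by each existing neighbour,

    ε_i = h_{X_i} + R(V_{X_i X_{i+1}}) + R(V_{X_i X_{i−1}}) ,

where R(V) = (V + Vᵀ)/2 keeps the onsite correction Hermitian (the exact
two-center onsite integral ⟨φ_iα|V̂|φ_iβ⟩ is Hermitian in the full theory;
symmetrization restores that property at the reduced level).  Hopping
blocks between neighbours are the coupling blocks themselves; all couplings
beyond first neighbours are structurally zero.

Only the single strand as given (5′→3′) is modelled; there is no
complement or base-pairing logic anywhere in the physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import AlphabetError
from .fragments import DNA_ALPHABET, RNA_ALPHABET, FragmentParameterSet


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated single-stranded sequence over a 4-letter alphabet.

    Sites are indexed 0-based internally; reports use 1-based positions.
    """

    symbols: str
    alphabet_kind: str = "DNA"
    identifier: str = ""

    def __post_init__(self) -> None:
        alphabet = set(self.alphabet())
        if not self.symbols:
            raise AlphabetError("sequence must be nonempty")
        bad = sorted(set(self.symbols) - alphabet)
        if bad:
            raise AlphabetError(
                f"symbols {bad} not in {self.alphabet_kind} alphabet")

    def alphabet(self) -> tuple[str, ...]:
        if self.alphabet_kind == "DNA":
            return DNA_ALPHABET
        if self.alphabet_kind == "RNA":
            return RNA_ALPHABET
        raise AlphabetError(f"unknown alphabet_kind {self.alphabet_kind!r}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __getitem__(self, i) -> str:
        return self.symbols[i]

    def reversed(self) -> "NucleotideSequence":
        return NucleotideSequence(self.symbols[::-1], self.alphabet_kind,
                                  self.identifier + "|reversed")


def read_fasta(path: str | Path, alphabet_kind: str = "DNA",
               convert_t_u: bool = False) -> list[NucleotideSequence]:
    """Read all records of a FASTA file as NucleotideSequence objects.

    ``convert_t_u=True`` explicitly maps T↔U to match ``alphabet_kind``
    (RNA records written with T, or vice versa); without the flag a
    mismatched symbol raises, the mapping is never silent.
    """
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if convert_t_u:
            seq = seq.replace("T", "U") if alphabet_kind == "RNA" else seq.replace("U", "T")
        out.append(NucleotideSequence(seq, alphabet_kind, record.id))
    if not out:
        raise AlphabetError(f"no FASTA records found in {path}")
    return out


def write_fasta(sequences: list[NucleotideSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f">{seq.identifier or f'seq{i + 1}'}\n{seq.symbols}\n")


@dataclass
class ChainHamiltonian:
    """Neighbour-renormalized block-tridiagonal Hamiltonian of a sequence."""

    onsite_blocks: list[np.ndarray]
    hopping_blocks: list[np.ndarray] = field(default_factory=list)
    sequence: NucleotideSequence | None = None
    m: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.onsite_blocks)

    @property
    def dimension(self) -> int:
        return self.n_sites * self.m


def _renorm(v: np.ndarray) -> np.ndarray:
    """Hermitian part of a coupling block (onsite renormalization map)."""
    return (v + v.conj().T) / 2.0


def build_chain(seq: NucleotideSequence,
                params: FragmentParameterSet) -> ChainHamiltonian:
    """Assemble onsite and hopping blocks for ``seq`` from fragment blocks."""
    if seq.alphabet_kind != params.alphabet_kind:
        raise AlphabetError(
            f"sequence is {seq.alphabet_kind} but parameters are "
            f"{params.alphabet_kind}")
    missing = sorted(set(seq.symbols) - set(params.alphabet))
    if missing:
        raise AlphabetError(f"symbols {missing} not in parameter alphabet")

    n = len(seq)
    onsite: list[np.ndarray] = []
    for i, base in enumerate(seq.symbols):
        block = params.onsite_blocks[base].copy()
        if i + 1 < n:
            block += _renorm(params.coupling_blocks[(base, seq[i + 1])])
        if i > 0:
            block += _renorm(params.coupling_blocks[(base, seq[i - 1])])
        onsite.append(block)
    hopping = [params.coupling_blocks[(seq[i], seq[i + 1])].copy()
               for i in range(n - 1)]
    return ChainHamiltonian(onsite, hopping, seq, params.m)


def assemble_dense(chain: ChainHamiltonian) -> np.ndarray:
    """Dense (n·m)×(n·m) Hermitian matrix with the block-tridiagonal layout."""
    n, m = chain.n_sites, chain.m
    dtype = np.result_type(*[b.dtype for b in chain.onsite_blocks])
    h = np.zeros((n * m, n * m), dtype=dtype)
    for i, block in enumerate(chain.onsite_blocks):
        h[i * m:(i + 1) * m, i * m:(i + 1) * m] = block
    for i, v in enumerate(chain.hopping_blocks):
        h[i * m:(i + 1) * m, (i + 1) * m:(i + 2) * m] = v
        h[(i + 1) * m:(i + 2) * m, i * m:(i + 1) * m] = v.conj().T
    return h
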