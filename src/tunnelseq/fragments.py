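"""Synthetic per-nucleotide tight-binding parameter sets.

The transport model represents a single-stranded DNA or RNA molecule as a
linear chain of sites, one per nucleotide, each carrying ``m`` molecular
orbitals (MOs).  In a first-principles workflow the m-by-m onsite blocks
``h_X`` and nearest-neighbour coupling blocks ``V_XY`` would be extracted
from fragment-molecular-orbital electronic-structure calculations of single
nucleotides and nucleotide pairs, projected onto the orbitals inside the
transport-active energy window.  Published electronic-structure data
constrain the *shape* of that reduced model — nucleotide HOMO levels fall
between −6.0 and −5.0 eV, the LUMO sits approximately 4.0 eV above the
HOMO, five MOs (four occupied plus one LUMO) dominate transport, and
second-nearest-neighbour couplings are two orders of magnitude smaller than
first-neighbour ones — but the individual matrix elements are not public.
This module generates seeded random parameter sets with exactly those
spectral features (a DFT surrogate), so every downstream stage — chain
assembly, Green's-function transport, calibration, base calling — runs at
realistic energy scales.

It also generates *full* (unreduced) fragment systems with a non-orthogonal
overlap matrix, used to exercise the projection machinery that produces
reduced models from large ones.

Default HOMO placement (eV), chosen to reproduce the qualitative current
ordering of the tunneling regime (G > A ~ C > T, with A and C close):

==== =======
base HOMO
==== =======
G    −5.15
A    −5.48
C    −5.62
T    −5.95
U    −5.99  (RNA only; lowest of the set, deeper levels shifted further)
==== =======
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import AlphabetError, SchemaError

DNA_ALPHABET: tuple[str, ...] = ("A", "C", "G", "T")
RNA_ALPHABET: tuple[str, ...] = ("A", "C", "G", "U")

PARAMS_SCHEMA = "tunnelseq-params-1"

#: Default HOMO targets (eV).  See module docstring.
HOMO_TARGETS = {"A": -5.48, "C": -5.62, "G": -5.15, "T": -5.95, "U": -5.99}

_HERMITICITY_TOL = 1e-12


@dataclass(frozen=True)
class RegimeSpec:
    """Level-placement recipe for the synthetic generator.

    Parameters are in eV unless noted.  ``coupling_scale`` bounds the
    per-pair magnitude scale of the nearest-neighbour coupling blocks; the
    scale is drawn log-uniformly within the bounds, placing couplings one to
    two orders of magnitude below the onsite level spread, consistent with a
    rapidly decaying inter-fragment interaction.
    """

    homo_targets: Mapping[str, float] = field(default_factory=lambda: dict(HOMO_TARGETS))
    gap: float = 4.0                      # LUMO − HOMO
    level_spacing: float = 0.75           # spacing of occupied levels below HOMO
    first_offset: float = 0.8             # HOMO-1 sits this far below the HOMO
    jitter: float = 0.008                 # seeded per-level jitter amplitude
    onsite_offdiag: float = 0.01          # symmetric onsite perturbation scale
    coupling_scale: tuple[float, float] = (0.05, 0.3)
    coupling_norm_cap: float = 0.7        # fraction of the onsite level spacing
    backbone_eps: float = 0.05            # RNA backbone perturbation bound (Frobenius)
    u_deep_extra: float = 0.25            # extra lowering of U's occupied non-HOMO levels
    tag: str = "default"


@dataclass(frozen=True)
class OrbitalLevelSet:
    """Ordered MO level energies of one nucleotide fragment.

    ``homo_index`` points at the highest occupied level; for the standard
    five-orbital model exactly one level (the LUMO) lies above it.
    """

    base_label: str
    level_energies: tuple[float, ...]
    homo_index: int

    def __post_init__(self) -> None:
        e = np.asarray(self.level_energies, dtype=float)
        if e.ndim != 1 or e.size < 1:
            raise ValueError("level_energies must be a nonempty 1-D sequence")
        if not np.all(np.diff(e) > 0):
            raise ValueError("level_energies must be strictly increasing")
        if not 0 <= self.homo_index < e.size:
            raise ValueError("homo_index out of range")

    @property
    def homo(self) -> float:
        return self.level_energies[self.homo_index]

    @property
    def lumo(self) -> float | None:
        if self.homo_index + 1 < len(self.level_energies):
            return self.level_energies[self.homo_index + 1]
        return None


@dataclass
class FragmentParameterSet:
    """Reduced tight-binding "alphabet": onsite and coupling blocks in eV.

    ``onsite_blocks[X]`` is the m×m Hermitian block of nucleotide X;
    ``coupling_blocks[(X, Y)]`` couples a site of base X to its right
    neighbour of base Y and satisfies V_YX = V_XYᵀ.  Only first
    nearest-neighbour couplings exist in this data model; second-neighbour
    terms are structurally zero.
    """

    alphabet: tuple[str, ...]
    alphabet_kind: str
    m: int
    onsite_blocks: dict[str, np.ndarray]
    coupling_blocks: dict[tuple[str, str], np.ndarray]
    metadata: dict = field(default_factory=dict)

    def validate(self, tol: float = _HERMITICITY_TOL) -> None:
        if len(self.alphabet) != 4:
            raise SchemaError("alphabet must have exactly 4 symbols")
        for base in self.alphabet:
            h = self.onsite_blocks.get(base)
            if h is None:
                raise SchemaError(f"missing onsite block for base {base!r}")
            if h.shape != (self.m, self.m):
                raise SchemaError(f"onsite block {base!r} has shape {h.shape}")
            if np.max(np.abs(h - h.conj().T)) > tol:
                raise SchemaError(f"onsite block {base!r} is not Hermitian to {tol:g}")
        for x in self.alphabet:
            for y in self.alphabet:
                v = self.coupling_blocks.get((x, y))
                if v is None:
                    raise SchemaError(f"missing coupling block for pair ({x}, {y})")
                vt = self.coupling_blocks[(y, x)]
                if np.max(np.abs(vt - v.T)) > tol:
                    raise SchemaError(f"coupling pair ({x}, {y}) violates V_YX = V_XYᵀ")

    def levels(self, base: str) -> OrbitalLevelSet:
        """Eigenlevels of the onsite block, with the HOMO flagged."""
        e = np.linalg.eigvalsh(self.onsite_blocks[base])
        homo_index = max(self.m - 2, 0) if self.m >= 2 else 0
        return OrbitalLevelSet(base, tuple(e), homo_index)

    def homo(self, base: str) -> float:
        return self.levels(base).homo

    def content_hash(self) -> str:
        """SHA-256 of the canonical serialization, for provenance records."""
        return hashlib.sha256(_to_json(self).encode()).hexdigest()[:16]


@dataclass
class FullFragmentSystem:
    """Unreduced fragment system: Hamiltonian, non-orthogonal overlap and the
    index set of the transport-active orbital subspace P."""

    hamiltonian: np.ndarray
    overlap: np.ndarray
    active_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        M = self.hamiltonian.shape[0]
        if self.hamiltonian.shape != (M, M) or self.overlap.shape != (M, M):
            raise ValueError("hamiltonian and overlap must be square and same size")
        idx = tuple(self.active_indices)
        if len(set(idx)) != len(idx) or not idx:
            raise ValueError("active_indices must be distinct and nonempty")
        if min(idx) < 0 or max(idx) >= M:
            raise ValueError("active_indices out of range")
        if len(idx) >= M:
            raise ValueError("active subspace must be a proper subset")
        object.__setattr__(self, "active_indices", idx)

    @property
    def size(self) -> int:
        return self.hamiltonian.shape[0]

    @property
    def inactive_indices(self) -> tuple[int, ...]:
        active = set(self.active_indices)
        return tuple(i for i in range(self.size) if i not in active)


def _alphabet_for(kind: str) -> tuple[str, ...]:
    kinds = {"DNA": DNA_ALPHABET, "RNA": RNA_ALPHABET}
    if kind not in kinds:
        raise AlphabetError(f"alphabet_kind must be 'DNA' or 'RNA', got {kind!r}")
    return kinds[kind]


def _level_template(homo: float, m: int, regime: RegimeSpec) -> np.ndarray:
    """Occupied ladder below the HOMO plus one LUMO at homo + gap."""
    if m == 1:
        return np.array([homo])
    deep = [homo - regime.first_offset - regime.level_spacing * j for j in range(m - 2)]
    return np.array(sorted(deep) + [homo, homo + regime.gap])


def _onsite_block(homo: float, m: int, regime: RegimeSpec, rng: np.random.Generator) -> np.ndarray:
    levels = _level_template(homo, m, regime)
    levels = levels + regime.jitter * rng.uniform(-1.0, 1.0, size=m)
    levels.sort()
    pert = regime.onsite_offdiag * rng.uniform(-1.0, 1.0, size=(m, m))
    pert = (pert + pert.T) / 2.0
    np.fill_diagonal(pert, 0.0)
    return np.diag(levels) + pert


def _coupling_block(m: int, regime: RegimeSpec, rng: np.random.Generator,
                    symmetric: bool) -> np.ndarray:
    lo, hi = regime.coupling_scale
    scale = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    block = scale * rng.uniform(-1.0, 1.0, size=(m, m))
    if symmetric:
        block = (block + block.T) / 2.0
    # stay perturbative: spectral norm below the onsite level spacing
    cap = regime.coupling_norm_cap * min(regime.first_offset, regime.level_spacing)
    norm = np.linalg.norm(block, 2)
    if norm > cap:
        block *= cap / norm
    return block


def _generate_dna(m: int, rng: np.random.Generator, regime: RegimeSpec) -> tuple[dict, dict]:
    onsite = {b: _onsite_block(regime.homo_targets[b], m, regime, rng) for b in DNA_ALPHABET}
    coupling: dict[tuple[str, str], np.ndarray] = {}
    for i, x in enumerate(DNA_ALPHABET):
        for y in DNA_ALPHABET[i:]:
            v = _coupling_block(m, regime, rng, symmetric=(x == y))
            coupling[(x, y)] = v
            coupling[(y, x)] = v.T
    return onsite, coupling


def _sym_perturbation(m: int, fro_norm: float, rng: np.random.Generator) -> np.ndarray:
    p = rng.standard_normal((m, m))
    p = (p + p.T) / 2.0
    return p * (fro_norm / np.linalg.norm(p))


def generate_parameter_set(alphabet_kind: str, m: int = 5, seed: int = 0,
                           regime: RegimeSpec | None = None) -> FragmentParameterSet:
    """Generate a seeded synthetic fragment parameter set.

    DNA sets place each base's HOMO inside [−6.0, −5.0] eV with the LUMO
    ``regime.gap`` (default 4.0 eV) above.  RNA sets reuse the DNA A/C/G
    blocks plus a backbone perturbation of Frobenius norm ≤
    ``regime.backbone_eps`` (the ribose backbone barely touches the frontier
    orbitals), while U is built from its own, clearly lower, level template
    (the chemical modification is in the base itself).

    Deterministic for a fixed ``(alphabet_kind, m, seed, regime)``.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    alphabet = _alphabet_for(alphabet_kind)
    regime = regime or RegimeSpec()
    ss = np.random.SeedSequence(seed)
    dna_stream, extra_stream = [np.random.default_rng(s) for s in ss.spawn(2)]

    onsite, coupling = _generate_dna(m, dna_stream, regime)

    if alphabet_kind == "RNA":
        # A', C', G': DNA blocks + small symmetric backbone perturbation.
        for b in ("A", "C", "G"):
            norm = 0.8 * regime.backbone_eps  # strictly inside the bound
            onsite[b] = onsite[b] + _sym_perturbation(m, norm, extra_stream)
        # U: own template, HOMO just below T's and deep levels pushed further down.
        u_regime = regime
        u_homo = regime.homo_targets.get("U", HOMO_TARGETS["U"])
        u_levels = _level_template(u_homo, m, u_regime)
        if m > 2:
            u_levels[: m - 2] -= regime.u_deep_extra
        u_block = np.diag(u_levels + regime.jitter * extra_stream.uniform(-1, 1, size=m))
        pert = regime.onsite_offdiag * extra_stream.uniform(-1, 1, size=(m, m))
        pert = (pert + pert.T) / 2.0
        np.fill_diagonal(pert, 0.0)
        onsite["U"] = u_block + pert
        onsite.pop("T")
        # Couplings: inherit the DNA blocks (T↦U) plus a tiny backbone term.
        rna_coupling: dict[tuple[str, str], np.ndarray] = {}
        mapped = {"A": "A", "C": "C", "G": "G", "U": "T"}
        for i, x in enumerate(RNA_ALPHABET):
            for y in RNA_ALPHABET[i:]:
                v = coupling[(mapped[x], mapped[y])].copy()
                delta = 0.1 * regime.backbone_eps * extra_stream.uniform(-1, 1, size=(m, m))
                if x == y:
                    delta = (delta + delta.T) / 2.0
                v = v + delta
                rna_coupling[(x, y)] = v
                rna_coupling[(y, x)] = v.T
        coupling = rna_coupling

    params = FragmentParameterSet(
        alphabet=alphabet,
        alphabet_kind=alphabet_kind,
        m=m,
        onsite_blocks={b: onsite[b] for b in alphabet},
        coupling_blocks=coupling,
        metadata={
            "seed": int(seed),
            "regime": regime.tag,
            "schema": PARAMS_SCHEMA,
            "coupling_scale": list(regime.coupling_scale),
        },
    )
    params.validate()
    return params


def generate_full_fragment_system(M: int, active_count: int, seed: int = 0,
                                  active_window: tuple[float, float] = (-6.0, -5.0),
                                  coupling_sigma: float = 0.15,
                                  overlap_strength: float = 0.3) -> FullFragmentSystem:
    """Random full fragment system with non-orthogonal SPD overlap.

    The first ``active_count`` orbitals carry level energies inside
    ``active_window``; the remaining orbitals are placed well below and
    above it, so the generalized eigenvalues cleanly separate into an
    active group (recoverable by the projected effective Hamiltonian) and
    far-away spectator levels.  The overlap has unit diagonal and is scaled
    to stay safely positive definite.
    """
    if M <= active_count or active_count < 1:
        raise ValueError("require M > active_count >= 1")
    rng = np.random.default_rng(seed)
    diag = np.empty(M)
    lo, hi = active_window
    diag[:active_count] = rng.uniform(lo, hi, size=active_count)
    n_q = M - active_count
    n_below = n_q // 2 + n_q % 2
    diag[active_count:active_count + n_below] = rng.uniform(-11.0, -8.5, size=n_below)
    diag[active_count + n_below:] = rng.uniform(-2.5, -1.0, size=n_q - n_below)
    off = coupling_sigma * rng.standard_normal((M, M))
    off = (off + off.T) / 2.0
    np.fill_diagonal(off, 0.0)
    H = np.diag(diag) + off

    K = rng.uniform(-1.0, 1.0, size=(M, M))
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 0.0)
    spread = np.max(np.abs(np.linalg.eigvalsh(K))) or 1.0
    S = np.eye(M) + (overlap_strength / spread) * K

    return FullFragmentSystem(H, S, tuple(range(active_count)))


# ---------------------------------------------------------------------------
# serialization (canonical JSON; byte-exact round trips)

def _to_json(params: FragmentParameterSet) -> str:
    doc = {
        "schema": PARAMS_SCHEMA,
        "alphabet": list(params.alphabet),
        "alphabet_kind": params.alphabet_kind,
        "m": params.m,
        "metadata": params.metadata,
        "onsite": {b: params.onsite_blocks[b].tolist() for b in params.alphabet},
        "coupling": {x + y: params.coupling_blocks[(x, y)].tolist()
                     for x in params.alphabet for y in params.alphabet},
    }
    return json.dumps(doc, sort_keys=True, indent=1)


def write_parameter_set(params: FragmentParameterSet, path: str | Path) -> None:
    """Write the canonical JSON serialization (row-major blocks, eV)."""
    Path(path).write_text(_to_json(params))


def read_parameter_set(path: str | Path) -> FragmentParameterSet:
    """Read and validate a parameter set; raises SchemaError on corruption."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not a parameter-set file: {exc}") from exc
    if doc.get("schema") != PARAMS_SCHEMA:
        raise SchemaError(f"unsupported schema version {doc.get('schema')!r}; "
                          f"expected {PARAMS_SCHEMA!r}")
    alphabet = tuple(doc["alphabet"])
    m = int(doc["m"])
    onsite = {b: np.array(doc["onsite"][b], dtype=float) for b in alphabet}
    coupling: dict[tuple[str, str], np.ndarray] = {}
    for x in alphabet:
        for y in alphabet:
            key = x + y
            if key not in doc["coupling"]:
                raise SchemaError(f"missing coupling block for pair ({x}, {y})")
            coupling[(x, y)] = np.array(doc["coupling"][key], dtype=float)
    params = FragmentParameterSet(alphabet, doc["alphabet_kind"], m, onsite,
                                  coupling, dict(doc.get("metadata", {})))
    params.validate()
    return params
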