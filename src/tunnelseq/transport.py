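"""Zero-temperature transverse tunneling current through each nucleotide.

Two wide-band electrodes contact one nucleotide k at a time; within the
wide-band approximation (WBA) the electrode self-energies are constant,
Σ_{L/R} = −i·Γ_{L/R}/2 on the m orbitals of the contacted site, and the
escape-rate matrices are Γ_{L/R} = −2·Im Σ_{L/R}.  The electrode chemical
potential equals minus the metal work function on the vacuum-referenced
molecular energy axis, so Al (W = 4.08 eV) probes the HOMO–LUMO gap
(tunneling regime) while Au (5.10 eV) lands on the HOMO band (resonant
regime).

The current through base k at zero temperature is the Meir–Wingreen /
Landauer integral over the bias window

    I_k = (2e/h) ∫_{μ_R}^{μ_L} dE  Tr[ Γ_L^k G(E) Γ_R^k G†(E) ] ,

with G(E) = (E − H_S − Σ_L − Σ_R)⁻¹ the retarded Green's function of the
electrode-coupled chain.  Currents are stored in units of (2e/h)·eV; the
constant ``CURRENT_UNIT_AMPERE`` converts one such unit to amperes.

Because Σ touches only the m×m block of the contacted site, the site-block
Green's function is obtained from a single eigendecomposition of H_S plus a
low-rank (Woodbury) update per energy:

    G_kk(E) = A + A σ (1 − A σ)⁻¹ A ,   A = U_k diag(1/(E−ε_j)) U_kᵀ ,

where U_k are the site-k rows of the eigenvectors of H_S and σ = −iΓ_tot/2.
Direct dense inversion remains the contract (and the test oracle).

Transmission features have width ~Γ = 10⁻³ eV, far finer than the bias
window, so the energy integral uses panel-adaptive Gauss–Legendre
quadrature with forced panel boundaries at every chain eigenvalue inside
the window (±10Γ margin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chain import ChainHamiltonian, NucleotideSequence, assemble_dense
from .errors import QuadratureError

#: amperes per (2e/h)·eV of integrated transmission
CURRENT_UNIT_AMPERE = 7.748091729e-5

#: default electrode work functions (eV)
WORK_FUNCTIONS = {"Al": 4.08, "Gr": 4.60, "Au": 5.10, "Pt": 5.65}

#: weak physisorption contact escape rate (eV)
DEFAULT_GAMMA = 1e-3


@dataclass(frozen=True)
class ElectrodePair:
    """Wide-band electrode pair: work function (eV) and escape rates (eV)."""

    work_function: float
    gamma_left: float = DEFAULT_GAMMA
    gamma_right: float = DEFAULT_GAMMA
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.gamma_left < 0 or self.gamma_right < 0:
            raise ValueError("escape rates must be nonnegative")
        if not np.isfinite(self.work_function):
            raise ValueError("work function must be finite")

    @classmethod
    def preset(cls, label: str, gamma: float = DEFAULT_GAMMA) -> "ElectrodePair":
        if label not in WORK_FUNCTIONS:
            raise ValueError(f"unknown electrode {label!r}; "
                             f"presets: {sorted(WORK_FUNCTIONS)}")
        return cls(WORK_FUNCTIONS[label], gamma, gamma, label)

    @property
    def chemical_potential(self) -> float:
        """Equilibrium chemical potential on the molecular energy axis (eV)."""
        return -self.work_function

    def scaled(self, factor: float) -> "ElectrodePair":
        return ElectrodePair(self.work_function, factor * self.gamma_left,
                             factor * self.gamma_right, self.label)


@dataclass(frozen=True)
class BiasSpec:
    """Bias voltage and its split across the junction; temperature is zero
    (step-function Fermi factors), so the current integral runs over the
    window [μ_R, μ_L]."""

    voltage: float = 0.1
    split: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.split <= 1.0:
            raise ValueError("split must lie in [0, 1]")

    def window(self, electrode: ElectrodePair) -> tuple[float, float]:
        mu = electrode.chemical_potential
        mu_l = mu + self.split * self.voltage
        mu_r = mu - (1.0 - self.split) * self.voltage
        return mu_r, mu_l


@dataclass
class CurrentTrace:
    """Per-site currents I_k in (2e/h)·eV units, 1-based site reporting."""

    currents: np.ndarray
    sequence: NucleotideSequence
    electrode: ElectrodePair
    bias: BiasSpec
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.currents)

    @property
    def log10_currents(self) -> np.ndarray:
        return np.log10(self.currents)

    @property
    def currents_ampere(self) -> np.ndarray:
        return self.currents * CURRENT_UNIT_AMPERE

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"# electrode: {self.electrode.label}",
                 f"# work_function_eV: {self.electrode.work_function!r}",
                 f"# gamma_eV: {self.electrode.gamma_left!r}\t{self.electrode.gamma_right!r}",
                 f"# bias_V: {self.bias.voltage!r}\t split: {self.bias.split!r}",
                 f"# alphabet_kind: {self.sequence.alphabet_kind}",
                 f"# current_unit: (2e/h)*eV = {CURRENT_UNIT_AMPERE!r} A"]
        lines += [f"# {k}: {v}" for k, v in self.provenance.items()]
        lines.append("site\tbase\tcurrent")
        for i, (b, c) in enumerate(zip(self.sequence.symbols, self.currents), start=1):
            lines.append(f"{i}\t{b}\t{float(c)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, alphabet_kind: str | None = None) -> "CurrentTrace":
        header: dict[str, str] = {}
        bases, currents = [], []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
            elif line and not line.startswith("site"):
                _, b, c = line.split("\t")
                bases.append(b)
                currents.append(float(c))
        kind = alphabet_kind or header.get("alphabet_kind", "DNA")
        gammas = header.get("gamma_eV", "0.001\t0.001").split("\t")
        bias_parts = header.get("bias_V", "0.1\t split: 0.5").split("\t")
        electrode = ElectrodePair(float(header.get("work_function_eV", 0.0)),
                                  float(gammas[0]), float(gammas[-1]),
                                  header.get("electrode", "custom"))
        bias = BiasSpec(float(bias_parts[0]),
                        float(bias_parts[-1].split(":")[-1]))
        seq = NucleotideSequence("".join(bases), kind, header.get("identifier", ""))
        return cls(np.array(currents), seq, electrode, bias, provenance=header)


# ---------------------------------------------------------------------------
# Green's functions

def self_energy(electrode: ElectrodePair, chain: ChainHamiltonian,
                k: int) -> tuple[np.ndarray, np.ndarray]:
    """WBA self-energies Σ_L, Σ_R for electrodes contacting site k (1-based).

    Each is −iΓ/2 on the m orbitals of site k and zero elsewhere; the
    escape-rate matrices are recovered as −2·Im Σ.
    """
    n, m = chain.n_sites, chain.m
    if not 1 <= k <= n:
        raise IndexError(f"site {k} out of range 1..{n}")
    sigmas = []
    for gamma in (electrode.gamma_left, electrode.gamma_right):
        sig = np.zeros((n * m, n * m), dtype=complex)
        sl = slice((k - 1) * m, k * m)
        sig[sl, sl] = -0.5j * gamma * np.eye(m)
        sigmas.append(sig)
    return sigmas[0], sigmas[1]


def green_function(chain: ChainHamiltonian, sigma_total: np.ndarray,
                   energy: float) -> np.ndarray:
    """Retarded Green's function by direct dense inversion (the contract)."""
    h = assemble_dense(chain)
    a = energy * np.eye(h.shape[0]) - h - sigma_total
    try:
        return np.linalg.inv(a)
    except np.linalg.LinAlgError as exc:  # measure-zero for complex Σ
        raise np.linalg.LinAlgError(
            f"singular (E−H−Σ) at E = {energy!r} eV") from exc


class ChainTransport:
    """Per-chain transport engine: one eigendecomposition of H_S, then
    low-rank electrode updates per contacted site and energy."""

    #: regularization (eV) for energies numerically at a chain eigenvalue
    _POLE_CLAMP = 1e-9

    def __init__(self, chain: ChainHamiltonian, electrode: ElectrodePair):
        self.chain = chain
        self.electrode = electrode
        h = assemble_dense(chain)
        self.eigenvalues, self._vectors = np.linalg.eigh(h)
        self.m = chain.m
        self.n_sites = chain.n_sites

    def _site_rows(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n_sites:
            raise IndexError(f"site {k} out of range 1..{self.n_sites}")
        return self._vectors[(k - 1) * self.m: k * self.m, :]  # m × nm

    def site_green_blocks(self, energies: np.ndarray, k: int) -> np.ndarray:
        """G_kk(E) for a batch of energies, shape (nE, m, m)."""
        energies = np.atleast_1d(np.asarray(energies, dtype=float))
        u = self._site_rows(k)
        delta = energies[:, None] - self.eigenvalues[None, :]
        small = np.abs(delta) < self._POLE_CLAMP
        if np.any(small):
            delta = np.where(small, np.where(delta >= 0, 1, -1) * self._POLE_CLAMP, delta)
        w = 1.0 / delta
        a = np.einsum("ak,ek,bk->eab", u, w, u.conj(), optimize=True)
        gamma_tot = self.electrode.gamma_left + self.electrode.gamma_right
        m_mat = np.eye(self.m) + 0.5j * gamma_tot * a
        # G_kk = A + A σ (1 − Aσ)⁻¹ A  with σ = −i Γ_tot/2 · 1
        correction = -0.5j * gamma_tot * (a @ np.linalg.solve(m_mat, a))
        return a + correction

    def transmission(self, energies: np.ndarray | float, k: int) -> np.ndarray:
        """T_k(E) = Tr[Γ_L G_kk Γ_R G_kk†] = Γ_L Γ_R ‖G_kk‖_F²."""
        g_kk = self.site_green_blocks(energies, k)
        t = (self.electrode.gamma_left * self.electrode.gamma_right
             * np.sum(np.abs(g_kk) ** 2, axis=(1, 2)))
        return t

    def current(self, k: int, bias: BiasSpec, rtol: float = 1e-6) -> float:
        """Zero-temperature current through base k in (2e/h)·eV units."""
        if bias.voltage == 0.0:
            return 0.0
        mu_r, mu_l = bias.window(self.electrode)
        lo, hi = min(mu_r, mu_l), max(mu_r, mu_l)
        sign = 1.0 if mu_l >= mu_r else -1.0
        gamma_tot = self.electrode.gamma_left + self.electrode.gamma_right
        margin = 10.0 * gamma_tot
        eigs = self.eigenvalues
        inside = eigs[(eigs > lo - margin) & (eigs < hi + margin)]
        points = [lo, hi]
        for e in inside:
            points.extend((e, e - margin, e + margin))
        breaks = np.unique(np.clip(np.array(points), lo, hi))
        value = _integrate_panels(lambda e: self.transmission(e, k), breaks, rtol)
        return sign * value

    def scan(self, bias: BiasSpec, rtol: float = 1e-6) -> CurrentTrace:
        """Currents through every base, electrodes contacting one site at a
        time."""
        currents = np.array([self.current(k, bias, rtol)
                             for k in range(1, self.n_sites + 1)])
        return CurrentTrace(currents, self.chain.sequence, self.electrode, bias)


# module-level operation wrappers --------------------------------------------

def transmission(chain: ChainHamiltonian, electrode: ElectrodePair,
                 k: int, energy: float | np.ndarray) -> np.ndarray | float:
    t = ChainTransport(chain, electrode).transmission(energy, k)
    return float(t[0]) if np.isscalar(energy) else t


def current(chain: ChainHamiltonian, electrode: ElectrodePair, k: int,
            bias: BiasSpec, rtol: float = 1e-6) -> float:
    return ChainTransport(chain, electrode).current(k, bias, rtol)


def scan(chain: ChainHamiltonian, electrode: ElectrodePair,
         bias: BiasSpec, rtol: float = 1e-6) -> CurrentTrace:
    return ChainTransport(chain, electrode).scan(bias, rtol)


# ---------------------------------------------------------------------------
# panel-adaptive Gauss–Legendre quadrature

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)

_MAX_DEPTH = 45


def _gl_batch(f, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """15-point Gauss–Legendre estimates of many intervals in one call."""
    half = 0.5 * (b - a)
    nodes = 0.5 * (a + b)[:, None] + half[:, None] * _GL_NODES[None, :]
    vals = np.asarray(f(nodes.ravel())).reshape(nodes.shape)
    return half * (vals @ _GL_WEIGHTS)


def _integrate_panels(f, breakpoints: np.ndarray, rtol: float) -> float:
    """Integrate a nonnegative transmission over [breaks[0], breaks[-1]].

    Bisection-adaptive on every panel, with all pending intervals of a
    refinement level evaluated in one vectorized call.  Gauss–Legendre
    nodes are interior, so panels bounded by chain eigenvalues are only
    ever evaluated off-resonance.
    """
    a = breakpoints[:-1].astype(float)
    b = breakpoints[1:].astype(float)
    keep = b > a
    a, b = a[keep], b[keep]
    if a.size == 0:
        return 0.0
    parent = _gl_batch(f, a, b)
    scale = max(float(np.sum(np.abs(parent))), 1e-300)
    total = 0.0
    for _ in range(_MAX_DEPTH):
        mid = 0.5 * (a + b)
        left = _gl_batch(f, a, mid)
        right = _gl_batch(f, mid, b)
        child = left + right
        err = np.abs(child - parent)
        # accept on local relative convergence, or once a panel's possible
        # error is negligible against the running total estimate
        done = err <= rtol * np.maximum(np.abs(child), 1e-3 * scale)
        total += float(np.sum(child[done]))
        if np.all(done):
            return total
        keep = ~done
        a = np.concatenate([a[keep], mid[keep]])
        b = np.concatenate([mid[keep], b[keep]])
        parent = np.concatenate([left[keep], right[keep]])
        scale = max(scale, total + float(np.sum(np.abs(parent))))
    raise QuadratureError(
        f"energy quadrature did not converge to rtol={rtol:g}; "
        f"{int(np.sum(~done))} panels still refining at depth {_MAX_DEPTH}")
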