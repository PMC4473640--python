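"""Non-orthogonal projection and the energy-dependent effective Hamiltonian.

A fragment system lives in a Hilbert space spanned by non-orthogonal
fragment MOs with metric S.  Splitting the basis into an active subset P
(the orbitals in the transport-active energy window) and the rest Q, the
oblique projectors onto P and Q are

    P̂ = Σ_{i∈P} |φ_i⟩ Σ_j [S⁻¹]_ij ⟨φ_j| ,   Q̂ likewise over i∈Q.

They are idempotent, mutually annihilating, complete (P̂+Q̂=1) and — because
the subspaces are non-orthogonal — non-Hermitian.  This module stores their
matrices in the bra-side (covariant) representation S·Π·S⁻¹, where Π is the
0/1 selector of the active columns: in that representation operator
composition is the plain matrix product, the four projector identities hold
entrywise, and the non-Hermiticity is visible as matrix asymmetry.

Eliminating Q from the projected Schrödinger equation gives the exact,
energy-dependent effective Hamiltonian on the active window (Schur
complement / Löwdin partitioning form):

    H_eff(E) = H_PP + (E·S_PQ − H_PQ) (E·S_QQ − H_QQ)⁻¹ (E·S_QP − H_QP)

equivalently, through the projected resolvent,

    H_eff(E) = E·S_PP + [G_PP(E)]⁻¹ ,   G(E) = (E·S − H)⁻¹ .

Fixed points of det(H_eff(E) − E·S_PP) = 0 reproduce the generalized
eigenvalues of the full (H, S) pencil; poles occur at the generalized
eigenvalues of (H_QQ, S_QQ).  Inside the active window the energy
dependence is weak, which justifies replacing H_eff(E) by its value at a
single anchor energy (the mean of the active-window level energies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import SingularEnergyError, SingularOverlapError
from .fragments import FullFragmentSystem

#: evaluation this close (eV) to a Q-pole raises SingularEnergyError
SINGULARITY_TOL = 1e-6

_COND_THRESHOLD = 1e12


@dataclass
class ProjectorPair:
    """Matrices of the oblique projectors P̂ and Q̂ (bra-side representation).

    Plain matrix products compose operators in this representation, so
    ``p_matrix @ p_matrix == p_matrix`` etc. hold entrywise; for a
    non-orthogonal overlap the matrices are not symmetric.
    """

    p_matrix: np.ndarray
    q_matrix: np.ndarray
    overlap: np.ndarray
    active_indices: tuple[int, ...]


def build_projectors(system: FullFragmentSystem) -> ProjectorPair:
    """Construct the P/Q projector pair of a full fragment system."""
    S = system.overlap
    eigvals = np.linalg.eigvalsh(S)
    if eigvals[0] <= 0:
        raise SingularOverlapError("overlap matrix is not positive definite")
    if eigvals[-1] / eigvals[0] > _COND_THRESHOLD:
        raise SingularOverlapError(
            f"overlap condition number {eigvals[-1] / eigvals[0]:.3g} exceeds "
            f"{_COND_THRESHOLD:.0e}")
    s_inv = np.linalg.inv(S)
    p_idx = list(system.active_indices)
    q_idx = list(system.inactive_indices)
    p = S[:, p_idx] @ s_inv[p_idx, :]
    q = S[:, q_idx] @ s_inv[q_idx, :]
    return ProjectorPair(p, q, S, system.active_indices)


class EffectiveHamiltonian:
    """Energy-dependent effective Hamiltonian on the active subspace.

    ``evaluate(E)`` uses the resolvent route E·S_PP + [G_PP(E)]⁻¹ and falls
    back to the (analytically identical) Schur-complement route at energies
    where E·S − H is exactly singular.  Output is symmetrized to suppress
    round-off asymmetry, since downstream eigensolvers assume Hermitian
    input.
    """

    def __init__(self, system: FullFragmentSystem):
        # validate overlap up front (raises SingularOverlapError)
        build_projectors(system)
        self.system = system
        p = list(system.active_indices)
        q = list(system.inactive_indices)
        H, S = system.hamiltonian, system.overlap
        self.h_pp = H[np.ix_(p, p)]
        self.h_pq = H[np.ix_(p, q)]
        self.h_qq = H[np.ix_(q, q)]
        self.s_pp = S[np.ix_(p, p)]
        self.s_pq = S[np.ix_(p, q)]
        self.s_qq = S[np.ix_(q, q)]
        self._p = p
        self._singularities: np.ndarray | None = None

    @property
    def overlap_pp(self) -> np.ndarray:
        return self.s_pp

    @property
    def singularities(self) -> np.ndarray:
        """Pole energies: generalized eigenvalues of (H_QQ, S_QQ), ascending."""
        if self._singularities is None:
            self._singularities = np.sort(
                scipy.linalg.eigh(self.h_qq, self.s_qq, eigvals_only=True))
        return self._singularities

    def _check_energy(self, energy: float) -> None:
        sing = self.singularities
        if sing.size and np.min(np.abs(sing - energy)) < SINGULARITY_TOL:
            nearest = sing[np.argmin(np.abs(sing - energy))]
            raise SingularEnergyError(
                f"E = {energy:.9f} eV lies within {SINGULARITY_TOL:g} eV of the "
                f"pole at {nearest:.9f} eV")

    def evaluate(self, energy: float) -> np.ndarray:
        """H_eff(E) by the resolvent route, symmetrized."""
        self._check_energy(energy)
        H, S = self.system.hamiltonian, self.system.overlap
        a = energy * S - H
        try:
            g_p_cols = np.linalg.solve(a, np.eye(self.system.size)[:, self._p])
            g_pp = g_p_cols[self._p, :]
            # with the resolvent G = (E·S − H)⁻¹ the block-inverse identity
            # gives H_eff = E·S_PP − [G_PP]⁻¹ (= the Schur-complement route)
            h_eff = energy * self.s_pp - np.linalg.inv(g_pp)
        except np.linalg.LinAlgError:
            # E numerically at a full-pencil eigenvalue: G blows up and
            # G_PP degenerates to (numerical) rank one; H_eff itself is
            # finite there, so use the stable Schur route
            return self.evaluate_schur(energy)
        return (h_eff + h_eff.conj().T) / 2.0

    def evaluate_schur(self, energy: float) -> np.ndarray:
        """H_eff(E) by the explicit Schur-complement route (independent check)."""
        self._check_energy(energy)
        b = energy * self.s_pq - self.h_pq
        g_qq = np.linalg.inv(energy * self.s_qq - self.h_qq)
        h_eff = self.h_pp + b @ g_qq @ b.conj().T
        return (h_eff + h_eff.conj().T) / 2.0

    def fixed_point_energies(self, window: tuple[float, float],
                             n_grid: int = 10_000) -> np.ndarray:
        """Solve det(H_eff(E) − E·S_PP) = 0 inside ``window``.

        Scan + bisection: the determinant is evaluated on a uniform grid and
        each sign change is refined with Brent's method.  Grid points that
        collide with a Q-pole are nudged off it.
        """
        from scipy.optimize import brentq

        def det_fn(e: float) -> float:
            return float(np.linalg.det(self.evaluate(e) - e * self.s_pp).real)

        lo, hi = window
        grid = np.linspace(lo, hi, n_grid)
        sing = self.singularities
        if sing.size:
            near = np.abs(grid[:, None] - sing[None, :]).min(axis=1) < 2 * SINGULARITY_TOL
            grid = grid[~near]
        vals = np.array([det_fn(e) for e in grid])
        roots = []
        sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
        for i in sign_change:
            roots.append(brentq(det_fn, grid[i], grid[i + 1], xtol=1e-12))
        return np.array(sorted(roots))


@dataclass(frozen=True)
class LinearizedHamiltonian:
    """Energy-independent reduction: H_eff evaluated at one anchor energy."""

    matrix: np.ndarray
    anchor_energy: float


def effective_hamiltonian(system: FullFragmentSystem) -> EffectiveHamiltonian:
    """Build the energy-dependent effective Hamiltonian of ``system``."""
    return EffectiveHamiltonian(system)


def q_singularities(system: FullFragmentSystem) -> np.ndarray:
    """Pole energies of H_eff: generalized eigenvalues of (H_QQ, S_QQ)."""
    return effective_hamiltonian(system).singularities


def linearize(eff: EffectiveHamiltonian,
              valence_energies: np.ndarray | list[float]) -> LinearizedHamiltonian:
    """Freeze H_eff at the mean of the supplied valence-orbital energies."""
    anchor = float(np.mean(np.asarray(valence_energies, dtype=float)))
    return LinearizedHamiltonian(eff.evaluate(anchor), anchor)
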