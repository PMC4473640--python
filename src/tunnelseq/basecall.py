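"""Base calling from a transverse-current trace.

Single-current calling assigns each site the base whose P1 density is
highest at the observed log-current.  Because the structural noise is
caused by the neighbours, the currents through adjacent bases are
correlated, and the joint P2/P3 densities carry information the P1 call
discards.  The iterative Bayesian refinement exploits this: starting from
the P1 sequence, each sweep re-maximizes every undecided site over the
joint density of its local current window with the neighbour identities
frozen to the previous guess,

    X̃_k^{(n)} = argmax_X  P_{… X …}(I window at k | neighbours from n−1) ,

and any site whose call agrees with the previous sweep is marked *certain*
and collapsed — it keeps its identity and only conditions its neighbours
from then on.  Sweeps repeat until no call changes (or a sweep cap).

Fidelity is the fraction of correctly called bases, f = (1/N) Σ_k
[X̃_k == X_k]; the complement is the error rate.  A site mask restricts
the sum (partial fidelity, e.g. over a homopolymer run).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import PDFLibrary
from .chain import NucleotideSequence
from .errors import CalibrationError
from .transport import CurrentTrace

MAX_SWEEPS = 10


@dataclass
class CallResult:
    """A called sequence with per-site diagnostics."""

    called: NucleotideSequence
    per_site_scores: np.ndarray
    certain_flags: np.ndarray
    refinement_order: int
    iteration_log: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.called)


@dataclass
class FidelityReport:
    """Fraction of matching sites plus a per-base confusion table."""

    fidelity: float
    n_sites: int
    mask: tuple[int, ...] | None
    per_base_confusion: pd.DataFrame

    @property
    def error_rate(self) -> float:
        return 1.0 - self.fidelity


def call_p1(trace: CurrentTrace, pdfs: PDFLibrary) -> CallResult:
    """Maximum-likelihood single-current calling (ties: alphabet order)."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    logs = trace.log10_currents
    alphabet = pdfs.alphabet
    scores = np.stack([pdfs.p1(b, logs) for b in alphabet])  # (4, n)
    best = np.argmax(scores, axis=0)  # argmax returns first max: alphabet order
    called = "".join(alphabet[i] for i in best)
    seq = NucleotideSequence(called, trace.sequence.alphabet_kind,
                             (trace.sequence.identifier or "trace") + "|called")
    return CallResult(seq, scores[best, np.arange(len(logs))],
                      np.zeros(len(logs), dtype=bool), 1)


def _window_score(pdfs: PDFLibrary, guess: list[str], logs: np.ndarray,
                  k: int, candidate: str, order: int) -> float:
    """Log conditional score of X_k = candidate given the other calls.

    With all other sites fixed, the joint density of the whole trace
    depends on X_k only through the order-``order`` windows that contain
    site k, so the score is the sum of those windows' log densities (a
    site away from the ends contributes ``order`` windows).  Sequences
    shorter than the window order fall back to the largest order that
    fits, down to the single-current density.
    """
    n = len(logs)
    g = list(guess)
    g[k] = candidate
    while order > 1:
        starts = range(max(0, k - order + 1), min(k, n - order) + 1)
        total = 0.0
        used = False
        for s in starts:
            bases = tuple(g[s:s + order])
            total += float(np.log(pdfs.density(bases, logs[None, s:s + order])[0]))
            used = True
        if used:
            return total
        order -= 1
    return float(np.log(pdfs.p1(candidate, logs[k])[0]))


def _sweep_to_convergence(pdfs: PDFLibrary, logs: np.ndarray, guess: list[str],
                          certain: np.ndarray, scores: np.ndarray, order: int,
                          log: list[int]) -> list[str]:
    alphabet = pdfs.alphabet
    prev = guess
    for _ in range(MAX_SWEEPS):
        new = prev.copy()
        for k in range(len(logs)):
            if certain[k]:
                continue
            cand = [_window_score(pdfs, prev, logs, k, x, order)
                    for x in alphabet]
            best = int(np.argmax(cand))
            new[k] = alphabet[best]
            scores[k] = cand[best]
        changes = sum(a != b for a, b in zip(new, prev))
        log.append(changes)
        certain |= np.array([a == b for a, b in zip(new, prev)])
        prev = new
        if changes == 0:
            break
    return prev


def refine(trace: CurrentTrace, pdfs: PDFLibrary, initial: CallResult,
           order: int = 3) -> CallResult:
    """Iterative joint-PDF refinement with the certainty/collapse rule.

    Improvement steps climb the order ladder: starting from the supplied
    (typically P1) call, the sequence is re-maximized under the pair
    densities, then — for ``order`` 3 — under the triple densities, each
    step sweeping left-to-right until no call changes.  A site whose call
    agrees with its previous value is marked certain and collapsed: it is
    never re-optimized, it only conditions its neighbours.  Certainty
    carries across ladder steps.
    """
    if order not in (2, 3):
        raise ValueError("refinement order must be 2 or 3")
    for o in range(2, order + 1):
        if o not in pdfs.orders:
            raise CalibrationError(f"PDF library lacks order {o}")
    logs = trace.log10_currents
    guess = list(initial.called.symbols)
    certain = initial.certain_flags.copy()
    scores = initial.per_site_scores.astype(float).copy()
    log: list[int] = []
    for o in range(2, order + 1):
        guess = _sweep_to_convergence(pdfs, logs, guess, certain, scores, o, log)
    seq = NucleotideSequence("".join(guess), trace.sequence.alphabet_kind,
                             (trace.sequence.identifier or "trace")
                             + f"|refined{order}")
    return CallResult(seq, scores, certain, order, log)


def fidelity(called: NucleotideSequence | str, truth: NucleotideSequence | str,
             mask: set[int] | None = None) -> FidelityReport:
    """Exact fraction of matching sites; ``mask`` holds 0-based indices."""
    called_s = called.symbols if isinstance(called, NucleotideSequence) else called
    truth_s = truth.symbols if isinstance(truth, NucleotideSequence) else truth
    if len(called_s) != len(truth_s):
        raise ValueError(f"length mismatch: {len(called_s)} vs {len(truth_s)}")
    sites = sorted(mask) if mask is not None else range(len(truth_s))
    if mask is not None and any(i < 0 or i >= len(truth_s) for i in mask):
        raise ValueError("mask index out of range")
    alphabet = sorted(set(truth_s) | set(called_s))
    confusion = pd.DataFrame(0, index=alphabet, columns=alphabet)
    matches = 0
    count = 0
    for i in sites:
        confusion.loc[truth_s[i], called_s[i]] += 1
        matches += truth_s[i] == called_s[i]
        count += 1
    if count == 0:
        raise ValueError("empty mask")
    return FidelityReport(matches / count, count,
                          tuple(sites) if mask is not None else None, confusion)


def load_bed_mask(path: str | Path, sequence_length: int) -> set[int]:
    """Site mask from a BED file (0-based, half-open intervals)."""
    bed = pd.read_csv(path, sep="\t", comment="#", header=None,
                      usecols=[0, 1, 2], names=["chrom", "start", "end"])
    mask: set[int] = set()
    for _, row in bed.iterrows():
        start, end = int(row["start"]), int(row["end"])
        if start < 0 or end > sequence_length or start >= end:
            raise ValueError(f"invalid BED interval [{start}, {end}) for "
                             f"sequence of length {sequence_length}")
        mask.update(range(start, end))
    return mask
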