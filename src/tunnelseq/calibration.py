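"""Non-parametric current-PDF calibration.

Training chains with known composition are scanned to collect the current
through every base, every adjacent pair, and every adjacent triple.  Since
reading direction is immaterial for a symmetric junction, ordered tuples
are pooled with their reversals: over a 4-letter alphabet this yields 4
single, 10 pair and 40 triple classes.  Per class, a fine histogram of
log₁₀ currents is smoothed with a Gaussian kernel (Silverman's rule per
dimension), floored at a small positive constant, and normalized to unit
integral — the P1/P2/P3 density library used by the base caller.

The default protocol generates 150 random 200-nt chains (uniform base
composition), 30 of which carry one inserted poly(X) homopolymer run of
length 3–20 so that strongly self-hybridized repeats are represented in
the training statistics; this yields exactly 30,000 single-current
observations.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .chain import NucleotideSequence
from .errors import CalibrationError
from .fragments import DNA_ALPHABET, RNA_ALPHABET
from .transport import CurrentTrace

PDF_SCHEMA = "tunnelseq-pdfs-1"


@dataclass(frozen=True)
class CalibrationConfig:
    """Training-set protocol (defaults are the full study conditions)."""

    n_sequences: int = 150
    sequence_length: int = 200
    n_polyx_sequences: int = 30
    polyx_length_range: tuple[int, int] = (3, 20)
    seed: int = 0
    alphabet_kind: str = "DNA"

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.sequence_length < 1:
            raise CalibrationError("sequence counts and lengths must be positive")
        if self.n_polyx_sequences > self.n_sequences:
            raise CalibrationError("n_polyx_sequences exceeds n_sequences")
        lo, hi = self.polyx_length_range
        if lo < 1 or hi < lo:
            raise CalibrationError("invalid polyx_length_range")
        if hi > self.sequence_length:
            raise CalibrationError("poly(X) run longer than the sequence")


def generate_training_sequences(config: CalibrationConfig) -> list[NucleotideSequence]:
    """Random uniform-composition chains, some with one poly(X) run.

    The poly(X) run replaces a slice of the random sequence (lengths stay
    fixed), its base cycles through the alphabet across the flagged
    sequences, its length is uniform in ``polyx_length_range`` and its
    position uniform along the chain.  Deterministic for a fixed seed.
    """
    alphabet = DNA_ALPHABET if config.alphabet_kind == "DNA" else RNA_ALPHABET
    rng = np.random.default_rng(config.seed)
    flagged = set(rng.choice(config.n_sequences, size=config.n_polyx_sequences,
                             replace=False).tolist())
    sequences = []
    cycle = 0
    for i in range(config.n_sequences):
        symbols = rng.choice(list(alphabet), size=config.sequence_length)
        name = f"train{i + 1}"
        if i in flagged:
            lo, hi = config.polyx_length_range
            run = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, config.sequence_length - run + 1))
            base = alphabet[cycle % len(alphabet)]
            cycle += 1
            symbols[start:start + run] = base
            name += f"|poly{base}x{run}@{start}"
        sequences.append(NucleotideSequence("".join(symbols),
                                            config.alphabet_kind, name))
    return sequences


def canonical_class(bases: tuple[str, ...]) -> tuple[tuple[str, ...], bool]:
    """Reversal-symmetry class representative; second value: was flipped."""
    rev = bases[::-1]
    if rev < bases:
        return rev, True
    return bases, False


def count_independent_pdfs(order: int, alphabet_size: int = 4) -> int:
    """Number of ordered base tuples up to reading-direction reversal."""
    if order not in (1, 2, 3):
        raise ValueError(f"unsupported order {order}")
    symbols = range(alphabet_size)
    classes = {min(t, t[::-1]) for t in itertools.product(symbols, repeat=order)}
    return len(classes)


@dataclass
class ObservationStore:
    """Raw log₁₀-current observations pooled by symmetry class.

    Every pair/triple observation enters its class in canonical
    orientation; palindromic classes (e.g. AA, GAG) additionally receive
    the mirrored reading so their densities are reversal-symmetric.
    """

    alphabet: tuple[str, ...]
    singles: dict[str, list[float]] = field(default_factory=dict)
    pairs: dict[tuple[str, str], list[tuple[float, float]]] = field(default_factory=dict)
    triples: dict[tuple[str, str, str], list[tuple[float, float, float]]] = field(default_factory=dict)
    n_pair_readings: int = 0
    n_triple_readings: int = 0

    @property
    def n_singles(self) -> int:
        return sum(len(v) for v in self.singles.values())

    def _add_tuple(self, store: dict, bases: tuple[str, ...],
                   values: tuple[float, ...]) -> None:
        key, flipped = canonical_class(bases)
        vals = values[::-1] if flipped else values
        bucket = store.setdefault(key, [])
        bucket.append(vals)
        if key == key[::-1]:
            # palindromic class: both reading directions are stored so the
            # density is exactly reversal-symmetric
            bucket.append(vals[::-1])


def collect_observations(sequences: list[NucleotideSequence],
                         traces: list[CurrentTrace]) -> ObservationStore:
    """Pool per-site, per-pair and per-triple log-current observations."""
    if len(sequences) != len(traces):
        raise CalibrationError("one trace per sequence required")
    alphabet = sequences[0].alphabet()
    store = ObservationStore(alphabet)
    for seq, trace in zip(sequences, traces):
        if len(seq) != len(trace):
            raise CalibrationError(
                f"length mismatch for {seq.identifier!r}: "
                f"{len(seq)} bases vs {len(trace)} currents")
        logs = trace.log10_currents
        for i, base in enumerate(seq.symbols):
            store.singles.setdefault(base, []).append(float(logs[i]))
        for i in range(len(seq) - 1):
            store._add_tuple(store.pairs, (seq[i], seq[i + 1]),
                             (float(logs[i]), float(logs[i + 1])))
            store.n_pair_readings += 1
        for i in range(len(seq) - 2):
            store._add_tuple(store.triples, (seq[i], seq[i + 1], seq[i + 2]),
                             (float(logs[i]), float(logs[i + 1]), float(logs[i + 2])))
            store.n_triple_readings += 1
    return store


@dataclass(frozen=True)
class GridSpec:
    """Histogram/smoothing controls for the density library.

    Bins per dimension shrink with order to keep the joint grids tractable.
    The Gaussian smoothing bandwidth per dimension is
    ``bandwidth_factor``·σ·n^(−1/5), clamped below at half a bin so sparse
    classes never collapse onto isolated histogram spikes.  The default
    factor is half of Silverman's 1.06: these densities are mixtures of
    narrow neighbour-context clusters, and the unimodal Silverman rule
    oversmooths exactly the between-base structure the caller relies on.
    """

    bins_by_order: tuple[int, int, int] = (200, 64, 64)
    pad_decades: float = 0.3
    floor: float = 1e-12
    min_count: int = 25
    bandwidth_factor: float = 0.53
    min_sigma_bins: float = 0.5


class PDFLibrary:
    """Smoothed P1/P2/P3 densities over shared log₁₀-current grids."""

    def __init__(self, alphabet: tuple[str, ...], edges: dict[int, np.ndarray],
                 densities: dict[int, dict[tuple[str, ...], np.ndarray]],
                 floor: float, meta: dict | None = None):
        self.alphabet = tuple(alphabet)
        self.edges = edges            # order -> 1-D bin edges (shared per axis)
        self.densities = densities    # order -> class tuple -> grid array
        self.floor = floor
        self.meta = meta or {}
        self._interp: dict[tuple[int, tuple[str, ...]], RegularGridInterpolator] = {}

    @property
    def orders(self) -> tuple[int, ...]:
        return tuple(sorted(self.densities))

    def centers(self, order: int) -> np.ndarray:
        e = self.edges[order]
        return 0.5 * (e[:-1] + e[1:])

    def _interpolator(self, order: int, key: tuple[str, ...]) -> RegularGridInterpolator:
        cached = self._interp.get((order, key))
        if cached is None:
            c = self.centers(order)
            cached = RegularGridInterpolator(
                (c,) * order, self.densities[order][key],
                bounds_error=False, fill_value=self.floor)
            self._interp[(order, key)] = cached
        return cached

    def density(self, bases: tuple[str, ...], log_currents) -> np.ndarray:
        """Joint density of the class containing ``bases``, evaluated with
        the arguments ordered to match the class's canonical orientation."""
        order = len(bases)
        key, flipped = canonical_class(tuple(bases))
        if key not in self.densities.get(order, {}):
            raise CalibrationError(f"library has no order-{order} class {key}")
        pts = np.atleast_2d(np.asarray(log_currents, dtype=float))
        if flipped:
            pts = pts[:, ::-1]
        return np.maximum(self._interpolator(order, key)(pts), self.floor)

    def p1(self, base: str, log_current) -> np.ndarray:
        x = np.atleast_1d(np.asarray(log_current, dtype=float))
        return self.density((base,), x[:, None])

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {}
        header = {"schema": PDF_SCHEMA, "alphabet": list(self.alphabet),
                  "floor": self.floor, "meta": self.meta,
                  "classes": {str(o): ["".join(k) for k in sorted(d)]
                              for o, d in self.densities.items()}}
        for order, d in self.densities.items():
            arrays[f"edges{order}"] = self.edges[order]
            for key, grid in d.items():
                arrays[f"d{order}_{''.join(key)}"] = grid
        np.savez_compressed(path, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PDFLibrary":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["header"]))
            if header.get("schema") != PDF_SCHEMA:
                raise CalibrationError(
                    f"unsupported PDF container schema {header.get('schema')!r}")
            edges, densities = {}, {}
            for order_str, keys in header["classes"].items():
                order = int(order_str)
                edges[order] = data[f"edges{order}"]
                densities[order] = {tuple(k): data[f"d{order}_{k}"] for k in keys}
        return cls(tuple(header["alphabet"]), edges, densities,
                   float(header["floor"]), header.get("meta"))


def _smooth_histogram(points: np.ndarray, edges: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Histogram on the shared grid, Gaussian-smoothed, floored, normalized."""
    d = points.shape[1]
    hist, _ = np.histogramdd(points, bins=[edges] * d)
    width = edges[1] - edges[0]
    n = len(points)
    sigmas = []
    for axis in range(d):
        sd = float(np.std(points[:, axis]))
        bw = spec.bandwidth_factor * sd * n ** (-0.2)
        sigmas.append(max(bw / width, spec.min_sigma_bins))
    smoothed = gaussian_filter(hist, sigma=sigmas, mode="constant")
    smoothed = np.maximum(smoothed, spec.floor)
    return smoothed / (smoothed.sum() * width ** d)


def build_pdfs(store: ObservationStore, spec: GridSpec | None = None,
               orders: tuple[int, ...] = (1, 2, 3)) -> PDFLibrary:
    """Build the smoothed density library from pooled observations.

    Every class of a requested order must hold at least ``spec.min_count``
    observations; under-populated classes are reported together.
    Deterministic given the store and grid spec.
    """
    spec = spec or GridSpec()
    all_logs = np.concatenate([np.asarray(v) for v in store.singles.values()])
    lo = float(all_logs.min()) - spec.pad_decades
    hi = float(all_logs.max()) + spec.pad_decades

    raw = {1: {(b,): np.asarray(v, dtype=float)[:, None]
               for b, v in store.singles.items()},
           2: {k: np.asarray(v, dtype=float) for k, v in store.pairs.items()},
           3: {k: np.asarray(v, dtype=float) for k, v in store.triples.items()}}

    starved = [(k, len(v)) for order in orders
               for k, v in raw[order].items() if len(v) < spec.min_count]
    if starved:
        detail = ", ".join(f"{''.join(k)}:{n}" for k, n in sorted(starved))
        raise CalibrationError(
            f"under-populated PDF classes (need >= {spec.min_count}): {detail}")

    edges, densities = {}, {}
    for order in orders:
        bins = spec.bins_by_order[order - 1]
        edges[order] = np.linspace(lo, hi, bins + 1)
        densities[order] = {k: _smooth_histogram(v, edges[order], spec)
                            for k, v in raw[order].items()}
    meta = {"n_singles": store.n_singles,
            "bins_by_order": list(spec.bins_by_order)}
    return PDFLibrary(store.alphabet, edges, densities, spec.floor, meta)


# ---------------------------------------------------------------------------
# distribution diagnostics

def standardized_overlap(singles: dict[str, np.ndarray], bins: int = 200) -> float:
    """Mean pairwise overlap coefficient of the standardized P1 densities.

    Log-currents are pooled-standardized (preserving between-base
    separation while removing the global scale), histogrammed on a common
    grid, lightly smoothed and compared via ∫ min(p, q).  Values near 0
    mean well-separated per-base distributions; near 1, indistinguishable.
    """
    samples = {b: np.asarray(v, dtype=float) for b, v in singles.items()}
    pooled = np.concatenate(list(samples.values()))
    mu, sd = pooled.mean(), pooled.std() or 1.0
    z = {b: (v - mu) / sd for b, v in samples.items()}
    zlo = min(v.min() for v in z.values()) - 0.25
    zhi = max(v.max() for v in z.values()) + 0.25
    edges = np.linspace(zlo, zhi, bins + 1)
    width = edges[1] - edges[0]
    dens = {}
    for b, v in z.items():
        hist, _ = np.histogram(v, bins=edges)
        bw = 1.06 * v.std() * len(v) ** (-0.2)
        smoothed = gaussian_filter(hist.astype(float),
                                   sigma=max(bw / width, 0.5), mode="constant")
        dens[b] = smoothed / (smoothed.sum() * width)
    bases = sorted(dens)
    overlaps = [np.minimum(dens[a], dens[b]).sum() * width
                for i, a in enumerate(bases) for b in bases[i + 1:]]
    return float(np.mean(overlaps))
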