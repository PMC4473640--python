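import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tunnelseq import errors
from tunnelseq.calibration import (CalibrationConfig, GridSpec, PDFLibrary,
                                   build_pdfs, canonical_class,
                                   collect_observations, count_independent_pdfs,
                                   generate_training_sequences,
                                   standardized_overlap)
from tunnelseq.chain import NucleotideSequence, build_chain
from tunnelseq.transport import BiasSpec, ChainTransport, CurrentTrace, ElectrodePair


def fake_trace(seq: NucleotideSequence, currents) -> CurrentTrace:
    return CurrentTrace(np.asarray(currents, dtype=float), seq,
                        ElectrodePair(4.0), BiasSpec(0.1))


def synthetic_store(n_seqs=60, length=40, seed=0, sep=1.0, noise=0.1):
    """Observation store from a toy current model: log I = mu(base) + noise.

    Keeps calibration tests independent of the transport stack.
    """
    rng = np.random.default_rng(seed)
    mu = {"A": 0.0, "C": -sep, "G": sep, "T": -2 * sep}
    seqs, traces = [], []
    for i in range(n_seqs):
        symbols = "".join(rng.choice(list("ACGT"), length))
        seq = NucleotideSequence(symbols, identifier=f"s{i}")
        logs = np.array([mu[b] for b in symbols]) + noise * rng.standard_normal(length)
        seqs.append(seq)
        traces.append(fake_trace(seq, 10.0 ** logs))
    return collect_observations(seqs, traces)


class TestTrainingSequences:
    def test_protocol_counts_full_scale(self):
        """The full calibration protocol yields 150 x 200 nt with exactly 30
        poly(X)-carrying chains."""
        seqs = generate_training_sequences(CalibrationConfig(seed=11))
        assert len(seqs) == 150
        assert all(len(s) == 200 for s in seqs)
        assert sum("poly" in s.identifier for s in seqs) == 30
        assert sum(len(s) for s in seqs) == 30_000

    def test_determinism(self):
        cfg = CalibrationConfig(10, 50, 3, seed=7)
        a = generate_training_sequences(cfg)
        b = generate_training_sequences(cfg)
        assert [s.symbols for s in a] == [s.symbols for s in b]

    def test_polyx_runs_present_and_cycling(self):
        cfg = CalibrationConfig(12, 60, 8, polyx_length_range=(5, 10), seed=3)
        seqs = generate_training_sequences(cfg)
        flagged = [s for s in seqs if "poly" in s.identifier]
        assert len(flagged) == 8
        bases = [s.identifier.split("poly")[1][0] for s in flagged]
        assert set(bases) == {"A", "C", "G", "T"}
        for s in flagged:
            tag = s.identifier.split("poly")[1]
            base, rest = tag[0], tag[1:]
            run = int(rest.split("@")[0].lstrip("x"))
            assert base * run in s.symbols

    def test_uniform_composition_binomial_bound(self):
        """Base frequencies within 3 sigma of 1/4 under the binomial model."""
        seqs = generate_training_sequences(CalibrationConfig(
            n_polyx_sequences=0, seed=5))
        symbols = "".join(s.symbols for s in seqs)
        n = len(symbols)
        sigma = np.sqrt(0.25 * 0.75 / n)
        for b in "ACGT":
            assert abs(symbols.count(b) / n - 0.25) < 3 * sigma

    def test_invalid_configs(self):
        with pytest.raises(errors.CalibrationError):
            CalibrationConfig(n_sequences=5, n_polyx_sequences=6)
        with pytest.raises(errors.CalibrationError):
            CalibrationConfig(sequence_length=10, polyx_length_range=(3, 20))


class TestCounting:
    @pytest.mark.parametrize("order,expected", [(1, 4), (2, 10), (3, 40)])
    def test_four_letter_class_counts(self, order, expected):
        assert count_independent_pdfs(order) == expected

    def test_single_letter_alphabet(self):
        assert count_independent_pdfs(2, alphabet_size=1) == 1

    @given(st.integers(1, 3), st.integers(1, 5))
    @settings(max_examples=15, deadline=None)
    def test_closed_form(self, order, a):
        """Enumeration matches (a^n + a^ceil(n/2)) / 2 reversal classes."""
        expected = (a ** order + a ** -(-order // 2)) // 2
        assert count_independent_pdfs(order, a) == expected

    def test_unsupported_order(self):
        with pytest.raises(ValueError):
            count_independent_pdfs(4)


class TestCollectObservations:
    def test_tuple_counting_small(self):
        seq = NucleotideSequence("GAT")
        store = collect_observations([seq], [fake_trace(seq, [1e-9, 1e-8, 1e-7])])
        assert store.n_singles == 3
        assert sum(len(v) for v in store.pairs.values()) == 2
        assert sum(len(v) for v in store.triples.values()) == 1

    def test_reversed_pair_lands_in_same_class_with_swapped_reading(self):
        s1 = NucleotideSequence("GA")
        s2 = NucleotideSequence("AG")
        store = collect_observations([s1, s2],
                                     [fake_trace(s1, [1e-9, 1e-8]),
                                      fake_trace(s2, [1e-8, 1e-9])])
        assert list(store.pairs) == [("A", "G")]
        obs = store.pairs[("A", "G")]
        assert len(obs) == 2
        assert obs[0] == obs[1]  # same physical reading, canonical order

    def test_palindromic_class_gets_mirrored_reading(self):
        seq = NucleotideSequence("AA")
        store = collect_observations([seq], [fake_trace(seq, [1e-9, 1e-8])])
        obs = store.pairs[("A", "A")]
        assert len(obs) == 2
        assert obs[0] == obs[1][::-1]

    def test_length_mismatch_rejected(self):
        seq = NucleotideSequence("GAT")
        with pytest.raises(errors.CalibrationError):
            collect_observations([seq], [fake_trace(NucleotideSequence("GA"),
                                                    [1e-9, 1e-8])])

    def test_canonical_class_involution(self):
        for bases in [("G", "A"), ("A", "G"), ("A", "A"), ("G", "A", "T")]:
            key, _ = canonical_class(bases)
            assert canonical_class(key)[0] == key
            assert key <= key[::-1]


class TestBuildPdfs:
    def test_every_density_normalized_and_floored(self):
        lib = build_pdfs(synthetic_store(), GridSpec(bins_by_order=(100, 40, 24)))
        for order in (1, 2, 3):
            edges = lib.edges[order]
            cell = (edges[1] - edges[0]) ** order
            for grid in lib.densities[order].values():
                assert grid.sum() * cell == pytest.approx(1.0, abs=1e-6)
                assert grid.min() > 0

    def test_delta_limit_single_peak(self):
        seq = NucleotideSequence("G" * 30, identifier="g")
        store = collect_observations([seq], [fake_trace(seq, [1e-8] * 30)])
        lib = build_pdfs(store, GridSpec(min_count=10), orders=(1,))
        dens = lib.densities[1][("G",)]
        centers = lib.centers(1)
        peak = centers[np.argmax(dens)]
        assert abs(peak - (-8.0)) < 0.1
        width = lib.edges[1][1] - lib.edges[1][0]
        assert dens.sum() * width == pytest.approx(1.0, abs=1e-6)

    def test_determinism(self):
        a = build_pdfs(synthetic_store())
        b = build_pdfs(synthetic_store())
        for order in (1, 2, 3):
            for k in a.densities[order]:
                assert np.array_equal(a.densities[order][k], b.densities[order][k])

    def test_underpopulated_class_error_lists_classes(self):
        store = synthetic_store(n_seqs=2, length=10)
        with pytest.raises(errors.CalibrationError, match="under-populated"):
            build_pdfs(store)

    def test_pair_marginal_matches_single_mixture(self):
        """Marginalizing a pair density over its second axis reproduces the
        mixture of the constituent singles (computed from raw observations)."""
        store = synthetic_store(n_seqs=100, length=60)
        lib = build_pdfs(store, GridSpec(bins_by_order=(120, 120, 24)),
                         orders=(1, 2))
        edges = lib.edges[2]
        width = edges[1] - edges[0]
        key = ("A", "G")
        marginal = lib.densities[2][key].sum(axis=1) * width
        obs_first = np.asarray(store.pairs[key])[:, 0]
        hist, _ = np.histogram(obs_first, bins=edges, density=True)
        # total-variation distance below the smoothing tolerance
        tv = 0.5 * np.sum(np.abs(marginal - hist)) * width
        assert tv < 0.15

    def test_save_load_roundtrip(self, tmp_path):
        lib = build_pdfs(synthetic_store(), GridSpec(bins_by_order=(100, 40, 24)))
        path = tmp_path / "pdfs.npz"
        lib.save(path)
        back = PDFLibrary.load(path)
        assert back.alphabet == lib.alphabet
        for order in (1, 2, 3):
            assert np.array_equal(back.edges[order], lib.edges[order])
            for k in lib.densities[order]:
                assert np.array_equal(back.densities[order][k],
                                      lib.densities[order][k])
        x = np.array([[0.1, -0.9]])
        assert back.density(("G", "A"), x) == lib.density(("G", "A"), x)


@pytest.fixture(scope="module")
def regime_traces(dna_params):
    rng = np.random.default_rng(21)
    seqs = [NucleotideSequence("".join(rng.choice(list("ACGT"), 40)),
                               identifier=f"r{i}") for i in range(6)]
    out = {}
    for label in ("Al", "Au"):
        el = ElectrodePair.preset(label)
        traces = [ChainTransport(build_chain(s, dna_params), el)
                  .scan(BiasSpec(0.1)) for s in seqs]
        out[label] = (seqs, traces)
    return out


class TestRegimeProperties:
    def test_tunneling_median_order_follows_homos(self, regime_traces):
        seqs, traces = regime_traces["Al"]
        store = collect_observations(seqs, traces)
        med = {b: np.median(store.singles[b]) for b in "AGT"}
        assert med["G"] > med["A"] > med["T"]

    def test_resonant_overlap_exceeds_tunneling(self, regime_traces):
        overlaps = {}
        for label in ("Al", "Au"):
            seqs, traces = regime_traces[label]
            store = collect_observations(seqs, traces)
            overlaps[label] = standardized_overlap(
                {b: np.asarray(v) for b, v in store.singles.items()})
        assert overlaps["Au"] > overlaps["Al"]


class TestStandardizedOverlap:
    def test_separated_vs_identical(self):
        rng = np.random.default_rng(4)
        far = {b: rng.standard_normal(400) + 10 * i
               for i, b in enumerate("ACGT")}
        same = {b: rng.standard_normal(400) for b in "ACGT"}
        assert standardized_overlap(far) < 0.05
        assert standardized_overlap(same) > 0.7
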