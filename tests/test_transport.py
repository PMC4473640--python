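import numpy as np
import pytest
import scipy.constants

from tunnelseq.chain import NucleotideSequence, build_chain
from tunnelseq.transport import (CURRENT_UNIT_AMPERE, BiasSpec, ChainTransport,
                                 CurrentTrace, ElectrodePair, green_function,
                                 self_energy)

from conftest import make_m1_params, single_site_chain

GAMMA = 1e-3


def electrodes_at(mu: float, gl: float = GAMMA, gr: float = GAMMA) -> ElectrodePair:
    return ElectrodePair(-mu, gl, gr, "custom")


def test_current_unit_constant_matches_codata():
    expected = 2 * scipy.constants.e / scipy.constants.h * scipy.constants.e
    assert CURRENT_UNIT_AMPERE == pytest.approx(expected, rel=1e-6)


class TestSelfEnergy:
    def test_wba_block_structure(self, dna_params):
        chain = build_chain(NucleotideSequence("ACG"), dna_params)
        sl, sr = self_energy(ElectrodePair.preset("Al"), chain, 2)
        m = chain.m
        block = sl[m:2 * m, m:2 * m]
        assert np.allclose(block, -0.5j * GAMMA * np.eye(m))
        sl_zeroed = sl.copy()
        sl_zeroed[m:2 * m, m:2 * m] = 0
        assert np.all(sl_zeroed == 0)
        # escape-rate matrix recovered and positive semidefinite
        gamma_mat = -2 * sl.imag
        assert np.allclose(gamma_mat[m:2 * m, m:2 * m], GAMMA * np.eye(m))
        assert np.linalg.eigvalsh(gamma_mat).min() >= 0

    def test_site_out_of_range(self, dna_params):
        chain = build_chain(NucleotideSequence("ACG"), dna_params)
        with pytest.raises(IndexError):
            self_energy(ElectrodePair.preset("Al"), chain, 4)


class TestGreenFunction:
    def test_single_level_scalar_closed_form(self):
        chain = single_site_chain(-5.5)
        el = electrodes_at(-5.5)
        sl, sr = self_energy(el, chain, 1)
        for e in (-5.6, -5.5, -5.4):
            g = green_function(chain, sl + sr, e)
            expected = 1.0 / (e - (-5.5) + 1j * GAMMA)
            assert g[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_uncoupled_poles_at_eigenvalues(self, dna_params):
        chain = build_chain(NucleotideSequence("AC"), dna_params)
        h = np.linalg.eigvalsh(
            np.block([[chain.onsite_blocks[0], chain.hopping_blocks[0]],
                      [chain.hopping_blocks[0].T, chain.onsite_blocks[1]]]))
        zero_sigma = np.zeros((10, 10), dtype=complex)
        norms = [np.linalg.norm(green_function(chain, zero_sigma, h[0] + d))
                 for d in (1e-2, 1e-4, 1e-6)]
        assert norms[0] < norms[1] < norms[2]

    @pytest.mark.parametrize("seed", range(5))
    def test_low_rank_route_equals_dense_inversion(self, dna_params, seed):
        rng = np.random.default_rng(seed)
        seq = NucleotideSequence("".join(rng.choice(list("ACGT"), 4)))
        chain = build_chain(seq, dna_params)
        el = ElectrodePair.preset("Al")
        engine = ChainTransport(chain, el)
        m = chain.m
        for k in (1, 3):
            sl, sr = self_energy(el, chain, k)
            for e in rng.uniform(-7.0, -4.0, size=3):
                dense = green_function(chain, sl + sr, e)
                block = dense[(k - 1) * m:k * m, (k - 1) * m:k * m]
                fast = engine.site_green_blocks(np.array([e]), k)[0]
                assert np.max(np.abs(fast - block)) <= 1e-8 * np.max(np.abs(block))


class TestTransmission:
    def test_breit_wigner_peak_and_profile(self):
        chain = single_site_chain(-5.5)
        engine = ChainTransport(chain, electrodes_at(-5.5))
        assert engine.transmission(-5.5, 1)[0] == pytest.approx(1.0, rel=1e-10)
        for e in (-5.502, -5.49):
            expected = GAMMA ** 2 / ((e + 5.5) ** 2 + GAMMA ** 2)
            assert engine.transmission(e, 1)[0] == pytest.approx(expected, rel=1e-9)

    def test_far_tail_gamma_squared_scaling(self):
        chain = single_site_chain(-5.5)
        e_far = -4.0
        t1 = ChainTransport(chain, electrodes_at(-5.5)).transmission(e_far, 1)[0]
        t2 = ChainTransport(chain, electrodes_at(-5.5, GAMMA / 2,
                                                 GAMMA / 2)).transmission(e_far, 1)[0]
        assert t1 / t2 == pytest.approx(4.0, rel=1e-4)

    def test_bounds_many_probes(self, dna_params):
        """0 <= T(E) <= m over a dense random probe set."""
        rng = np.random.default_rng(9)
        seq = NucleotideSequence("".join(rng.choice(list("ACGT"), 8)))
        engine = ChainTransport(build_chain(seq, dna_params),
                                ElectrodePair.preset("Au"))
        energies = rng.uniform(-8.0, -1.0, size=10_000)
        for k in (1, 4, 8):
            t = engine.transmission(energies, k)
            assert np.all(t >= 0)
            assert np.all(t <= dna_params.m + 1e-9)


class TestCurrent:
    def test_zero_bias_zero_current(self):
        engine = ChainTransport(single_site_chain(-5.5), electrodes_at(-5.5))
        assert engine.current(1, BiasSpec(0.0)) == 0.0

    def test_wide_window_lorentzian_integral(self):
        """Window >> Γ around a single level: I -> 2πΓ_LΓ_R/(Γ_L+Γ_R)."""
        engine = ChainTransport(single_site_chain(-5.5), electrodes_at(-5.5))
        current = engine.current(1, BiasSpec(20.0), rtol=1e-7)
        assert current == pytest.approx(np.pi * GAMMA, rel=1e-4)

    def test_monotone_in_positive_bias(self):
        engine = ChainTransport(single_site_chain(-5.5), electrodes_at(-5.3))
        values = [engine.current(1, BiasSpec(v)) for v in (0.0, 0.1, 0.5, 1.0)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert all(v >= 0 for v in values)

    def test_decoupled_electrode_gives_zero(self):
        engine = ChainTransport(single_site_chain(-5.5),
                                ElectrodePair(5.5, 0.0, GAMMA, "custom"))
        assert engine.current(1, BiasSpec(0.4)) == pytest.approx(0.0, abs=1e-30)


class TestScan:
    def test_interior_translational_symmetry(self, dna_params):
        trace = ChainTransport(build_chain(NucleotideSequence("A" * 25), dna_params),
                               ElectrodePair.preset("Al")).scan(BiasSpec(0.1),
                                                                rtol=1e-8)
        # mirror symmetry of a finite homopolymer is exact
        assert np.allclose(trace.currents, trace.currents[::-1], rtol=1e-7)
        # deep interior sites have converged to the translationally
        # invariant bulk value (end effects decay with distance)
        interior = trace.currents[10:15]
        assert np.max(np.abs(interior - interior.mean())) <= 1e-6 * interior.mean()

    def test_length_one_scan_equals_current(self, m1_params):
        chain = build_chain(NucleotideSequence("G"), m1_params)
        engine = ChainTransport(chain, ElectrodePair.preset("Al"))
        trace = engine.scan(BiasSpec(0.1))
        assert trace.currents[0] == engine.current(1, BiasSpec(0.1))

    def test_reversed_sequence_reverses_trace(self, dna_params):
        seq = NucleotideSequence("AGGTCC")
        el = ElectrodePair.preset("Al")
        fwd = ChainTransport(build_chain(seq, dna_params), el).scan(BiasSpec(0.1),
                                                                    rtol=1e-8)
        rev = ChainTransport(build_chain(seq.reversed(), dna_params),
                             el).scan(BiasSpec(0.1), rtol=1e-8)
        assert np.allclose(fwd.currents, rev.currents[::-1], rtol=1e-6)

    def test_tsv_roundtrip(self, tmp_path, dna_params):
        seq = NucleotideSequence("ACGT", identifier="t")
        trace = ChainTransport(build_chain(seq, dna_params),
                               ElectrodePair.preset("Al")).scan(BiasSpec(0.1))
        path = tmp_path / "trace.tsv"
        trace.provenance = {"identifier": "t"}
        trace.to_tsv(path)
        back = CurrentTrace.from_tsv(path)
        assert np.array_equal(back.currents, trace.currents)
        assert back.sequence.symbols == "ACGT"
        assert back.electrode.work_function == trace.electrode.work_function
        assert back.bias.voltage == trace.bias.voltage
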