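# tunnelseq

Simulation of **transverse tunneling-current nanopore sequencing** for
single-stranded DNA and RNA, with a correlation-aware statistical base
caller.

In transverse-current sequencing a single strand translocates between two
nanopore-mounted electrodes that contact one nucleotide at a time; the
tunneling current across the contacted base reports its identity through
its electronic structure. Even for a perfectly still molecule the current
through a base depends on its neighbours — hybridization of each
nucleotide's molecular orbitals with those of the adjacent bases spreads
the per-base current distributions and makes naive base calling
error-prone. This *structural noise* is intrinsic to the chain, not to the
apparatus. `tunnelseq` quantifies it and implements the statistical
machinery that removes it: because the noise comes from the neighbours,
the currents through adjacent bases are *correlated*, and joint
current densities over base pairs and triples recover what the
single-current densities lose.

The package is aimed at people modelling solid-state nanopore readout —
quantum-transport theorists and sequencing-technology developers who want
a fast, fully controlled sandbox for the statistics of base calling under
structural noise.

## Model

* **Chain Hamiltonian.** Each nucleotide X is a site with m molecular
  orbitals (default m = 5: four occupied, one LUMO ≈ 4 eV above the HOMO,
  HOMOs in [−6, −5] eV). A sequence X₁…Xₙ maps to a block-tridiagonal
  Hamiltonian with onsite blocks ε_i = h_{X_i} + R(V_{X_i X_{i+1}}) +
  R(V_{X_i X_{i−1}}) (two-center neighbour renormalization, R the
  Hermitian part) and hopping blocks V_{X_i X_{i+1}}. Couplings beyond
  first neighbours vanish. Because the DFT-derived blocks behind the
  original study are not public, a seeded synthetic generator
  (`generate_parameter_set`) produces blocks with the published spectral
  features.
* **Projection.** For full (unreduced) fragment systems with
  non-orthogonal overlap S, oblique projectors onto the active orbital
  window give the exact energy-dependent effective Hamiltonian
  H_eff(E) = H_PP + (E·S_PQ − H_PQ)(E·S_QQ − H_QQ)⁻¹(E·S_QP − H_QP),
  whose fixed points det(H_eff(E) − E·S_PP) = 0 reproduce the full
  generalized eigenvalues; its weak energy dependence justifies
  linearization at the mean valence energy.
* **Transport.** Wide-band electrodes: Σ_{L/R} = −iΓ/2 on the contacted
  site (Γ = 10⁻³ eV), chemical potential μ = −W (work function W: Al 4.08,
  Gr 4.60, Au 5.10, Pt 5.65 eV). Zero-temperature Landauer/Meir–Wingreen
  current through base k:
  I_k = (2e/h) ∫_{μ_R}^{μ_L} dE Tr[Γ_L G(E) Γ_R G†(E)],
  with G the retarded Green's function of the coupled chain, evaluated by
  an eigendecomposition plus low-rank electrode update and integrated with
  panel-adaptive Gauss–Legendre quadrature anchored on the chain
  eigenvalues. Al/Gr probe the gap (tunneling regime); Au/Pt sit on the
  HOMO band (resonant regime).
* **Calibration.** Random training chains (default 150 × 200 nt, 30 with
  an inserted poly(X) run, i.e. 30,000 observations) yield non-parametric
  smoothed densities of log₁₀ current for every base (P1), neighbour pair
  (P2) and triple (P3), pooled over reading-direction reversal — 4, 10 and
  40 classes respectively.
* **Base calling.** P1 calling assigns argmax_X P_X(I_k). Refinement
  climbs the order ladder: each sweep re-maximizes every undecided site
  over the joint densities of all order-n windows containing it, with
  neighbour identities fixed to the previous guess; sites whose call
  repeats are collapsed as *certain*. Fidelity f = (1/N) Σ_k [X̃_k = X_k]
  scores the result (optionally over a masked segment such as a repeat).

## Worked example

```bash
python examples/04_calibrate_and_call.py
```

```
calibrated on 3000 current observations (10 pair and 40 triple density classes)
P1 (single-current)    fidelity 0.9350 (error rate 0.0650)
P3 (refined)           fidelity 0.9950 (error rate 0.0050)
```

The calibration scanned 30 random 100-nt chains with Al electrodes at
0.1 V bias and built the P1/P2/P3 library; on a held-out 200-nt chain,
single-current calling misreads 6.5% of the bases (structural noise makes
the A and C current distributions overlap), while the correlation-aware
order-3 refinement brings the error rate down to 0.5% — the central
qualitative result. `examples/03_scan_currents.py` shows the underlying
per-site currents and the tunneling-regime ordering G > A > C > T;
`examples/05_gamma_scaling.py` verifies that the contact strength only
rescales the currents (a rigid log₁₀ 4 shift when Γ doubles) without
reshaping their distribution.

The same pipeline is scriptable from the shell:

```bash
tunnelseq generate-params --kind DNA --seed 1 --out params.json
tunnelseq calibrate --params params.json --electrode Al --seed 11 --out pdfs.npz
tunnelseq scan --params params.json --fasta in.fasta --electrode Al --out trace.tsv
tunnelseq call --trace trace.tsv --pdfs pdfs.npz --order 3 --out called.fasta
tunnelseq score --called called.fasta --truth truth.fasta
```

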