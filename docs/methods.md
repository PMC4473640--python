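# Methods

This note documents the models, parameter choices and numerical decisions
behind `tunnelseq`, and what the synthetic benchmarks do and do not show
about real devices.

## Physical model and assumptions

A single-stranded DNA/RNA molecule is a linear chain of sites, one per
nucleotide, each carrying m molecular orbitals (MOs). The model is
zero-temperature and static: the strand is frozen with respect to the
electrodes, there is no solvent, no conformational motion, no
base-pairing and no inelastic scattering. All remaining current spread is
therefore *structural* — caused purely by the electronic interaction of
each base with its neighbours along the chain. This isolates the noise
source the package studies; a real measurement adds dynamic and
environmental noise on top.

### Fragment parameter surrogate

The onsite blocks h_X and nearest-neighbour coupling blocks V_XY of the
reduced tight-binding model would, in a first-principles workflow, be
extracted from fragment-MO electronic-structure calculations of single
nucleotides and pairs. Those matrices are not publicly available, so
`fragments.generate_parameter_set` draws seeded random blocks constrained
by what published electronic-structure data do fix:

| quantity | value | rationale |
|---|---|---|
| orbitals per site m | 5 (4 occupied + 1 LUMO) | the HOMO-side orbitals dominate transport; one LUMO bounds the gap |
| HOMO energies (eV) | G −5.15, A −5.48, C −5.62, T −5.95, U −5.99 | all inside the photoemission band [−6, −5]; ordering G > A ~ C > T reproduces the tunneling-current ordering; U lowest, as its base (not backbone) differs from T |
| HOMO–LUMO gap | 4.0 eV (±0.5 tolerance band) | nucleobase optical gaps |
| occupied-level spacing | 0.8 eV below the HOMO, then 0.75 eV steps | dense valence manifold without accidental degeneracies |
| onsite off-diagonal scale | 0.01 eV | fragment MOs are near-eigenstates of the isolated fragment |
| coupling entries | uniform(−s, s), s log-uniform in [0.05, 0.3] eV per pair, spectral norm capped at 0.7× the level spacing | see below |
| RNA backbone shift | symmetric perturbation, ‖·‖_F ≤ 0.05 eV on A/C/G | backbone levels lie deep and barely move the frontier orbitals |
| per-level jitter | ±0.008 eV | seeded variability without leaving the bands |

The coupling magnitude is the one quantity with no published value, and
it controls everything interesting: the onsite renormalization a base
receives from its neighbours is of the coupling's order, so it sets the
structural-noise amplitude relative to the inter-base HOMO separations
(0.14–0.33 eV). The default range 0.05–0.3 eV was chosen to reproduce the
reported phenomenology of the tunneling regime — a current spread of
several tenths of a decade to a decade, single-current calling that is
clearly imperfect, and near-perfect correlation-aware calling. Weaker
couplings (e.g. an order of magnitude below the level spacing) make every
base separable from its single current alone and the correlation
machinery pointless; stronger ones leave the perturbative regime. Second-
neighbour couplings are structurally zero in the data model, consistent
with their rapid decay in stacked nucleotides.

RNA reuses the DNA A/C/G blocks plus the backbone perturbation, so the
synthetic RNA keeps the DNA ordering of A vs C; a first-principles
parameterization could order them differently. U is built from its own
template (HOMO −5.99 eV, deeper levels an extra 0.25 eV down), making it
the most separable RNA base.

### Projection

Full fragment systems (M orbitals, non-orthogonal SPD overlap S) are
reduced to an active window P by oblique projectors. Within the package
the projector matrices are stored in the bra-side representation
S·Π·S⁻¹ (Π the active-column selector), in which operator composition is
the plain matrix product, the projector identities hold entrywise, and
the non-Hermiticity of oblique projection is visible as matrix asymmetry.
The effective Hamiltonian is evaluated by the resolvent route
H_eff(E) = E·S_PP − [G_PP(E)]⁻¹ with G = (E·S − H)⁻¹; the explicit
Schur-complement form serves as an independent algebraic check (the two
are equal by the block-inverse identity) and as the numerical fallback
when E sits on a full-pencil eigenvalue, where G_PP degenerates to
numerical rank one while H_eff itself stays finite. Evaluation within
1e−6 eV of a pole (a generalized eigenvalue of (H_QQ, S_QQ)) raises an
error, because the inversion is ill-conditioned there. Outputs are
symmetrized ((X+Xᵀ)/2) so downstream eigensolvers receive Hermitian
input. Fixed points of det(H_eff(E) − E·S_PP) are located by a uniform
scan (default 10⁴ points) plus Brent refinement — robust at the sizes
used, though it would miss exactly degenerate double roots, which the
random test systems do not produce.

### Chain assembly

The two-center onsite correction in the chain Hamiltonian is symmetrized,
R(V) = (V + Vᵀ)/2: the exact onsite integral ⟨φ_iα|V̂|φ_iβ⟩ is Hermitian
in the full theory, and symmetrization restores that property at the
reduced level (adding a raw non-symmetric coupling block would break the
Hermiticity of the Hamiltonian). Only the given strand is modelled,
5′→3′ as written; there is no complement logic. Length-1 chains are
legal.

### Transport

* Wide-band electrodes: Σ_{L/R} = −iΓ_{L/R}/2 on all m orbitals of the
  contacted site, Γ = 10⁻³ eV by default (weak physisorption). Both
  electrodes contact the same site with equal weight on every orbital.
* Chemical potential μ = −W on the vacuum-referenced energy axis; work
  functions Al 4.08, Gr 4.60, Au 5.10, Pt 5.65 eV (configurable). Al/Gr
  land in the HOMO–LUMO gap (tunneling), Au/Pt on the HOMO band
  (resonant).
* Bias split symmetrically, μ_{L/R} = −W ± eV/2 (configurable split);
  temperature exactly zero, so the current is the transmission integral
  over [μ_R, μ_L].
* The site-block Green's function uses one eigendecomposition of the
  chain Hamiltonian plus a Woodbury update per energy (the self-energy
  touches a single m×m block); energies within 1e−9 eV of a chain
  eigenvalue are clamped away from the pole, a perturbation far below
  the Γ-broadened linewidth. Dense inversion of (E − H − Σ) remains the
  contract and the test oracle.
* Quadrature: panel boundaries at every chain eigenvalue within the bias
  window ±10Γ, 15-point Gauss–Legendre per panel with bisection
  refinement (all pending panels of a level evaluated in one vectorized
  call), relative tolerance 1e−6 (1e−5 in the statistical pipelines,
  where KDE smoothing dwarfs quadrature error). Nodes are interior, so
  resonant panel edges are never evaluated exactly on a pole.
* Currents are stored in units of (2e/h)·eV; `CURRENT_UNIT_AMPERE`
  (7.748×10⁻⁵ A) converts to amperes.

### Calibration and densities

Training chains are uniform-composition random sequences; a configurable
subset carries one poly(X) run (base cycling through the alphabet, length
uniform in 3–20, position uniform) so that strongly self-hybridized
repeats appear in the statistics. All adjacent pairs and triples enter
the pair/triple pools; boundary sites simply contribute to fewer windows.
Ordered tuples are pooled with their reading-direction reversal (10 pair,
40 triple classes over 4 letters); palindromic classes store both
orientations of each reading so their densities are exactly
reversal-symmetric.

Densities are histograms of log₁₀ current on shared grids — 200 bins
(1-D), 64 bins/dim (2-D and 3-D) over the observed range padded by 0.3
decades — smoothed with a Gaussian kernel, floored at 10⁻¹² and
normalized to unit integral. The per-dimension bandwidth is
0.53·σ·n^(−1/5), half of Silverman's constant: these densities are
mixtures of narrow neighbour-context clusters, and the unimodal Silverman
rule oversmooths precisely the between-base structure the caller needs
(measured on the tunneling benchmark, full Silverman smoothing costs
about two percentage points of refined fidelity). The bandwidth is
clamped below at half a bin so sparse classes never collapse to isolated
spikes. Classes with fewer than 25 observations abort calibration with a
list of the starved classes.

### Base calling and refinement

P1 calling takes argmax over bases of the single-current density; ties
break in alphabet order. Refinement climbs the order ladder: first the
pair densities, then (order 3) the triples. Within a ladder step, sweeps
run left-to-right over the undecided sites; the score of candidate X at
site k is the sum of log joint densities of *all* order-n windows
containing k, with the other identities fixed to the previous sweep —
this is the exact conditional of the trace-level joint score given the
other calls, and it is what makes the iteration escape locally stable
error clusters that a single centered window cannot (measured: ~1.9
percentage points of refined fidelity on the tunneling benchmark). Sites
whose call repeats between consecutive sweeps are collapsed as certain —
frozen for the rest of the run, conditioning their neighbours only. A
step ends when a sweep changes nothing (cap: 10 sweeps). Reversal-pooled
classes are evaluated with arguments ordered to the class's canonical
orientation. The collapse rule is a hard freeze; renormalizing the
neighbours' conditionals instead would be a softer reading of the same
idea and is not implemented.

Fidelity is the exact fraction of matching sites; a site mask (e.g. a
BED-defined repeat segment) restricts the count (partial fidelity). The
error rate is its complement.

## Benchmark problem sizes

The statistical benchmarks run a scaled-down version of the full
protocol: calibration on 30 chains of 100 nt (6 with poly(X) runs, 3,000
observations) and evaluation on 20 held-out 200-nt chains, chosen so the
whole suite and the acceptance script each run in minutes on one CPU.
The full protocol (150 × 200 nt) is the library default and runs in
roughly half an hour. At the scaled sizes the triple classes hold ~90
observations each; the refinement still reaches fidelity ≈ 0.98–1.00 in
the tunneling regime, so the conclusions do not hinge on the larger
statistics, but absolute fidelities at full scale would be slightly
higher still.

## What the synthetic benchmarks show — and what they do not

They show that the package's transport core is numerically exact against
dense oracles, that the projected effective Hamiltonian is exact inside
the active window, and that under structural noise of the modelled kind,
current-current correlations between neighbours recover nearly all the
fidelity that single-current calling loses — including the tunneling vs
resonant regime contrast and the Γ-invariance of the distribution shape.
They do not show device-level error rates: the coupling magnitudes are
synthetic, there is no dynamic/environmental noise, no translocation
dynamics, no finite temperature, and natural-sequence composition bias is
not modelled. Absolute fidelities therefore characterize the method, not
any instrument.

## Known limitations

* The synthetic A/C HOMO separation (0.14 eV) is a choice; real
  parameterizations could be harder or easier to separate.
* 3-D density grids at 64 bins/dim with ~90 samples per class are sparse;
  the order-2 stage carries much of the refinement at benchmark scale.
* The fixed-point scanner assumes simple roots.
* Long homopolymer runs approach the polymer band limit; with the default
  3–20-nt training runs, repeats near the top of that range remain the
  hardest contexts, mirroring the motivation for including them in
  calibration.
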