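# Methods

This note documents the models, numerical choices and limitations behind
`lobehf`. It is the place where design decisions that the code cannot
explain by itself are written down.

## Model overview

`lobehf` implements all-electron restricted Hartree–Fock (RHF) in a
minimal basis for biomolecular fragments, with four ingredients aimed at
linear scaling:

1. **Gaussian lobe basis functions.** Every basis function is a signed sum
   of displaced s-Gaussians. s shells are ordinary contractions; p shells
   are two mirror-image sets of three s-Gaussians displaced symmetrically
   along the shell axis, one set entering with a minus sign. All one- and
   two-electron integrals therefore reduce to the same s-Gaussian closed
   forms — a single uniform kernel handles every shell combination.
2. **Three-stage screening of electron-repulsion integrals (ERIs).** A
   density `ρ_ij = φ_i φ_j` is kept only if the analytic integral of
   `|φ_i||φ_j|` (its *relevance*) exceeds a threshold; an ERI `(ij|kl)` is
   evaluated only if both densities are relevant, their centers (atomic
   means) lie within the upper Coulomb cut-off, and the combined relevance
   `r_ij·r_kl / max(d, 1 Bohr)` exceeds a final threshold. ERIs between
   the lower and upper cut-off radii are weighted by the smoothstep
   `f(x) = 1 + 2x³ − 3x²`.
3. **Divide and conquer.** Large systems are split into core regions
   (k-means clusters or grid cells), each grown by a buffer and repaired
   chemically at the boundary (double bonds pull both partners in; single
   bonds are capped with hydrogen at the standard X–H length). Each
   subsystem is solved independently; core-atom energies are kept and the
   density matrices merged.
4. **Real-time TDHF.** Absorption spectra come from propagating the
   converged density under a weak Gaussian field pulse and Fourier
   transforming the induced dipole.

## Basis construction

The reference data is an STO-6G-style minimal basis generated in-package:
each Slater orbital (standard molecular-optimized exponents: H 1.24,
He 1.69, C 5.67/1.72, N 6.67/1.95, O 7.66/2.25) is expanded in six
Gaussians by weighted least squares on a radial grid
(`scripts/make_reference_basis.py`). The construction is the classic
STO-NG recipe re-derived from scratch; the shipped file
`sto6g_synthetic.gbs` is labelled synthetic because it is generated, not
downloaded. The hydrogen expansion reproduces the published STO-6G
values to six digits, which validates the generator.

Lobe expansions (3 Gaussians per s shell, 3 mirror pairs per p shell,
STO-3G-equivalent accuracy) are fitted to the reference shells on a cubic
real-space grid by bound-constrained trust-region least squares with
analytic Jacobians. Choices that matter:

* **Grid.** Default cube half-width 8 Bohr, spacing 0.2 Bohr, *scaled per
  shell* by `sqrt(35.5 / max reference exponent)`. A fixed 0.2 Bohr grid
  cannot resolve heavy-atom 1s cusps (the O 1s core is ~0.13 Bohr wide);
  scaling the whole cube to the shell's natural length keeps the grid
  shape identical in dimensionless form for every shell.
* **Initial guesses.** The classic ζ=1 STO-3G exponent triplets scaled by
  ζ², plus symmetric displacements of 0.1 (scaled) for p pairs. These
  inits are fixed, so fits are bitwise reproducible. Free inits were found
  to leave O 2s/2p in poor local minima (~0.25 Ha on water).
* **Displacement bound.** Lobe displacements are capped at 0.35 of the
  shell length scale. Larger displacements buy negligible residual but
  visibly break rotational invariance (see below).
* **Acceptance.** A fit is accepted when its weighted residual RMS is
  below 5·10⁻³ of the peak target amplitude; the optimizer landscape is
  flat in the small-displacement direction (a displaced pair approaches a
  Cartesian p times derivative), so step-size convergence is not a
  meaningful criterion there.
* **Normalization.** Fitted expansions are renormalized analytically to
  unit self-overlap.

With these choices the small-molecule RHF energies land within ~10 mHa of
STO-3G literature values (H₂ −1.1168, H₂O −74.954, CH₄ −39.732,
NH₃ −55.448, C₂H₆ −78.305 Ha); the residual is the refit-vs-maximum-
overlap difference inherent to re-deriving the basis.

For the relevance screen each p shell is additionally fitted *per lobe*
with anisotropic Gaussians (individual parallel/transverse exponents and
along-axis offsets, coefficients bounded at zero). Each lobe is therefore
sign-definite and the integral of its absolute value — and of any product
of two lobes — is analytic. s shells reuse their own primitives with
absolute coefficients.

## Integral kernel

The primitive ERI is
`(g_a g_b | g_c g_d) = O_ab · O_cd · √P · F₁₁(½, 3/2, −P d²)` with pair
overlaps `O` (prefactor √2·π^(5/4)), reduced exponent
`P = p q / (p + q)` and pair-center distance `d`. The typographically
ambiguous prefactor of the source expressions is resolved by requiring
exact equality with the textbook `(ss|ss)` closed form; the package treats
that closed form as normative.

`F₁₁` is evaluated as `√π·erf(√x)/(2√x)` with the rational erf
approximation (coefficients 0.3275911, 0.254829592, −0.284496736,
1.421413741, −1.453152027, 1.061405429), saturating to exactly 1 for
arguments ≥ 4 (where 1 − erf(4) ≈ 1.5·10⁻⁸). Below x = 0.09 a short
Taylor series continues the x → 0 limit because the erf ratio loses
relative accuracy there; the combined kernel has max relative error
2.7·10⁻⁷ over all x ≥ 0. The sign of the second rational coefficient is
negative (its source is the Abramowitz–Stegun 7.1.26 family; the positive
sign sometimes seen in transcriptions makes erf(0) = −0.57).

One-electron nuclear attraction uses the same Boys-function form with
machine-precision erf: it is an O(n²) one-time cost and keeping it exact
preserves the tight agreement with quadrature oracles that the hot ERI
path cannot (and need not) reach.

## Scope of the Coulomb cut-off

The smoothstep weight is applied consistently to *all three* classes of
electrostatic interaction: electron–electron (each ERI, by density-center
distance), electron–nuclear (each nucleus contribution to V, by
density-center-to-nucleus distance) and nuclear–nuclear (by atom-pair
distance). Cutting only the ERIs would leave distant *charged*
monopoles interacting through V and the nuclear repulsion while their
electronic counterweight is removed; on decane that imbalance is ~19 Ha.
With the consistent treatment — which is how classical force-field
cut-offs behave, the stated model for this truncation — the screened
decane total energy agrees with the unscreened one to 1·10⁻⁵ relative and
the orbital-energy RMSD is 3.4 mHa.

A practical limit follows: once a *single* SCF spans a system much larger
than the cut-off, distant regions become electrostatically decoupled and
the global iteration can slosh charge between their near-degenerate
levels. The cure is the intended usage: keep single-SCF systems within a
few cut-off radii and use divide-and-conquer beyond that. The driver
additionally supports level shifting and a deterministic level-shifted
retry for hard cases.

## SCF driver

Symmetric (Löwdin) orthogonalization with a 10⁻⁷ eigenvalue cut-off
(canonical drop below it); diagonalized-core initial guess; DIIS (depth 8)
on the orthogonalized commutator residual; convergence on the RMSD of
successive density matrices at 10⁻⁶. The reported total energy includes
the (screened) nuclear repulsion; electronic and nuclear parts are kept
separately in the result object.

Atomic energies follow the nuclear-charge-normalized partition
`E_a = (1/Z_a) Σ_{i∈val(a)} Σ_j P_ij (H_ij + ½ G_ij)` where the first sum
runs over valence functions centered on atom `a` (heavy-atom 1s functions
are core) and the second over the whole basis. With every function
counted as valence, `Σ_a Z_a E_a` recovers the electronic energy exactly.

## Real-time TDHF

Length-gauge Gaussian pulse (strength 10⁻⁵ a.u., σ = 0.2 a.u., centered
at t₀ = 2 a.u.); unitary exponential-midpoint propagation with one
predictor–corrector Fock rebuild per step (default 2000 steps of
0.25 a.u., i.e. 500 a.u. ≈ 12.1 fs); trace and idempotency checked every
100 steps. The induced dipole is damped by exp(−0.01 t), transformed, and
divided by the analytic pulse spectrum; absorption is −ω·Im α(ω) (the
sign follows the e^(−iωt) transform convention), clipped at zero.
Frequencies beyond three pulse bandwidths (3/σ) or half the sampling
limit are discarded: the division by the pulse spectrum amplifies
propagator noise where the pulse carries no power.

Computed excitation energies are *divided* by the empirical factor 1.335
to map time-dependent Hartree–Fock excitations onto the experimental
scale (TDHF systematically overestimates); the unrescaled axis is kept
alongside, and the factor is a config knob.

The propagator's frequency error is second order in the time step: the
minimal-basis H₂ peak moves 25.45 → 25.37 → 25.34 eV as dt goes
0.25 → 0.125 → 0.0625 a.u., converging on the linear-response TDHF
(RPA/Casida) value 25.336 eV computed independently from the same ground
state. Note that linear response of real-time TDHF is RPA, *not* CIS/TDA:
for H₂ the two differ by 0.48 eV.

## Divide and conquer

Bond classification uses single-bond covalent radii (H 0.31, C 0.76,
N 0.71, O 0.66, S 1.05, P 1.07 Å) and double-bond radii (C 0.67, N 0.60,
O 0.57, S 0.94, P 1.02 Å). The double-bond band adds ±0.06 Å (tight:
ethylene 1.34 Å is double, ethane 1.54 Å single); the single-bond band
adds +0.15 Å so that thermally or artificially distorted bonds — the
jittered tails of the quality-gradient fixtures, or H₂ at 0.74 Å — do not
silently dissociate. Cap lengths: C–H 1.09, N–H 1.01, O–H 0.96,
S–H 1.34 Å.

If a capped subsystem ends up with an odd electron count, capped atoms
are pulled fully in (nearest-first, preferring candidates whose inclusion
flips parity); when no capped bonds exist — a dissociated fragment — the
nearest outside atoms are considered. The repair is deterministic and
logged.

Merging follows the ownership rule: a density element whose two parent
atoms both lie in one subsystem is taken from the subsystem whose *core*
contains the lower-indexed atom; if the two atoms only co-reside in
subsystems that do not own the element, the arithmetic mean is used;
cap-atom functions never map back. The merged density is not exactly
idempotent — its electron count is verified to ~1% on test chains rather
than exactly.

Subsystems are processed independently and statelessly, so results are
bitwise independent of processing order.

## Structure assessment pipeline

Per-atom energies are smoothed along the chain (file order) with a
Savitzky–Golay filter (window 150, polynomial order 3; the window is
shrunk to the track length for small systems — 150 atoms corresponds to
~2% of the solvated proteins the scale of the method targets), linearly
mapped onto the pLDDT range (factor 15 with a structure-specific offset;
the default offset auto-fits the track median to the pLDDT median, a
reproducible surrogate for hand-chosen offsets), and clipped at the
structure's own min/max pLDDT. The baseline comparator counts
non-hydrogen atoms within 8 Å. Correlations are Pearson and Spearman.

The analysis layer can additionally center energies per element
(subtracting each element's mean track value) before smoothing. Raw
`E_a` values carry systematic per-element offsets (O ≈ −9.3, C ≈ −7.9 Ha
in peptide tests, with hydrogen the noisiest since it lacks the 1/Z
damping); the element pattern of a chain otherwise imprints directly on
the track. This implements the "normalized by element type" step beyond
the bare 1/Z factor of the partition.

## Synthetic data

All test inputs are generated: hard-coded standard geometries (H₂ 0.74 Å,
water 0.9572 Å/104.52°, etc.), idealized all-trans alkanes and polyenes,
an extended polyglycine built from standard bond lengths, seeded
rejection-sampled water shells (default minimum heavy-contact distance
2.4 Å; the solvated scoring fixtures use 2.55–2.6 Å, closer to physical
O–O packing, because compressed contacts make the SCF needlessly hard),
and the quality-gradient peptide: ideal head, tail with Gaussian
coordinate jitter ramping to σ = 0.3 Å, and a monotone pLDDT-like track
(90 → 35) planted in the B-factor slot.

What these fixtures do *not* emulate: real conformational ensembles,
hydrogen-bond networks of equilibrated solvent, the error statistics of
any structure predictor, or charged residues (all systems are neutral
closed-shell). Passing tests demonstrate the machinery — screening
consistency, subsystem recovery, spectral physics, score pipelines — at
desk scale, not biological accuracy of any specific prediction.

## Problem sizes

The validation suites run at deliberately small scale chosen as the
smallest systems that still exercise each mechanism: decane (32 atoms,
72 basis functions) for screening consistency and two-subsystem recovery;
water/methane for oracle agreement; H₂ for spectra (where an exact
linear-response oracle exists); a 6-residue glycine peptide in a thin
water shell for the scoring pipeline. The same code paths scale to the
thousands-of-atoms regime via divide and conquer, but those runs are not
part of the test envelope.

A caveat on the scoring fixture: at this scale the comparison between the
quantum energy track and the neighbour-count baseline is statistically
tight. The planted confidence track is monotone along the chain, so *any*
chain-position artifact correlates with it; the neighbour count picks up
a nearly constant +0.4 from end-vs-middle geometry, while the energy
track's correlation varies between −0.2 and −0.7 with the disorder
realization (seed). The energy track wins for the default realization and
increasingly reliably as the system grows; on the ~10⁴-atom solvated
proteins this method targets, the 59-atom fixture's variance is not
representative.

## Known limitations

* Minimal basis only (s and p shells); no d/f shells, ECPs or
  split-valence sets.
* Closed-shell RHF only; odd-electron systems are rejected rather than
  treated unrestricted.
* Rotational invariance is approximate: ~7·10⁻⁶ Ha on water from the
  axis-aligned displaced lobes plus ~7·10⁻⁵ Ha from the orientation
  dependence of the rational erf kernel; the documented bound is
  2·10⁻⁴ Ha.
* The screened functional is meaningful for neutral, locally compact
  systems; global SCF across many cut-off radii belongs to the
  divide-and-conquer path.
* No analytic gradients, geometry optimization, or open-shell spectra.
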