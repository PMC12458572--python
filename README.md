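# lobehf

Linear-scaling all-electron restricted Hartree–Fock for biomolecular
systems, built from four pieces:

* **Gaussian lobe basis functions** — a minimal (STO-3G-equivalent) basis
  in which p orbitals are signed pairs of displaced s-Gaussians, so every
  one- and two-electron integral reduces to the same s-Gaussian closed
  form and a single uniform kernel evaluates all of them;
* **three-stage screening of electron-repulsion integrals** — an analytic
  density-relevance test (integral of |φᵢφⱼ| via a sign-definite per-lobe
  representation), a Coulomb distance cut-off with a smoothstep weight
  `f(x) = 1 + 2x³ − 3x²` between 8 and 10 Å applied consistently to
  electron–electron, electron–nuclear and nuclear–nuclear terms, and a
  combined-relevance test `r(ρᵢⱼ)·r(ρₖₗ)/d`;
* **divide and conquer** — k-means or grid cores grown by buffered
  regions with chemically informed boundary repair (intersected double
  bonds pull both partners in, cut single bonds are hydrogen-capped at
  the standard X–H length), independent per-subsystem SCF, and
  density-matrix merging;
* **real-time TDHF** — absorption spectra from unitary propagation of the
  density matrix under a weak Gaussian field pulse (10⁻⁵ a.u., σ = 0.2,
  2000 × 0.25 a.u. steps), damped Fourier transform of the induced
  dipole, and an empirical 1.335 rescaling of excitation energies.

Downstream of the solver, per-atom energies

    E_a = (1/Z_a) Σ_{i∈val(a)} Σ_j P_ij (H_ij + ½ G_ij)

are smoothed, rescaled to the pLDDT confidence range, and compared with a
predicted model's confidence track — a quantum, physics-grounded score
for predicted protein structures.

The intended users are method developers and computational structural
biologists who want an inspectable, pure-Python (numpy + numba)
implementation of these techniques at desk scale: every approximation is
a config knob and every stage is exposed as a library function.

## Worked example

Ground-state SCF on water, from the command line:

```
$ lobehf fixtures H2O -o water.xyz
wrote 3 atoms to water.xyz
$ lobehf scf water.xyz --no-screening -o out
converged: True in 8 iterations
total energy: -74.953918 Ha (electronic -84.148884, nuclear 9.194965)
```

−74.954 Ha is the expected minimal-basis RHF value for water (STO-3G
literature: −74.963 Ha; the small offset is the refit-vs-maximum-overlap
difference of the in-package basis). The same from Python, plus the
screening counters:

```python
>>> from lobehf import *
>>> from lobehf.fixtures import make_chain
>>> decane = make_chain("alkane", 10)
>>> basis = basis_for_structure(decane)
>>> eris = build_screened_eris(basis, ScreeningConfig())
>>> eris.counters()
{'n_theoretical': 26873856, 'n_unique': 3454506,
 'n_density_surviving': 975106, 'n_fully_surviving': 880001}
>>> result = scf_solve(decane, basis, eris=eris)
>>> round(result.total_energy, 6)
-386.932585
```

Of decane's 3.45 million unique ERIs, the density-relevance screen keeps
about 28% and the Coulomb screens keep 880 001 (25%); the total energy
differs from the unscreened calculation (−386.928753 Ha) by 1·10⁻⁵
relative, with an orbital-energy RMSD of 3.4 mHa.

An absorption spectrum of H₂ and a divide-and-conquer run:

```
$ lobehf fixtures H2 -o h2.xyz && lobehf spectrum h2.xyz -o out
spectrum written to out/spectrum.tsv        # strongest peak: 25.45 eV raw
$ lobehf fixtures alkane:10 -o c10.xyz && lobehf dnc c10.xyz --mode kmeans
2 subsystems, 0 failures
```

Scoring a predicted model against its pLDDT column (B-factors):

```
$ lobehf score model.pdb -o out
energy vs pLDDT: pearson ..., spearman ...
```

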