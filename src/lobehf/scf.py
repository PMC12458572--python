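"""Restricted Hartree-Fock over screened lobe-basis integrals.

The driver assembles the core Hamiltonian, iterates Fock builds from the
screened ERI list (each ERI carrying its smoothstep Coulomb weight), and
converges on the RMSD of successive density matrices.  DIIS acceleration
is on by default; the initial guess is the diagonalized core Hamiltonian,
so runs are deterministic.

Also here: the nuclear-charge-normalized atomic-energy partition over
valence basis functions, and the electron-density evaluation on uniform
real-space grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .basis import OrbitalBasis, basis_for_structure
from .integrals import (ScreenedERISet, ScreeningConfig, build_screened_eris,
                        core_hamiltonian, nuclear_repulsion_screened,
                        two_electron_matrix)
from .structure import AtomicStructure

__all__ = ["SCFConfig", "SCFResult", "AtomicEnergies", "SCFError",
           "scf_solve", "atomic_energies", "DensityGridSpec", "DensityGrid",
           "density_on_grid"]


class SCFError(RuntimeError):
    pass


@dataclass
class SCFConfig:
    density_rmsd_tol: float = 1e-6
    max_iterations: int = 200
    mixing: str = "diis"          # one of: none, damping, diis
    damping: float = 0.5          # fraction of old density kept (mixing=damping)
    diis_depth: int = 8
    #: "atomic": superposition of neutral-atom shell occupations (robust
    #: for clusters of molecules); "core": diagonalized core Hamiltonian
    initial_guess: str = "atomic"
    orth_eigen_cutoff: float = 1e-7
    #: Hartree added to virtual orbitals during iteration; damps the charge
    #: sloshing of near-degenerate occupied spaces (e.g. water clusters).
    #: Applied only while iterating, so the converged result is unshifted.
    level_shift: float = 0.0
    #: on non-convergence, retry once with a level shift (warm-started from
    #: the last density); the retry is deterministic
    fallback_on_failure: bool = True
    fallback_level_shift: float = 0.5

    def __post_init__(self) -> None:
        if self.density_rmsd_tol <= 0:
            raise ValueError("density_rmsd_tol must be positive")
        if self.mixing not in ("none", "damping", "diis"):
            raise ValueError(f"unknown mixing scheme {self.mixing!r}")


@dataclass
class SCFResult:
    density_matrix: np.ndarray       # P, closed-shell (Tr PS = n_electrons)
    fock: np.ndarray
    core_hamiltonian: np.ndarray
    two_electron_matrix: np.ndarray  # G = J - K/2 at convergence
    overlap: np.ndarray
    orbital_energies: np.ndarray     # ascending, Hartree
    mo_coefficients: np.ndarray      # columns in overlap metric
    electronic_energy: float
    nuclear_repulsion: float
    total_energy: float              # electronic + nuclear, Hartree
    n_electrons: int
    converged: bool
    iterations: int
    history: list = field(default_factory=list, repr=False)

    @property
    def n_occupied(self) -> int:
        return self.n_electrons // 2

    @property
    def homo_lumo_gap(self) -> float:
        occ = self.n_occupied
        return float(self.orbital_energies[occ] - self.orbital_energies[occ - 1])


def _orthogonalizer(S: np.ndarray, cutoff: float) -> np.ndarray:
    """Symmetric (Loewdin) orthogonalizer; canonical drop below cutoff."""
    evals, vecs = np.linalg.eigh(S)
    if evals[-1] <= 0:
        raise SCFError("overlap matrix not positive definite")
    keep = evals > cutoff
    if not np.all(keep):
        # canonical orthogonalization: drop near-dependent combinations
        return vecs[:, keep] / np.sqrt(evals[keep])
    return (vecs / np.sqrt(evals)) @ vecs.T


def _density_from_fock(F, X, n_occ):
    e, c = np.linalg.eigh(X.T @ F @ X)
    C = X @ c
    P = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
    return P, e, C


#: neutral-atom electrons per shell for the superposition guess
_SHELL_OCCUPATIONS = {
    ("H", "1s"): 1.0, ("He", "1s"): 2.0,
    ("C", "1s"): 2.0, ("C", "2s"): 2.0, ("C", "2p"): 2.0 / 3.0,
    ("N", "1s"): 2.0, ("N", "2s"): 2.0, ("N", "2p"): 1.0,
    ("O", "1s"): 2.0, ("O", "2s"): 2.0, ("O", "2p"): 4.0 / 3.0,
}


def _atomic_guess(basis: OrbitalBasis, S: np.ndarray, n_el: int
                  ) -> np.ndarray:
    """Superposition-of-atomic-densities guess: diagonal shell occupations
    scaled to the exact electron count.  Not idempotent, but it starts the
    iteration from locally neutral atoms, which avoids the initial charge
    sloshing a core-Hamiltonian guess causes in molecular clusters."""
    elements = basis.structure.elements
    occ = np.empty(basis.n_bf)
    for i, orb in enumerate(basis.orbitals):
        el = elements[orb.atom_index]
        key = (el, orb.shell_label[:2] if orb.shell_label[-1] in "xyz"
               else orb.shell_label)
        occ[i] = _SHELL_OCCUPATIONS.get(key, 0.0)
    P = np.diag(occ)
    tr = float(np.sum(occ * np.diag(S)))
    if tr <= 0:
        return P
    return P * (n_el / tr)


class _DIIS:
    def __init__(self, depth: int):
        self.depth = depth
        self.focks: list[np.ndarray] = []
        self.errors: list[np.ndarray] = []

    def update(self, F, err):
        self.focks.append(F)
        self.errors.append(err.ravel())
        if len(self.focks) > self.depth:
            self.focks.pop(0)
            self.errors.pop(0)
        # prune stale vectors whose residual dwarfs the current best:
        # they make B ill-conditioned and destabilize near-converged states
        norms = [float(np.linalg.norm(e)) for e in self.errors]
        best = min(norms)
        keep = [i for i, nm in enumerate(norms) if nm <= 1e3 * best + 1e-300]
        self.focks = [self.focks[i] for i in keep]
        self.errors = [self.errors[i] for i in keep]
        m = len(self.focks)
        if m < 2:
            return F
        B = np.empty((m + 1, m + 1))
        B[-1, :] = -1.0
        B[:, -1] = -1.0
        B[-1, -1] = 0.0
        for i in range(m):
            for j in range(i, m):
                B[i, j] = B[j, i] = float(self.errors[i] @ self.errors[j])
        # scale the error block to unit diagonal for conditioning
        d = np.sqrt(np.abs(np.diag(B)[:m])) + 1e-300
        Bs = B.copy()
        Bs[:m, :m] = B[:m, :m] / np.outer(d, d)
        Bs[:m, -1] = -1.0 / d
        Bs[-1, :m] = -1.0 / d
        rhs = np.zeros(m + 1)
        rhs[-1] = -1.0
        try:
            sol = np.linalg.solve(Bs, rhs)
        except np.linalg.LinAlgError:
            return F
        w = sol[:m] / d
        if not np.all(np.isfinite(w)) or np.abs(w).sum() > 1e4:
            return F
        return sum(wi * Fi for wi, Fi in zip(w, self.focks))


def scf_solve(structure: AtomicStructure,
              basis: OrbitalBasis | None = None,
              screening: ScreeningConfig | None = None,
              config: SCFConfig | None = None,
              eris: ScreenedERISet | None = None) -> SCFResult:
    """Converge a closed-shell RHF calculation.

    ``eris`` may be passed to reuse a precomputed screened ERI set (the
    screening config is then ignored).  Raises :class:`SCFError` for odd
    electron counts or a singular overlap matrix.
    """
    config = config or SCFConfig()
    basis = basis if basis is not None else basis_for_structure(structure)
    n_el = structure.n_electrons
    if n_el % 2 != 0:
        raise SCFError(
            f"odd electron count {n_el}: closed-shell RHF requires an even "
            "count (adjust capping/charge)")
    n_occ = n_el // 2
    if eris is None:
        eris = build_screened_eris(basis, screening)
    screening = eris.config   # one config governs e-e, e-N and N-N weights
    S, H = core_hamiltonian(basis, screening)
    X = _orthogonalizer(S, config.orth_eigen_cutoff)
    if X.shape[1] < n_occ:
        raise SCFError("overlap matrix near-singular: basis linear dependence")

    e_nuc = nuclear_repulsion_screened(structure, screening)

    def iterate(cfg: SCFConfig, P0=None):
        if P0 is not None:
            P = P0
        elif cfg.initial_guess == "atomic":
            P = _atomic_guess(basis, S, n_el)
        else:
            P = _density_from_fock(H, X, n_occ)[0]
        diis = _DIIS(cfg.diis_depth) if cfg.mixing == "diis" else None
        history = []
        converged = False
        it = 0
        for it in range(1, cfg.max_iterations + 1):
            G = two_electron_matrix(eris, P)
            F = H + G
            e_elec = 0.5 * float(np.sum(P * (H + F)))
            if diis is not None:
                err = X.T @ (F @ P @ S - S @ P @ F) @ X
                F_eff = diis.update(F, err)
            else:
                F_eff = F
            if cfg.level_shift > 0.0:
                # shift virtual space up: F += shift * S (1 - P S / 2)
                F_eff = F_eff + cfg.level_shift * (S - 0.5 * S @ P @ S)
            P_new, e_orb, C = _density_from_fock(F_eff, X, n_occ)
            if cfg.mixing == "damping":
                P_new = (1.0 - cfg.damping) * P_new + cfg.damping * P
            rmsd = float(np.sqrt(np.mean((P_new - P) ** 2)))
            history.append({"iteration": it, "electronic_energy": e_elec,
                            "density_rmsd": rmsd})
            P = P_new
            if rmsd < cfg.density_rmsd_tol:
                converged = True
                break
        return P, converged, it, history

    P, converged, it, history = iterate(config)
    if not converged and config.fallback_on_failure \
            and config.level_shift == 0.0:
        # deterministic retry: level-shifted iteration warm-started from
        # the last density (suppresses occupied/virtual sloshing)
        from dataclasses import replace as _replace
        retry_cfg = _replace(config,
                             level_shift=config.fallback_level_shift,
                             fallback_on_failure=False)
        P2, conv2, it2, hist2 = iterate(retry_cfg, P0=P)
        if conv2:
            P, converged = P2, True
        it += it2
        history = history + hist2
    G = two_electron_matrix(eris, P)
    F = H + G
    e_elec = 0.5 * float(np.sum(P * (H + F)))
    _, e_orb, C = _density_from_fock(F, X, n_occ)
    return SCFResult(
        density_matrix=P, fock=F, core_hamiltonian=H, two_electron_matrix=G,
        overlap=S, orbital_energies=e_orb, mo_coefficients=C,
        electronic_energy=e_elec, nuclear_repulsion=e_nuc,
        total_energy=e_elec + e_nuc, n_electrons=n_el,
        converged=converged, iterations=it, history=history)


# ------------------------------------------------------------ atomic energies

@dataclass
class AtomicEnergies:
    """Per-atom energy partition E_a = (1/Z_a) sum_{i in val(a)} sum_j
    P_ij (H_ij + G_ij / 2)."""

    energies: np.ndarray        # Hartree, one per atom
    charges: np.ndarray
    valence_counts: np.ndarray  # valence basis functions per atom


def atomic_energies(result: SCFResult, basis: OrbitalBasis,
                    structure: AtomicStructure | None = None
                    ) -> AtomicEnergies:
    """Nuclear-charge-normalized atomic energies over valence functions.

    The i-sum runs only over valence basis functions centered on atom a;
    the j-sum runs over the full basis, so the partition assigns each
    density element to the atom of its first (valence) index.
    """
    structure = structure or basis.structure
    z = structure.atomic_numbers.astype(float)
    if np.any(z == 0):
        raise ValueError("atom with zero nuclear charge")
    per_orbital = np.sum(
        result.density_matrix
        * (result.core_hamiltonian + 0.5 * result.two_electron_matrix),
        axis=1)
    n_atoms = structure.n_atoms
    e = np.zeros(n_atoms)
    counts = np.zeros(n_atoms, dtype=np.int64)
    for i, (atom, val) in enumerate(zip(basis.atom_index, basis.is_valence)):
        if val:
            e[atom] += per_orbital[i]
            counts[atom] += 1
    return AtomicEnergies(energies=e / z, charges=z.astype(np.int64),
                          valence_counts=counts)


# ------------------------------------------------------------- density grids

@dataclass
class DensityGridSpec:
    origin: np.ndarray            # Bohr
    spacing: float = 1.5          # Bohr, uniform
    shape: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @classmethod
    def bounding(cls, structure: AtomicStructure, margin: float = 4.0,
                 spacing: float = 1.5) -> "DensityGridSpec":
        lo = structure.coords.min(axis=0) - margin
        hi = structure.coords.max(axis=0) + margin
        shape = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1
                      for k in range(3))
        return cls(origin=lo, spacing=spacing, shape=shape)

    def points(self) -> np.ndarray:
        ax = [self.origin[k] + self.spacing * np.arange(self.shape[k])
              for k in range(3)]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)


@dataclass
class DensityGrid:
    spec: DensityGridSpec
    values: np.ndarray            # shape == spec.shape

    def integral(self) -> float:
        return float(self.values.sum() * self.spec.spacing ** 3)


def density_on_grid(result: SCFResult, basis: OrbitalBasis,
                    grid_spec: DensityGridSpec,
                    pair_index: np.ndarray | None = None,
                    valence_only: bool = False,
                    chunk: int = 200_000) -> DensityGrid:
    """Electron density rho(r) = sum_{ab retained} P_ab phi_a phi_b.

    ``pair_index`` (n, 2) restricts the double sum to retained pairs (e.g.
    the density-screen survivors); by default all pairs contribute.
    ``valence_only`` drops core (heavy-atom 1s) contributions for display.
    """
    n = basis.n_bf
    if pair_index is None:
        iu, ju = np.triu_indices(n)
        pair_index = np.stack([iu, ju], axis=1)
    pair_index = np.asarray(pair_index, dtype=np.int64).reshape(-1, 2)
    if valence_only:
        keep = (basis.is_valence[pair_index[:, 0]]
                & basis.is_valence[pair_index[:, 1]])
        pair_index = pair_index[keep]
    pts = grid_spec.points()
    P = result.density_matrix
    out = np.zeros(len(pts))
    for start in range(0, len(pts), chunk):
        block = pts[start:start + chunk]
        if len(pair_index) == 0:
            continue
        used = np.unique(pair_index)
        vals = {a: basis.orbitals[a].evaluate(block) for a in used}
        acc = np.zeros(len(block))
        for a, b in pair_index:
            w = P[a, b] * (2.0 if a != b else 1.0)
            if w != 0.0:
                acc += w * vals[a] * vals[b]
        out[start:start + chunk] = acc
    return DensityGrid(spec=grid_spec, values=out.reshape(grid_spec.shape))
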