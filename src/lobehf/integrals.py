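"""One- and two-electron integrals over lobe s-Gaussians, with screening.

Because every basis function is a signed sum of s-Gaussians, a single set
of closed forms covers all integrals.  The two-electron path goes through
three screens before any ERI is evaluated:

1. *density relevance*: the analytic integral of |phi_i phi_j| (via the
   sign-definite per-lobe representation) must exceed a threshold for both
   the bra and the ket density;
2. *Coulomb distance*: the two density centers (arithmetic means of the
   parent atom positions) must lie within the upper Coulomb cut-off, with a
   smoothstep weight applied between the lower and upper radii;
3. *combined relevance*: the product of the two relevances divided by the
   center distance (floored at 1 Bohr) must exceed a final threshold.

Surviving quadruplets are evaluated from precomputed primitive-pair tables
with the uniform erf-based kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .basis import OrbitalBasis
from .structure import AtomicStructure
from .units import BOHR_PER_ANGSTROM

__all__ = [
    "ScreeningConfig", "PairTable", "ScreenedERISet",
    "overlap_matrix", "kinetic_matrix", "nuclear_attraction_matrix",
    "core_hamiltonian", "dipole_matrices", "erf_approx", "f11",
    "coulomb_weight", "density_relevance", "eri_primitive",
    "build_pair_table", "build_screened_eris", "unique_eri_count",
]

#: combined-relevance distance floor (Bohr); avoids division blow-up at
#: coincident density centers
D_FLOOR_BOHR = 1.0


# ------------------------------------------------------------- configuration

@dataclass
class ScreeningConfig:
    """Thresholds for the three ERI screens.

    Distances are in Angstrom (converted internally); thresholds are
    dimensionless relevance values.  ``disabled()`` turns every screen off,
    which reproduces the unscreened calculation bitwise.
    """

    density_threshold: float = 1e-4
    coulomb_lower: float = 8.0       # Angstrom
    coulomb_upper: float = 10.0      # Angstrom
    combined_relevance_threshold: float = 1e-6
    erf_saturation_x: float = 16.0   # kernel argument; sqrt(x) >= 4

    def __post_init__(self) -> None:
        if not (0.0 < self.coulomb_lower < self.coulomb_upper):
            raise ValueError("require 0 < coulomb_lower < coulomb_upper")
        if min(self.density_threshold, self.combined_relevance_threshold) < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def disabled(cls) -> "ScreeningConfig":
        return cls(density_threshold=0.0, coulomb_lower=1e8,
                   coulomb_upper=1e9, combined_relevance_threshold=0.0)

    @classmethod
    def density_only(cls, density_threshold: float = 1e-4,
                     combined_relevance_threshold: float = 1e-6
                     ) -> "ScreeningConfig":
        """Relevance screens active, Coulomb distance cut-off effectively off.

        The smoothstep-weighted Coulomb kernel is not positive definite, so
        a single SCF spanning well beyond the cut-off radius can become
        variationally unstable.  Density screening keeps a principal
        submatrix of the exact (positive-definite) Coulomb metric and is
        always safe; this is the recommended mode for moderate systems and
        for divide-and-conquer subsystems, where the distance cut-off
        saves little anyway.
        """
        return cls(density_threshold=density_threshold,
                   coulomb_lower=4e2, coulomb_upper=5e2,
                   combined_relevance_threshold=combined_relevance_threshold)


# ----------------------------------------------------------- one-electron API

def _cutoffs_bohr(config: "ScreeningConfig | None") -> tuple[float, float]:
    if config is None:
        return 1e30, 1e31
    return (config.coulomb_lower * BOHR_PER_ANGSTROM,
            config.coulomb_upper * BOHR_PER_ANGSTROM)


def _one_electron(basis: OrbitalBasis, config: "ScreeningConfig | None" = None,
                  nuclei: AtomicStructure | None = None):
    st = nuclei or basis.structure
    r_cl, r_cu = _cutoffs_bohr(config)
    orb_atom_pos = basis.structure.coords[basis.atom_index]
    return kernels.one_electron_matrices(
        basis.prim_offsets, basis.prim_coeff, basis.prim_alpha,
        basis.prim_center, st.coords, st.atomic_numbers.astype(np.float64),
        orb_atom_pos, r_cl, r_cu)


def overlap_matrix(basis: OrbitalBasis) -> np.ndarray:
    if basis.n_bf == 0:
        return np.zeros((0, 0))
    S, _, _ = _one_electron(basis)
    return S


def kinetic_matrix(basis: OrbitalBasis) -> np.ndarray:
    _, T, _ = _one_electron(basis)
    return T


def nuclear_attraction_matrix(basis: OrbitalBasis,
                              nuclei: AtomicStructure | None = None,
                              config: "ScreeningConfig | None" = None
                              ) -> np.ndarray:
    st = nuclei or basis.structure
    if np.any(st.atomic_numbers <= 0):
        raise ValueError("nucleus with non-positive charge")
    _, _, V = _one_electron(basis, config, st)
    return V


def core_hamiltonian(basis: OrbitalBasis,
                     config: "ScreeningConfig | None" = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(S, H) with H = T + V; V carries the Coulomb cut-off weights."""
    S, T, V = _one_electron(basis, config)
    return S, T + V


def nuclear_repulsion_screened(structure: AtomicStructure,
                               config: "ScreeningConfig | None" = None
                               ) -> float:
    """Nuclear repulsion with the same smoothstep Coulomb cut-off.

    Screening the e-e, e-N and N-N terms with one weight keeps the net
    electrostatics of distant neutral groups consistently suppressed; an
    unweighted N-N sum would otherwise dominate the screened total energy.
    """
    r_cl, r_cu = _cutoffs_bohr(config)
    z = structure.atomic_numbers.astype(float)
    e = 0.0
    for i in range(structure.n_atoms):
        d = np.linalg.norm(structure.coords[i + 1:] - structure.coords[i],
                           axis=1)
        w = np.array([kernels.smoothstep_weight(di, r_cl, r_cu) for di in d])
        e += float(np.sum(w * z[i] * z[i + 1:] / d))
    return e


def dipole_matrices(basis: OrbitalBasis) -> np.ndarray:
    """Position-operator matrices <i|r|j>, shape (3, n_bf, n_bf)."""
    return kernels.dipole_matrices(
        basis.prim_offsets, basis.prim_coeff, basis.prim_alpha,
        basis.prim_center)


# -------------------------------------------------------------- scalar kernels

def erf_approx(x):
    """Rational erf approximation with saturation to 1 for x >= 4.

    Only non-negative arguments are meaningful for the integral kernels;
    negative input raises.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("erf_approx requires x >= 0")
    out = np.vectorize(kernels.erf_approx_scalar)(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def f11(x):
    """Confluent hypergeometric kernel F11(1/2, 3/2, -x) for x >= 0."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("f11 requires x >= 0")
    out = np.vectorize(kernels.f11_half)(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def coulomb_weight(d, config: ScreeningConfig):
    """Smoothstep Coulomb weight in [0, 1] for center distance d (Angstrom).

    1 below the lower cut-off, 0 above the upper, and 1 + 2x^3 - 3x^2 on the
    linearly mapped interval between them; C1-continuous at both ends.
    """
    d = np.asarray(d, dtype=float)
    x = np.clip((d - config.coulomb_lower)
                / (config.coulomb_upper - config.coulomb_lower), 0.0, 1.0)
    w = 1.0 + 2.0 * x ** 3 - 3.0 * x ** 2
    return float(w) if w.ndim == 0 else w


# ----------------------------------------------------------------- pair tables

@dataclass
class PairTable:
    """Primitive-pair lookup tables for a list of orbital pairs.

    ``offsets[p]:offsets[p+1]`` indexes the primitive pairs of orbital pair
    p; ``overlap`` carries the kernel prefactor, ``center`` the
    Gaussian-product center (Bohr), ``alpha_sum`` the combined exponent.
    """

    pair_i: np.ndarray
    pair_j: np.ndarray
    offsets: np.ndarray
    overlap: np.ndarray
    center: np.ndarray
    alpha_sum: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)


def build_pair_table(basis: OrbitalBasis, pair_i, pair_j) -> PairTable:
    pair_i = np.asarray(pair_i, dtype=np.int64)
    pair_j = np.asarray(pair_j, dtype=np.int64)
    off, O, cen, psum = kernels.build_pair_table(
        basis.prim_offsets, basis.prim_coeff, basis.prim_alpha,
        basis.prim_center, pair_i, pair_j)
    return PairTable(pair_i, pair_j, off, O, cen, psum)


def eri_primitive(overlap_ab: float, center_ab, alpha_sum_ab: float,
                  overlap_cd: float, center_cd, alpha_sum_cd: float) -> float:
    """Single primitive-pair ERI (g_a g_b | g_c g_d) from pair-table entries."""
    P = alpha_sum_ab * alpha_sum_cd / (alpha_sum_ab + alpha_sum_cd)
    d2 = float(np.sum((np.asarray(center_ab, float)
                       - np.asarray(center_cd, float)) ** 2))
    return overlap_ab * overlap_cd * math.sqrt(P) * kernels.f11_half(P * d2)


def density_relevance(basis: OrbitalBasis, i: int, j: int) -> float:
    """r(rho_ij): analytic integral of |phi_i| |phi_j| (abs-lobe product)."""
    out = kernels.density_relevances(
        basis.abs_offsets, basis.abs_coeff, basis.abs_alpha, basis.abs_center,
        np.array([i], dtype=np.int64), np.array([j], dtype=np.int64))
    return float(out[0])


# ------------------------------------------------------------- screened ERIs

def unique_eri_count(n_bf: int) -> int:
    """Canonical-symmetry unique ERI count m(m+1)/2 with m = n(n+1)/2."""
    m = n_bf * (n_bf + 1) // 2
    return m * (m + 1) // 2


@dataclass
class ScreenedERISet:
    """Surviving canonical ERIs with Coulomb weights and screen counters."""

    n_bf: int
    quads: np.ndarray        # (n, 4) int32, canonical i<=j, k<=l, (ij)<=(kl)
    values: np.ndarray       # unweighted ERI values
    weights: np.ndarray      # smoothstep Coulomb weights in [0, 1]
    n_theoretical: int
    n_unique: int
    n_density_surviving: int
    n_fully_surviving: int
    config: "ScreeningConfig | None" = None
    pair_relevances: np.ndarray = field(default=None, repr=False)
    pair_index: np.ndarray = field(default=None, repr=False)  # (npair, 2)

    def weighted_values(self) -> np.ndarray:
        return self.values * self.weights

    def counters(self) -> dict[str, int]:
        return {"n_theoretical": self.n_theoretical,
                "n_unique": self.n_unique,
                "n_density_surviving": self.n_density_surviving,
                "n_fully_surviving": self.n_fully_surviving}

    def dump(self, path) -> None:
        """Debug dump: per record 4 x int32 indices, float64 value,
        float32 weight (little-endian, no header)."""
        rec = np.dtype([("quad", "<i4", 4), ("value", "<f8"),
                        ("weight", "<f4")])
        out = np.empty(len(self.values), dtype=rec)
        out["quad"] = self.quads
        out["value"] = self.values
        out["weight"] = self.weights
        out.tofile(str(path))


def surviving_density_pairs(basis: OrbitalBasis, config: ScreeningConfig
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                       np.ndarray]:
    """Orbital pairs passing the density-relevance screen.

    Returns (pair_i, pair_j, relevance, centers_bohr); centers are the
    arithmetic means of the two parent atom positions.
    """
    n = basis.n_bf
    iu, ju = np.triu_indices(n)
    iu = iu.astype(np.int64)
    ju = ju.astype(np.int64)
    rel = kernels.density_relevances(
        basis.abs_offsets, basis.abs_coeff, basis.abs_alpha, basis.abs_center,
        iu, ju)
    keep = rel > config.density_threshold
    iu, ju, rel = iu[keep], ju[keep], rel[keep]
    coords = basis.structure.coords
    centers = 0.5 * (coords[basis.atom_index[iu]]
                     + coords[basis.atom_index[ju]])
    return iu, ju, rel, centers


def build_screened_eris(basis: OrbitalBasis,
                        config: ScreeningConfig | None = None
                        ) -> ScreenedERISet:
    """Run all three screens and evaluate the surviving ERIs."""
    config = config or ScreeningConfig()
    n = basis.n_bf
    n_theoretical = n ** 4
    n_unique = unique_eri_count(n)
    if n == 0:
        z = np.zeros(0)
        return ScreenedERISet(0, np.zeros((0, 4), np.int32), z, z,
                              0, 0, 0, 0, config, z,
                              np.zeros((0, 2), np.int64))
    pi, pj, rel, centers = surviving_density_pairs(basis, config)
    npair = len(pi)
    n_density_surviving = npair * (npair + 1) // 2
    r_cu_bohr = config.coulomb_upper * BOHR_PER_ANGSTROM
    qp, qq, dist = kernels.select_eri_quads(
        centers, rel, r_cu_bohr, config.combined_relevance_threshold,
        D_FLOOR_BOHR)
    table = build_pair_table(basis, pi, pj)
    values = kernels.eri_from_pairs(table.offsets, table.overlap,
                                    table.center, table.alpha_sum, qp, qq)
    from .units import ANGSTROM_PER_BOHR
    weights = coulomb_weight(dist * ANGSTROM_PER_BOHR, config)
    weights = np.atleast_1d(np.asarray(weights, float))
    quads = np.empty((len(qp), 4), dtype=np.int32)
    quads[:, 0] = pi[qp]
    quads[:, 1] = pj[qp]
    quads[:, 2] = pi[qq]
    quads[:, 3] = pj[qq]
    return ScreenedERISet(
        n_bf=n, quads=quads, values=values, weights=weights,
        n_theoretical=n_theoretical, n_unique=n_unique,
        n_density_surviving=n_density_surviving,
        n_fully_surviving=len(values), config=config,
        pair_relevances=rel, pair_index=np.stack([pi, pj], axis=1))


def two_electron_matrix(eris: ScreenedERISet, P: np.ndarray) -> np.ndarray:
    """G(P) = J - K/2 assembled from the weighted screened ERI list."""
    q = eris.quads
    return kernels.fock_two_electron(
        eris.n_bf, q[:, 0].astype(np.int64), q[:, 1].astype(np.int64),
        q[:, 2].astype(np.int64), q[:, 3].astype(np.int64),
        eris.weighted_values(), np.ascontiguousarray(P))
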