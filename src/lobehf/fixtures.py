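"""Seeded generators for test and demonstration systems.

Everything the package needs to exercise its pipelines is generated here:
hard-coded standard small-molecule geometries, idealized homologous chains
(alkanes, polyenes, polyglycine), rejection-sampled water shells, and a
"quality gradient" peptide whose tail carries seeded coordinate disorder
plus a synthetic pLDDT-like confidence track.  All generators are
deterministic given their spec and seed.
"""

from __future__ import annotations

import numpy as np

from .structure import AtomicStructure
from .units import BOHR_PER_ANGSTROM

__all__ = ["make_molecule", "make_chain", "make_water_shell",
           "make_quality_gradient_peptide", "make_assessment_fixture",
           "make_stoichiometric"]


def _deg(x):
    return np.deg2rad(x)


# hard-coded geometries (Angstrom): standard experimental/idealized values
# (H2 0.74; water r=0.9572, a=104.52; CH4 r=1.089 tetrahedral; NH3 r=1.012,
# a=106.7; ethylene C=C 1.339; ethane C-C 1.536 staggered; benzene C-C 1.39)
def _h2():
    return ["H", "H"], [[0, 0, 0], [0, 0, 0.74]]


def _h2o():
    r, a = 0.9572, _deg(104.52)
    return ["O", "H", "H"], [
        [0, 0, 0],
        [r * np.sin(a / 2), 0, r * np.cos(a / 2)],
        [-r * np.sin(a / 2), 0, r * np.cos(a / 2)],
    ]


def _ch4():
    r = 1.089
    t = r / np.sqrt(3.0)
    return ["C", "H", "H", "H", "H"], [
        [0, 0, 0], [t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t]]


def _nh3():
    r, a = 1.012, _deg(106.7)
    # pyramidal: three H at a common polar angle below the N
    cos_t = np.sqrt(max(0.0, (1 + 2 * np.cos(a)) / 3.0))
    sin_t = np.sqrt(1 - cos_t ** 2)
    hs = [[r * sin_t * np.cos(p), r * sin_t * np.sin(p), -r * cos_t]
          for p in (0, 2 * np.pi / 3, 4 * np.pi / 3)]
    return ["N", "H", "H", "H"], [[0, 0, 0]] + hs


def _ethylene():
    cc, ch, hcc = 1.339, 1.087, _deg(121.3)
    x = cc / 2
    # H direction makes the H-C=C angle with the bond toward the other C
    hx = x - ch * np.cos(hcc)      # cos(121.3) < 0: H points outward
    hy = ch * np.sin(hcc)
    return (["C", "C", "H", "H", "H", "H"],
            [[-x, 0, 0], [x, 0, 0],
             [-hx, hy, 0], [-hx, -hy, 0], [hx, hy, 0], [hx, -hy, 0]])


def _ethane():
    cc, ch, ang = 1.536, 1.091, _deg(111.2)
    z = cc / 2
    ct = np.cos(np.pi - ang)
    st = np.sin(np.pi - ang)
    tops = [[ch * st * np.cos(p), ch * st * np.sin(p), z + ch * ct]
            for p in (0, 2 * np.pi / 3, 4 * np.pi / 3)]
    bots = [[ch * st * np.cos(p), ch * st * np.sin(p), -z - ch * ct]
            for p in (np.pi / 3, np.pi, 5 * np.pi / 3)]
    return (["C", "C"] + ["H"] * 6,
            [[0, 0, z], [0, 0, -z]] + tops + bots)


def _benzene():
    cc, ch = 1.39, 1.09
    rc = cc / (2 * np.sin(np.pi / 6))
    rh = rc + ch
    els, pos = [], []
    for k in range(6):
        p = k * np.pi / 3
        els.append("C")
        pos.append([rc * np.cos(p), rc * np.sin(p), 0])
    for k in range(6):
        p = k * np.pi / 3
        els.append("H")
        pos.append([rh * np.cos(p), rh * np.sin(p), 0])
    return els, pos


_MOLECULES = {"H2": _h2, "H2O": _h2o, "CH4": _ch4, "NH3": _nh3,
              "ethylene": _ethylene, "ethane": _ethane, "benzene": _benzene}


def make_molecule(name: str) -> AtomicStructure:
    """A hard-coded standard small-molecule geometry."""
    key = {"water": "H2O", "methane": "CH4", "ammonia": "NH3"}.get(name, name)
    if key not in _MOLECULES:
        raise KeyError(f"unknown molecule {name!r}; "
                       f"available: {sorted(_MOLECULES)}")
    els, pos = _MOLECULES[key]()
    return AtomicStructure.from_angstrom(els, pos, provenance=f"fixture:{key}")


# ------------------------------------------------------------------- chains

def _zigzag_backbone(n: int, bond: float | list, angle: float) -> np.ndarray:
    """Planar all-trans zigzag of n atoms in the xz plane (Angstrom)."""
    half = _deg(angle) / 2.0
    pos = np.zeros((n, 3))
    x = 0.0
    for i in range(1, n):
        b = bond[(i - 1) % len(bond)] if isinstance(bond, list) else bond
        x += b * np.sin(half)
        pos[i, 0] = x
        pos[i, 2] = b * np.cos(half) * (i % 2)
    return pos


_Y = np.array([0.0, 1.0, 0.0])


def _unit(v):
    return v / np.linalg.norm(v)


def _terminal_hydrogens(c, u, ch, n_h, phase=0.0, angle_deg=109.47):
    """n_h hydrogens around carbon c, each at ``angle_deg`` from the bond
    direction u (unit vector toward the backbone neighbour)."""
    th = _deg(angle_deg)
    p1 = _unit(np.cross(u, _Y))
    out = []
    for k in range(n_h):
        phi = phase + 2 * np.pi * k / max(n_h, 2) * (1 if n_h > 1 else 0)
        d = np.cos(th) * u + np.sin(th) * (np.cos(phi) * p1
                                           + np.sin(phi) * _Y)
        out.append(c + ch * d)
    return out


def _alkane(n: int) -> tuple[list[str], np.ndarray]:
    """All-trans C_n H_{2n+2}; hydrogens from local tetrahedral frames."""
    cc, ch, ccc = 1.54, 1.09, 111.7
    hch = _deg(107.8)
    c = _zigzag_backbone(n, cc, ccc)
    els = ["C"] * n
    pos = [c[i] for i in range(n)]
    if n == 1:
        els1, pos1 = _ch4()
        return els1, np.array(pos1)
    for i in range(n):
        if 0 < i < n - 1:
            u1 = _unit(c[i - 1] - c[i])
            u2 = _unit(c[i + 1] - c[i])
            b = _unit(-(u1 + u2))
            for sy in (1.0, -1.0):
                d = _unit(np.cos(hch / 2) * b + sy * np.sin(hch / 2) * _Y)
                els.append("H")
                pos.append(c[i] + ch * d)
        else:
            nb = 1 if i == 0 else n - 2
            u = _unit(c[nb] - c[i])
            phase = 0.0 if i == 0 else np.pi / 3
            for h in _terminal_hydrogens(c[i], u, ch, 3, phase=phase):
                els.append("H")
                pos.append(h)
    return els, np.array(pos)


def _polyene(n: int) -> tuple[list[str], np.ndarray]:
    """All-trans conjugated chain C_{2n} H_{2n+2}, alternating 1.34/1.45.

    sp2 carbons: in-chain hydrogens sit on the in-plane bisector; terminal
    carbons carry a planar CH2 group.
    """
    nc = 2 * n
    c = _zigzag_backbone(nc, [1.34, 1.45], 124.0)
    els = ["C"] * nc
    pos = [c[i] for i in range(nc)]
    ch = 1.085
    for i in range(nc):
        if 0 < i < nc - 1:
            u1 = _unit(c[i - 1] - c[i])
            u2 = _unit(c[i + 1] - c[i])
            els.append("H")
            pos.append(c[i] + ch * _unit(-(u1 + u2)))
        else:
            nb = 1 if i == 0 else nc - 2
            u = _unit(c[nb] - c[i])
            # planar CH2: two in-plane H at ~120 degrees from the C-C bond
            p1 = _unit(np.cross(np.cross(u, _Y), u))   # in-plane, normal to u
            for sy in (1.0, -1.0):
                d = np.cos(_deg(121.0)) * u + sy * np.sin(_deg(121.0)) * p1
                els.append("H")
                pos.append(c[i] + ch * _unit(d))
    return els, np.array(pos)


def _polyglycine(n: int) -> tuple[list[str], np.ndarray, list]:
    """Idealized extended polyglycine: N-CA-C(=O) repeats, NH2/COOH termini.

    The backbone is built sequentially in the xz plane with bond directions
    alternating +-35 degrees from the chain axis, which gives exact standard
    bond lengths (N-CA 1.46, CA-C 1.52, C-N 1.33 A) and ~110 degree angles.
    Good enough for covalent topology and electronic-structure tests, not a
    relaxed conformer.
    """
    els: list[str] = []
    pos: list[np.ndarray] = []
    res: list[tuple[str, int, str]] = []

    def add(el, p, i):
        els.append(el)
        pos.append(np.asarray(p, float))
        res.append(("A", i + 1, "GLY"))

    th = _deg(35.0)
    d_up = np.array([np.cos(th), 0.0, np.sin(th)])
    d_dn = np.array([np.cos(th), 0.0, -np.sin(th)])
    up = np.array([0.0, 0.0, 1.0])
    cur = np.zeros(3)          # current N position
    direction_up = True        # next backbone bond direction
    for i in range(n):
        d1 = d_up if direction_up else d_dn      # N -> CA
        d2 = d_dn if direction_up else d_up      # CA -> C
        d3 = d_up if direction_up else d_dn      # C -> N(next)
        zsign = 1.0 if direction_up else -1.0
        N = cur
        CA = N + 1.46 * d1
        C = CA + 1.52 * d2
        add("N", N, i)
        # amide H: in-plane, opposite the carbonyl side
        add("H", N + 1.01 * np.array([0.0, 0.0, -zsign]), i)
        if i == 0:
            add("H", N - 1.01 * d1, i)           # N-terminal second H
        add("C", CA, i)
        for sy in (1.0, -1.0):
            add("H", CA + 1.09 * np.array([0.0, sy * 0.894,
                                           0.447 * zsign]), i)
        add("C", C, i)
        add("O", C + 1.23 * np.array([0.0, 0.0, -zsign]), i)
        cur = C + 1.33 * d3
        direction_up = not direction_up
    # C-terminal hydroxyl replaces the next nitrogen
    last_up = not direction_up                   # flag during the last residue
    d3 = d_up if last_up else d_dn               # last C -> next-N direction
    d4 = d_dn if last_up else d_up               # continuing zigzag for O-H
    OH = pos[-2] + 1.36 * d3
    add("O", OH, n - 1)
    add("H", OH + 0.96 * d4, n - 1)
    return els, np.array(pos), res


def make_chain(kind: str, n: int, seed: int = 0) -> AtomicStructure:
    """Idealized homologous chain: 'alkane', 'polyene' or 'polyglycine'."""
    if n <= 0:
        raise ValueError("n must be positive")
    if kind == "alkane":
        els, pos = _alkane(n)
        res = None
    elif kind == "polyene":
        els, pos = _polyene(n)
        res = None
    elif kind == "polyglycine":
        els, pos, res = _polyglycine(n)
    else:
        raise KeyError(f"unknown chain kind {kind!r}")
    return AtomicStructure.from_angstrom(
        els, pos, residue_ids=res, provenance=f"fixture:{kind}({n})")


# -------------------------------------------------------------- water shells

_WATER_TEMPLATE = np.array([[0.0, 0.0, 0.0],
                            [0.9572 * np.sin(_deg(52.26)), 0.0,
                             0.9572 * np.cos(_deg(52.26))],
                            [-0.9572 * np.sin(_deg(52.26)), 0.0,
                             0.9572 * np.cos(_deg(52.26))]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def make_water_shell(solute: AtomicStructure, thickness: float,
                     min_dist: float = 2.4, seed: int = 0,
                     max_attempts_per_water: int = 200) -> AtomicStructure:
    """Surround a solute with rigid waters in a shell of given thickness (A).

    Water oxygens are placed by seeded rejection sampling between the
    solute surface and surface + thickness; no atom of an accepted water
    comes closer than ``min_dist`` (A) to any already-placed atom.
    """
    if thickness <= 0:
        return solute
    rng = np.random.default_rng(seed)
    sol = solute.coords_angstrom
    lo = sol.min(axis=0) - thickness - 2.0
    hi = sol.max(axis=0) + thickness + 2.0
    els = list(solute.elements)
    pos = [p for p in sol]
    all_pos = np.array(pos)
    # target count from shell volume at ~0.033 waters/A^3 (ambient density)
    from scipy.spatial import cKDTree
    tree = cKDTree(sol)
    vol_box = np.prod(hi - lo)
    n_target = int(0.0334 * vol_box)   # upper bound; rejection trims it
    placed = 0
    attempts = 0
    max_attempts = n_target * max_attempts_per_water
    while attempts < max_attempts:
        attempts += 1
        o = lo + rng.random(3) * (hi - lo)
        d_surf = tree.query(o)[0]
        if not (0.0 < d_surf <= thickness):
            continue
        R = _random_rotation(rng)
        w = _WATER_TEMPLATE @ R.T + o
        d = np.linalg.norm(all_pos[:, None, :] - w[None, :, :], axis=2)
        if d.min() < min_dist:
            continue
        els.extend(["O", "H", "H"])
        pos.extend(w)
        all_pos = np.vstack([all_pos, w])
        placed += 1
    return AtomicStructure.from_angstrom(
        els, np.array(pos),
        provenance=f"{solute.provenance}+water_shell({thickness}A,{placed})")


# ---------------------------------------------------- quality-gradient chain

def make_quality_gradient_peptide(n: int, disorder_fraction: float = 0.4,
                                  seed: int = 0, max_sigma: float = 0.3
                                  ) -> tuple[AtomicStructure, np.ndarray]:
    """A toy peptide with an ordered head and a disordered tail.

    The first (1 - f) fraction of atoms keeps the ideal geometry; the last
    f fraction receives Gaussian coordinate jitter ramping up to
    ``max_sigma`` (A) toward the terminus — a stand-in for the
    low-confidence regions of predicted models, not a model of any
    predictor's error statistics.  A synthetic pLDDT-like track (high at
    the head, low at the tail, monotone non-increasing) is planted in the
    B-factor slot and returned alongside.
    """
    if not (0.0 <= disorder_fraction <= 1.0):
        raise ValueError("disorder_fraction must be in [0, 1]")
    base = make_chain("polyglycine", n)
    rng = np.random.default_rng(seed)
    n_at = base.n_atoms
    frac = np.arange(n_at) / max(n_at - 1, 1)
    start = 1.0 - disorder_fraction
    ramp = np.clip((frac - start) / max(disorder_fraction, 1e-12), 0.0, 1.0)
    sigma = max_sigma * ramp
    jitter = rng.normal(size=(n_at, 3)) * sigma[:, None] * BOHR_PER_ANGSTROM
    coords = base.coords + jitter
    plddt = 90.0 - 55.0 * ramp            # 90 head -> 35 tail, non-increasing
    st = AtomicStructure(base.elements, coords, b_factors=plddt.copy(),
                         residue_ids=base.residue_ids,
                         provenance=f"fixture:quality_peptide({n},"
                                    f"{disorder_fraction},{seed})")
    return st, plddt


def make_assessment_fixture(seed: int = 0, n_residues: int = 6,
                            disorder_fraction: float = 0.4,
                            shell_thickness: float = 2.8,
                            shell_min_dist: float = 2.55
                            ) -> tuple[AtomicStructure, AtomicStructure,
                                       np.ndarray]:
    """The canonical structure-assessment test system.

    A quality-gradient glycine peptide solvated in a thin water shell —
    the desk-scale analogue of scoring a solvated predicted structure.
    Solvation matters: without it, chain-end effects dominate the per-atom
    energies.  Returns (bare peptide, solvated system, planted track).
    """
    peptide, track = make_quality_gradient_peptide(
        n_residues, disorder_fraction, seed=seed)
    solvated = make_water_shell(peptide, shell_thickness,
                                min_dist=shell_min_dist, seed=seed)
    return peptide, solvated, track


def make_stoichiometric(formula_counts: dict[str, int], spacing: float = 4.0,
                        seed: int = 0) -> AtomicStructure:
    """Atoms of a given stoichiometry on a jittered cubic lattice.

    Useful for counting exercises (basis sizes, ERI combinatorics) where
    only the molecular formula matters, not a physical geometry.
    """
    els = [el for el, c in sorted(formula_counts.items()) for _ in range(c)]
    n = len(els)
    side = int(np.ceil(n ** (1.0 / 3.0)))
    rng = np.random.default_rng(seed)
    pts = []
    for i in range(n):
        iz, rem = divmod(i, side * side)
        iy, ix = divmod(rem, side)
        pts.append((np.array([ix, iy, iz]) * spacing
                    + 0.1 * rng.standard_normal(3)))
    return AtomicStructure.from_angstrom(els, np.array(pts),
                                         provenance="fixture:stoichiometric")
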