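"""Structure readers/writers, cube files, and run configuration.

PDB and mmCIF go through gemmi; XYZ is read directly (the format is three
whitespace columns plus a symbol).  Coordinates are converted to Bohr on
read.  Density grids are written in Gaussian cube format (Bohr, z-fastest
value order) and round-trip bitwise.
"""

from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np

from .scf import DensityGrid, DensityGridSpec
from .structure import ATOMIC_NUMBERS, SYMBOLS, AtomicStructure
from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM

logger = logging.getLogger(__name__)

__all__ = ["read_structure", "write_structure", "read_xyz", "write_xyz",
           "write_cube", "read_cube", "RunConfig", "load_run_config"]


def _normalize_element(raw: str) -> str:
    s = raw.strip()
    if not s:
        raise ValueError("empty element symbol")
    s = s[0].upper() + s[1:].lower()
    if s not in ATOMIC_NUMBERS:
        raise ValueError(f"unknown element symbol {raw!r}")
    return s


# ------------------------------------------------------------------------ XYZ

def read_xyz(path) -> AtomicStructure:
    lines = pathlib.Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: first line must be the atom count")
    els, pos = [], []
    for ln, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected 'El x y z'")
        try:
            els.append(_normalize_element(parts[0]))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: {exc}") from exc
        pos.append([float(v) for v in parts[1:4]])
    if len(els) != n:
        raise ValueError(f"{path}: expected {n} atoms, found {len(els)}")
    if n == 0:
        raise ValueError(f"{path}: empty model")
    return AtomicStructure.from_angstrom(els, np.array(pos),
                                         provenance=str(path))


def write_xyz(structure: AtomicStructure, path, comment: str = "") -> None:
    lines = [str(structure.n_atoms), comment.replace("\n", " ")]
    for el, p in zip(structure.elements, structure.coords_angstrom):
        lines.append(f"{el:2s} {p[0]:15.8f} {p[1]:15.8f} {p[2]:15.8f}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ PDB/mmCIF

def _read_gemmi(path, fmt: str) -> AtomicStructure:
    import gemmi
    if fmt == "pdb":
        st = gemmi.read_pdb(str(path))
    else:
        st = gemmi.make_structure_from_block(
            gemmi.cif.read(str(path)).sole_block())
    if len(st) == 0:
        raise ValueError(f"{path}: empty model")
    model = st[0]
    els, pos, bfs, rids = [], [], [], []
    n_alt_dropped = 0
    hetatm_water = 0
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "A", "\0"):
                    n_alt_dropped += 1
                    continue
                sym = atom.element.name
                if sym == "X" or not sym:
                    raise ValueError(
                        f"{path}: unknown element for atom {atom.name!r} in "
                        f"residue {residue.name} {residue.seqid.num}")
                els.append(_normalize_element(sym))
                pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                bfs.append(atom.b_iso)
                rids.append((chain.name, residue.seqid.num, residue.name))
                if residue.name in ("HOH", "WAT"):
                    hetatm_water += 1
    if n_alt_dropped:
        logger.warning("%s: dropped %d non-A altloc atoms", path,
                       n_alt_dropped)
    if not els:
        raise ValueError(f"{path}: empty model")
    if "H" not in els:
        logger.warning("%s: no hydrogens found; heavy-atom-only input "
                       "(protonation is not added automatically)", path)
    return AtomicStructure.from_angstrom(
        els, np.array(pos), b_factors=np.array(bfs), residue_ids=rids,
        provenance=str(path))


def read_structure(path, format: str | None = None) -> AtomicStructure:
    """Read a structure from PDB, mmCIF or XYZ (format inferred from suffix).

    Altloc A is kept (others dropped with a warning), HETATM water is
    retained, pLDDT-style B-factors are preserved, and coordinates are
    converted to Bohr.
    """
    path = pathlib.Path(path)
    fmt = format or {".pdb": "pdb", ".ent": "pdb", ".cif": "mmcif",
                     ".mmcif": "mmcif", ".xyz": "xyz"}.get(
                         path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer format of {path}")
    if fmt == "xyz":
        return read_xyz(path)
    if fmt in ("pdb", "mmcif"):
        return _read_gemmi(path, fmt)
    raise ValueError(f"unsupported format {fmt!r}")


def write_structure(structure: AtomicStructure, path) -> None:
    """Write XYZ or PDB depending on suffix."""
    path = pathlib.Path(path)
    if path.suffix.lower() == ".xyz":
        write_xyz(structure, path, comment=structure.provenance)
        return
    if path.suffix.lower() != ".pdb":
        raise ValueError(f"unsupported output format {path.suffix!r}")
    import gemmi
    st = gemmi.Structure()
    st.name = "lobehf"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    coords = structure.coords_angstrom
    for i, (el, p) in enumerate(zip(structure.elements, coords)):
        rid = (structure.residue_ids[i] if structure.residue_ids
               else ("A", i + 1, "UNK"))
        if len(chain) == 0 or chain[-1].seqid.num != rid[1]:
            res = gemmi.Residue()
            res.name = rid[2]
            res.seqid = gemmi.SeqId(int(rid[1]), " ")
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = f"{el}{i % 100}"
        atom.element = gemmi.Element(el)
        atom.pos = gemmi.Position(*p)
        if structure.b_factors is not None:
            atom.b_iso = float(structure.b_factors[i])
        chain[-1].add_atom(atom)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ----------------------------------------------------------------- cube files

def write_cube(grid: DensityGrid, structure: AtomicStructure, path,
               comment: str = "electron density") -> None:
    """Standard Gaussian cube: Bohr units, values z-fastest."""
    spec = grid.spec
    n = structure.n_atoms
    lines = ["lobehf cube file", comment,
             f"{n:5d} {spec.origin[0]:12.6f} {spec.origin[1]:12.6f} "
             f"{spec.origin[2]:12.6f}"]
    for k in range(3):
        vec = [0.0, 0.0, 0.0]
        vec[k] = spec.spacing
        lines.append(f"{spec.shape[k]:5d} {vec[0]:12.6f} {vec[1]:12.6f} "
                     f"{vec[2]:12.6f}")
    z = structure.atomic_numbers
    for zi, p in zip(z, structure.coords):
        lines.append(f"{zi:5d} {float(zi):12.6f} {p[0]:12.6f} {p[1]:12.6f} "
                     f"{p[2]:12.6f}")
    vals = grid.values.reshape(spec.shape)
    for ix in range(spec.shape[0]):
        for iy in range(spec.shape[1]):
            row = vals[ix, iy, :]
            for start in range(0, len(row), 6):
                lines.append(" ".join(f"{v: .5E}"
                                      for v in row[start:start + 6]))
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path) -> tuple[DensityGrid, AtomicStructure]:
    lines = pathlib.Path(path).read_text().splitlines()
    n_atoms = int(lines[2].split()[0])
    origin = np.array([float(v) for v in lines[2].split()[1:4]])
    shape = []
    spacing = None
    for k in range(3):
        parts = lines[3 + k].split()
        shape.append(int(parts[0]))
        vec = np.array([float(v) for v in parts[1:4]])
        if spacing is None:
            spacing = float(np.max(np.abs(vec)))
    els, pos = [], []
    for i in range(n_atoms):
        parts = lines[6 + i].split()
        els.append(SYMBOLS[int(parts[0])])
        pos.append([float(v) for v in parts[2:5]])
    vals = []
    for line in lines[6 + n_atoms:]:
        vals.extend(float(v) for v in line.split())
    spec = DensityGridSpec(origin=origin, spacing=spacing,
                           shape=tuple(shape))
    grid = DensityGrid(spec=spec, values=np.array(vals).reshape(shape))
    structure = AtomicStructure(els, np.array(pos), provenance=str(path))
    return grid, structure


# -------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Validated run configuration mirroring the per-module configs."""

    screening: dict = field(default_factory=dict)
    scf: dict = field(default_factory=dict)
    partition: dict = field(default_factory=dict)
    pulse: dict = field(default_factory=dict)
    propagation: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def build(self):
        """Instantiate the typed config objects (validates all fields)."""
        from .integrals import ScreeningConfig
        from .partition import PartitionConfig
        from .rttdhf import PropagationParams, PulseParams
        from .scf import SCFConfig
        return {
            "screening": ScreeningConfig(**self.screening),
            "scf": SCFConfig(**self.scf),
            "partition": PartitionConfig(**self.partition),
            "pulse": PulseParams(**self.pulse),
            "propagation": PropagationParams(**self.propagation),
        }


def load_run_config(path) -> RunConfig:
    """Read a TOML run configuration and validate it."""
    import tomllib
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    known = {"screening", "scf", "partition", "pulse", "propagation",
             "seed", "output_dir"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg = RunConfig(**doc)
    cfg.build()   # raises on invalid fields
    return cfg
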