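"""Atomic structures: the in-memory container shared by all modules.

Coordinates are stored in Bohr; readers convert from Angstrom at the
boundary.  Optional per-atom metadata (B-factor / pLDDT, residue and chain
labels) is carried along for the structure-assessment pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM

#: element symbol -> atomic number, for the elements this package supports
#: (minimal-basis quantum regions plus the heteroatoms seen in bond tables)
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "P": 15, "S": 16, "Cl": 17,
    "K": 19, "Ca": 20, "Fe": 26, "Zn": 30,
}
SYMBOLS = {z: s for s, z in ATOMIC_NUMBERS.items()}


@dataclass
class AtomicStructure:
    """A molecular structure with optional per-atom annotations.

    Parameters
    ----------
    elements:
        Element symbols, one per atom.
    coords:
        ``(n, 3)`` array of positions in **Bohr**.
    b_factors:
        Optional per-atom B-factor column; for predicted models this slot
        carries the pLDDT confidence score.
    """

    elements: list[str]
    coords: np.ndarray
    b_factors: np.ndarray | None = None
    residue_ids: list[tuple[str, int, str]] | None = None  # (chain, resseq, resname)
    provenance: str = ""
    charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for sym in self.elements:
            if sym not in ATOMIC_NUMBERS:
                raise ValueError(f"unknown element symbol {sym!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[s] for s in self.elements], dtype=np.int64)

    @property
    def n_electrons(self) -> int:
        return int(self.atomic_numbers.sum()) - self.charge

    @property
    def coords_angstrom(self) -> np.ndarray:
        return self.coords * ANGSTROM_PER_BOHR

    @classmethod
    def from_angstrom(
        cls, elements: list[str], coords_angstrom, **kwargs
    ) -> "AtomicStructure":
        coords = np.asarray(coords_angstrom, dtype=float) * BOHR_PER_ANGSTROM
        return cls(list(elements), coords, **kwargs)

    def nuclear_repulsion(self) -> float:
        """Point-charge nuclear repulsion energy in Hartree."""
        z = self.atomic_numbers.astype(float)
        e = 0.0
        for i in range(self.n_atoms):
            d = np.linalg.norm(self.coords[i + 1:] - self.coords[i], axis=1)
            e += float(np.sum(z[i] * z[i + 1:] / d))
        return e

    def subset(self, indices) -> "AtomicStructure":
        idx = list(indices)
        return AtomicStructure(
            [self.elements[i] for i in idx],
            self.coords[idx],
            b_factors=None if self.b_factors is None else self.b_factors[idx],
            residue_ids=None
            if self.residue_ids is None
            else [self.residue_ids[i] for i in idx],
            provenance=self.provenance,
        )

    def translated(self, shift_bohr) -> "AtomicStructure":
        return AtomicStructure(
            list(self.elements),
            self.coords + np.asarray(shift_bohr, dtype=float),
            b_factors=self.b_factors,
            residue_ids=self.residue_ids,
            provenance=self.provenance,
            charge=self.charge,
        )
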