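"""Atomic structure loading (PDB/mmCIF via biotite).

Coordinates are kept in ångströms — the native unit of the formats — and
converted at the rasterization boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mcart.errors import FormatError


@dataclass
class AtomicStructure:
    """Flat atom table of one complex.

    Attributes
    ----------
    coords_A:
        ``(N, 3)`` atom positions in ångströms, ``(x, y, z)``.
    elements, chain_ids:
        Per-atom element symbols and chain identifiers.
    occupancy:
        Per-atom occupancies (1.0 when the file omits them).
    """

    coords_A: np.ndarray
    elements: np.ndarray
    chain_ids: np.ndarray
    occupancy: np.ndarray = field(default=None)  # type: ignore[assignment]
    res_names: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords_A = np.asarray(self.coords_A, dtype=float)
        if self.coords_A.ndim != 2 or self.coords_A.shape[1] != 3:
            raise ValueError("coords_A must have shape (N, 3)")
        if len(self.coords_A) == 0:
            raise FormatError("structure contains zero atoms")
        if not np.all(np.isfinite(self.coords_A)):
            raise FormatError("structure contains non-finite coordinates")
        self.elements = np.asarray(self.elements)
        self.chain_ids = np.asarray(self.chain_ids)
        if self.occupancy is None:
            self.occupancy = np.ones(len(self.coords_A))
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.res_names is None:
            self.res_names = np.full(len(self.coords_A), "UNK")
        self.res_names = np.asarray(self.res_names)

    @property
    def n_atoms(self) -> int:
        return len(self.coords_A)

    @property
    def chains(self) -> list[str]:
        return sorted(set(self.chain_ids.tolist()))

    def centroid_A(self) -> np.ndarray:
        return self.coords_A.mean(axis=0)

    def select_chains(self, chains) -> "AtomicStructure":
        """Subset of atoms whose chain ID is in ``chains``."""
        mask = np.isin(self.chain_ids, list(chains))
        if not mask.any():
            raise FormatError(f"no atoms left after selecting chains {sorted(chains)}")
        return AtomicStructure(
            self.coords_A[mask],
            self.elements[mask],
            self.chain_ids[mask],
            self.occupancy[mask],
            self.res_names[mask],
        )

    def translated(self, shift_A) -> "AtomicStructure":
        return AtomicStructure(
            self.coords_A + np.asarray(shift_A, dtype=float),
            self.elements,
            self.chain_ids,
            self.occupancy,
            self.res_names,
        )

    def rotated(self, matrix: np.ndarray) -> "AtomicStructure":
        """Rotate about the centroid by a 3x3 matrix."""
        c = self.centroid_A()
        return AtomicStructure(
            (self.coords_A - c) @ np.asarray(matrix, dtype=float).T + c,
            self.elements,
            self.chain_ids,
            self.occupancy,
            self.res_names,
        )


def read_structure(path: str | Path, model: int = 1) -> AtomicStructure:
    """Read a PDB or mmCIF file into an :class:`AtomicStructure`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".pdb", ".ent"}:
        from biotite.structure.io.pdb import PDBFile

        atoms = PDBFile.read(str(path)).get_structure(model=model)
    elif suffix in {".cif", ".mmcif", ".pdbx"}:
        from biotite.structure.io.pdbx import CIFFile, get_structure

        atoms = get_structure(CIFFile.read(str(path)), model=model)
    else:
        raise FormatError(f"{path}: unrecognized structure format {suffix!r}")

    if atoms.array_length() == 0:
        raise FormatError(f"{path}: structure contains zero atoms")
    occupancy = (
        np.asarray(atoms.occupancy, dtype=float)
        if "occupancy" in atoms.get_annotation_categories()
        else np.ones(atoms.array_length())
    )
    return AtomicStructure(
        coords_A=np.asarray(atoms.coord, dtype=float),
        elements=np.asarray(atoms.element),
        chain_ids=np.asarray(atoms.chain_id),
        occupancy=occupancy,
        res_names=np.asarray(atoms.res_name),
    )
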