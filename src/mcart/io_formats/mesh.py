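"""Oriented triangle meshes and Wavefront OBJ I/O.

All mesh coordinates held in memory are nanometres. OBJ files carry no unit
metadata, so the caller must declare the file's units explicitly
(``"nm"``, ``"angstrom"`` or ``"voxel"`` with a voxel size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mcart.errors import FormatError, GeometryError

_UNIT_SCALE_NM = {"nm": 1.0, "angstrom": 0.1}


def triangle_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-face (non-unit) normals: 0.5 * (b-a) x (c-a); norm = triangle area."""
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.cross(b - a, c - a)


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted unit vertex normals."""
    fn = triangle_normals(vertices, faces)
    vn = np.zeros_like(vertices)
    for i in range(3):
        np.add.at(vn, faces[:, i], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vn / norms


@dataclass
class MembraneSurface:
    """Oriented triangle mesh of one membrane region.

    ``normals`` follow the convention that they point from the membrane toward
    the stromal side (use :func:`flip` to change orientation). Coordinates in
    nanometres.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None
    membrane_id: str = ""
    region_class: str | None = None  # "appressed" | "non_appressed"
    side: str | None = None  # "stromal" | "luminal" when side-specific
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must have shape (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be triangles with shape (M, 3)")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_normals(self) -> "MembraneSurface":
        """Return self, computing area-weighted vertex normals if absent."""
        if self.normals is None:
            self.normals = vertex_normals(self.vertices, self.faces)
        return self

    def flip(self) -> "MembraneSurface":
        """Reverse orientation (winding and normals)."""
        normals = None if self.normals is None else -self.normals
        return MembraneSurface(
            self.vertices.copy(),
            self.faces[:, ::-1].copy(),
            normals,
            self.membrane_id,
            self.region_class,
            self.side,
            dict(self.metadata),
        )

    def copy(self) -> "MembraneSurface":
        return MembraneSurface(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.normals is None else self.normals.copy(),
            self.membrane_id,
            self.region_class,
            self.side,
            dict(self.metadata),
        )


def read_mesh(
    path: str | Path,
    units: str = "nm",
    voxel_size_A: float | None = None,
    membrane_id: str = "",
) -> MembraneSurface:
    """Read a triangular OBJ mesh.

    Parameters
    ----------
    units:
        Units of the coordinates in the file: ``"nm"``, ``"angstrom"`` or
        ``"voxel"`` (requires ``voxel_size_A``).
    """
    if units == "voxel":
        if voxel_size_A is None:
            raise FormatError("units='voxel' requires voxel_size_A")
        scale = voxel_size_A / 10.0
    elif units in _UNIT_SCALE_NM:
        scale = _UNIT_SCALE_NM[units]
    else:
        raise FormatError(f"unknown mesh units {units!r}; use nm, angstrom or voxel")

    verts: list[list[float]] = []
    norms: list[list[float]] = []
    faces: list[list[int]] = []
    face_norm_idx: list[list[int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        tag = parts[0]
        if tag == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif tag == "vn":
            norms.append([float(x) for x in parts[1:4]])
        elif tag == "f":
            refs = parts[1:]
            if len(refs) != 3:
                raise FormatError(
                    f"{path}:{lineno}: face with {len(refs)} vertices; "
                    "only triangles are supported — triangulate the mesh first"
                )
            vi, ni = [], []
            for ref in refs:
                bits = ref.split("/")
                vi.append(int(bits[0]))
                if len(bits) == 3 and bits[2]:
                    ni.append(int(bits[2]))
            faces.append(vi)
            if len(ni) == 3:
                face_norm_idx.append(ni)
    if not verts or not faces:
        raise FormatError(f"{path}: no triangular geometry found")

    v = np.asarray(verts) * scale
    f = np.asarray(faces, dtype=np.int64)
    f = np.where(f > 0, f - 1, len(v) + f)  # OBJ is 1-based, negatives relative

    vn = None
    if norms and len(face_norm_idx) == len(faces):
        # Average the referenced file normals onto vertices.
        nsrc = np.asarray(norms)
        nidx = np.asarray(face_norm_idx, dtype=np.int64)
        nidx = np.where(nidx > 0, nidx - 1, len(nsrc) + nidx)
        vn = np.zeros_like(v)
        counts = np.zeros(len(v))
        for corner in range(3):
            np.add.at(vn, f[:, corner], nsrc[nidx[:, corner]])
            np.add.at(counts, f[:, corner], 1.0)
        vn /= np.maximum(counts, 1.0)[:, None]
        lens = np.linalg.norm(vn, axis=1, keepdims=True)
        lens[lens == 0] = 1.0
        vn /= lens

    surf = MembraneSurface(v, f, vn, membrane_id=membrane_id)
    return surf.with_normals()


def write_mesh(surface: MembraneSurface, path: str | Path) -> None:
    """Write an OBJ file (coordinates in nm, ``v``/``vn``/``f`` records)."""
    surface = surface.with_normals()
    lines = [f"# mcart mesh, units: nm, membrane_id: {surface.membrane_id}"]
    for x, y, z in surface.vertices:
        lines.append(f"v {x:.8g} {y:.8g} {z:.8g}")
    for x, y, z in surface.normals:
        lines.append(f"vn {x:.8g} {y:.8g} {z:.8g}")
    for a, b, c in surface.faces + 1:
        lines.append(f"f {a}//{a} {b}//{b} {c}//{c}")
    Path(path).write_text("\n".join(lines) + "\n")
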