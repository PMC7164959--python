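"""Shared fixtures: tiny volumes, analytic meshes, toy structures."""

from __future__ import annotations

import numpy as np
import pytest

from mcart.io_formats.mesh import MembraneSurface
from mcart.io_formats.mrc import DensityVolume
from mcart.io_formats.particles import ParticleRecord, ParticleSet
from mcart.io_formats.structure import AtomicStructure


def make_uv_sphere(radius_nm: float, n_theta: int = 24, n_phi: int = 48):
    """Closed UV sphere with exact outward normals (v / r)."""
    thetas = np.linspace(0, np.pi, n_theta)[1:-1]
    verts = [(0.0, 0.0, radius_nm), (0.0, 0.0, -radius_nm)]
    rows = []
    for t in thetas:
        row = []
        for k in range(n_phi):
            p = 2 * np.pi * k / n_phi
            row.append(len(verts))
            verts.append(
                (
                    radius_nm * np.sin(t) * np.cos(p),
                    radius_nm * np.sin(t) * np.sin(p),
                    radius_nm * np.cos(t),
                )
            )
        rows.append(row)
    faces = []
    for k in range(n_phi):
        faces.append((0, rows[0][k], rows[0][(k + 1) % n_phi]))
        faces.append((1, rows[-1][(k + 1) % n_phi], rows[-1][k]))
    for a, b in zip(rows[:-1], rows[1:]):
        for k in range(n_phi):
            k2 = (k + 1) % n_phi
            faces.append((a[k], b[k], b[k2]))
            faces.append((a[k], b[k2], a[k2]))
    v = np.array(verts)
    surf = MembraneSurface(v, np.array(faces), normals=v / radius_nm)
    return surf


@pytest.fixture
def sphere_surface():
    return make_uv_sphere(50.0)


@pytest.fixture
def ramp_volume():
    """f(x, y, z) = z nm on a 16^3 grid with 10 A voxels."""
    n = 16
    data = np.broadcast_to(
        np.arange(n, dtype=np.float32)[:, None, None], (n, n, n)
    ).copy()
    return DensityVolume(data, voxel_size_A=10.0)


@pytest.fixture
def toy_structure():
    return AtomicStructure(
        coords_A=np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 20.0, 0.0]]),
        elements=np.array(["C", "N", "O"]),
        chain_ids=np.array(["A", "A", "B"]),
    )


@pytest.fixture
def toy_pdb(tmp_path):
    lines = [
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C",
        "ATOM      2  CB  ALA A   1       4.000   5.000   6.000  1.00  0.00           C",
        "ATOM      3  CA  GLY B   2       7.000   8.000   9.000  1.00  0.00           C",
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def particle_set():
    return ParticleSet(
        [
            ParticleRecord("PSII", (10.0, 20.0, 0.0), 0.5, "M1", "luminal"),
            ParticleRecord("PSII", (40.0, 20.0, 0.0), 1.5, "M1", "luminal"),
            ParticleRecord("CYTB6F", (25.0, 40.0, 0.0), 0.0, "M1", "luminal"),
            ParticleRecord("ATPS", (5.0, 5.0, 0.0), 2.0, "M2", "stromal", "low"),
            ParticleRecord("RIBO", (60.0, 60.0, 0.0), 3.0, "M2", "stromal"),
        ]
    )
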