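"""Voxel segmentations to smooth oriented surfaces, and surface manipulation.

Pipeline mirroring standard segmentation post-processing: optional growth of
the one-voxel-wide mask by morphological dilation, marching-cubes
isosurfacing at the 0.5 level, vertex-clustering decimation to a target
triangle fraction, and Laplacian smoothing (boundary vertices fixed).
Continuous signed normal offsets ("grow/shrink") operate on the mesh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from skimage.measure import marching_cubes

from mcart.errors import GeometryError
from mcart.io_formats.mesh import MembraneSurface, triangle_normals
from mcart.io_formats.particles import ParticleSet


@dataclass
class SegmentationMask:
    """Binary voxel mask aligned to a :class:`DensityVolume` grid.

    ``mask`` is indexed ``[z, y, x]``; physical metadata as for volumes.
    """

    mask: np.ndarray
    voxel_size_A: float
    origin_A: np.ndarray = field(default_factory=lambda: np.zeros(3))
    region_class: str | None = None
    membrane_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.origin_A = np.asarray(self.origin_A, dtype=float)
        if self.mask.ndim != 3:
            raise GeometryError("segmentation mask must be 3D")
        if not self.mask.any():
            raise GeometryError("segmentation mask is empty")

    @property
    def voxel_size_nm(self) -> float:
        return self.voxel_size_A / 10.0

    @property
    def n_components(self) -> int:
        """Number of 6-connected components."""
        _, n = ndimage.label(self.mask)
        return int(n)

    def grown(self, voxels: int) -> "SegmentationMask":
        """Morphological dilation by ``voxels`` in all directions."""
        if voxels == 0:
            return self
        grown = ndimage.binary_dilation(self.mask, iterations=voxels)
        return SegmentationMask(
            grown, self.voxel_size_A, self.origin_A, self.region_class, self.membrane_id
        )


@dataclass
class SmoothingParams:
    """Surface post-processing parameters.

    ``inflate`` is the negative (Taubin) counter-step interleaved with each
    relaxation step inside :func:`mask_to_surface` to compensate the volume
    shrinkage of plain Laplacian smoothing; set it to 0 for the uncompensated
    update rule of :func:`laplacian_smooth`.
    """

    iterations: int = 50
    lam: float = 0.4
    decimation_fraction: float = 0.1
    inflate: float = -0.42

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must be in [0, 1]")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not (0.0 < self.decimation_fraction <= 1.0):
            raise ValueError("decimation_fraction must be in (0, 1]")


@dataclass
class PlanarFrame:
    """Orthonormal in-plane basis (e1, e2) + normal anchored at origin (nm)."""

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    normal: np.ndarray

    def project(self, points_nm: np.ndarray) -> np.ndarray:
        """Orthogonal projection to in-plane (u, v) coordinates."""
        d = np.atleast_2d(points_nm) - self.origin
        return np.column_stack([d @ self.e1, d @ self.e2])

    def residuals(self, points_nm: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points_nm) - self.origin
        return d @ self.normal

    def lift(self, uv: np.ndarray, w=0.0) -> np.ndarray:
        """Back to 3D: origin + u*e1 + v*e2 + w*normal."""
        uv = np.atleast_2d(uv)
        w = np.broadcast_to(np.asarray(w, dtype=float), (len(uv),))
        return (
            self.origin
            + uv[:, :1] * self.e1
            + uv[:, 1:2] * self.e2
            + w[:, None] * self.normal
        )


def fit_plane(points_nm: np.ndarray) -> PlanarFrame:
    """Least-squares plane through points via SVD of the centred cloud."""
    pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
    if len(pts) < 3:
        raise GeometryError("plane fit requires at least 3 points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1e-30):
        raise GeometryError("degenerate (collinear) point set; cannot fit a plane")
    return PlanarFrame(origin=centroid, e1=vt[0], e2=vt[1], normal=vt[2])


def _boundary_vertices(n_vertices: int, faces: np.ndarray) -> np.ndarray:
    """Vertices on edges referenced by exactly one face."""
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    border = uniq[counts == 1]
    out = np.zeros(n_vertices, dtype=bool)
    out[border.ravel()] = True
    return out


def _adjacency(n_vertices: int, faces: np.ndarray) -> sparse.csr_matrix:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    a = sparse.coo_matrix(
        (np.ones(len(i)), (i, j)), shape=(n_vertices, n_vertices)
    ).tocsr()
    a.data[:] = 1.0  # collapse duplicate edge entries
    return a


def laplacian_smooth(
    surface: MembraneSurface,
    iterations: int = 50,
    lam: float = 0.4,
    inflate: float = 0.0,
) -> MembraneSurface:
    """Iterative Laplacian relaxation: v <- v + lam * (mean(neighbors) - v).

    Boundary vertices (on open mesh borders) are kept fixed so that cropped
    membrane regions do not shrink inwards at their rims. A nonzero
    ``inflate`` (e.g. -0.42) interleaves a Taubin counter-step after every
    relaxation step, compensating the shrinkage of closed meshes.
    """
    if iterations == 0 or lam == 0.0:
        return surface.copy()
    v = surface.vertices.copy()
    f = surface.faces
    adj = _adjacency(len(v), f)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    interior = (~_boundary_vertices(len(v), f)) & (deg > 0)
    inv_deg = np.zeros_like(deg)
    inv_deg[deg > 0] = 1.0 / deg[deg > 0]
    steps = [lam] if inflate == 0.0 else [lam, inflate]
    for _ in range(iterations):
        for step in steps:
            centroid = adj @ v * inv_deg[:, None]
            v[interior] += step * (centroid[interior] - v[interior])
    out = MembraneSurface(
        v, f.copy(), None, surface.membrane_id, surface.region_class, surface.side
    )
    return out.with_normals()


def decimate_mesh(
    vertices: np.ndarray, faces: np.ndarray, fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vertex-clustering decimation to approximately ``fraction`` of the faces.

    Vertices falling in the same cubic cell are merged at their mean; the cell
    size is found by bisection so the face count lands near the target.
    """
    if fraction >= 1.0:
        return vertices, faces
    target = max(int(round(fraction * len(faces))), 4)
    extent = float(np.ptp(vertices, axis=0).max())
    if extent == 0:
        return vertices, faces

    def cluster(cell: float):
        keys = np.floor((vertices - vertices.min(axis=0)) / cell).astype(np.int64)
        _, inverse = np.unique(keys, axis=0, return_inverse=True)
        n_new = inverse.max() + 1
        new_v = np.zeros((n_new, 3))
        counts = np.zeros(n_new)
        np.add.at(new_v, inverse, vertices)
        np.add.at(counts, inverse, 1.0)
        new_v /= counts[:, None]
        nf = inverse[faces]
        keep = (nf[:, 0] != nf[:, 1]) & (nf[:, 1] != nf[:, 2]) & (nf[:, 0] != nf[:, 2])
        nf = np.unique(np.sort(nf[keep], axis=1), axis=0) if keep.any() else nf[:0]
        return new_v, nf

    lo, hi = extent / max(len(vertices), 2) ** 0.5, extent / 2
    best = None
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        new_v, nf = cluster(mid)
        if best is None or abs(len(nf) - target) < abs(len(best[1]) - target):
            best = (new_v, nf)
        if len(nf) > target:
            lo = mid
        else:
            hi = mid
        if abs(len(nf) - target) <= max(2, int(0.05 * target)):
            break
    new_v, nf = best
    if len(nf) == 0:
        return vertices, faces
    return new_v, nf.astype(np.int64)


def _orient_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip winding so face normals on average point away from the centroid."""
    fn = triangle_normals(vertices, faces)
    centers = vertices[faces].mean(axis=1)
    outward = np.einsum("ij,ij->", fn, centers - vertices.mean(axis=0))
    return faces[:, ::-1] if outward < 0 else faces


def mask_to_surface(
    mask: SegmentationMask, params: SmoothingParams | None = None
) -> MembraneSurface:
    """Isosurface a binary mask, decimate and smooth.

    Marching cubes at the 0.5 level; output coordinates are physical nm
    (``origin + index * voxel_size``). Normals are oriented outward from the
    mask's centroid; re-orient per membrane with :meth:`MembraneSurface.flip`.
    """
    params = params or SmoothingParams()
    vs_nm = mask.voxel_size_nm
    try:
        verts, faces, _, _ = marching_cubes(
            mask.mask.astype(np.float32), level=0.5, spacing=(vs_nm, vs_nm, vs_nm)
        )
    except (ValueError, RuntimeError) as exc:
        raise GeometryError(
            "isosurface failed; if the mask is a single voxel thin sheet, "
            "grow it first (SegmentationMask.grown)"
        ) from exc
    # marching_cubes indexes (z, y, x); convert to (x, y, z) physical coords.
    verts = verts[:, ::-1] + mask.origin_A / 10.0
    verts, faces = decimate_mesh(verts, faces, params.decimation_fraction)
    faces = _orient_outward(verts, faces)
    surf = MembraneSurface(
        verts,
        faces,
        None,
        membrane_id=mask.membrane_id,
        region_class=mask.region_class,
    )
    return laplacian_smooth(surf, params.iterations, params.lam, params.inflate)


def offset_surface(surface: MembraneSurface, offset_nm: float) -> MembraneSurface:
    """Displace every vertex along its unit normal by ``offset_nm``.

    Topology is unchanged. If the offset flips triangles (self-intersection at
    high curvature), a warning reports the flipped-triangle count.
    """
    surface = surface.with_normals()
    if offset_nm == 0.0:
        return surface.copy()
    if abs(offset_nm) > 50.0:
        raise ValueError("|offset_nm| > 50 nm exceeds the sanity bound")
    v = surface.vertices + offset_nm * surface.normals
    before = triangle_normals(surface.vertices, surface.faces)
    after = triangle_normals(v, surface.faces)
    flipped = int(np.sum(np.einsum("ij,ij->i", before, after) < 0))
    if flipped:
        warnings.warn(
            f"offset_surface: {flipped} triangles flipped (self-intersection "
            "at high curvature)",
            stacklevel=2,
        )
    return MembraneSurface(
        v,
        surface.faces.copy(),
        surface.normals.copy(),
        surface.membrane_id,
        surface.region_class,
        surface.side,
    )


@dataclass
class PlaneProjection:
    """Result of flattening a surface (+ its particles) onto a plane."""

    frame: PlanarFrame
    vertex_uv: np.ndarray
    vertex_residuals: np.ndarray
    particle_uv: np.ndarray
    particle_residuals: np.ndarray

    @property
    def max_residual(self) -> float:
        return float(np.abs(self.vertex_residuals).max())


def fit_plane_project(
    surface: MembraneSurface,
    particles: ParticleSet | None = None,
    flatness_fraction: float = 0.1,
) -> PlaneProjection:
    """Project an essentially-flat surface and its particles onto a plane.

    Warns when the maximum vertex residual exceeds ``flatness_fraction`` of
    the in-plane extent (flatness precondition violated).
    """
    frame = fit_plane(surface.vertices)
    vuv = frame.project(surface.vertices)
    vres = frame.residuals(surface.vertices)
    extent = float(np.ptp(vuv, axis=0).max())
    if extent > 0 and np.abs(vres).max() > flatness_fraction * extent:
        warnings.warn(
            "surface is not essentially flat: max residual "
            f"{np.abs(vres).max():.2f} nm exceeds {flatness_fraction:.0%} of the "
            f"{extent:.1f} nm extent",
            stacklevel=2,
        )
    if particles is not None and len(particles):
        pos = particles.positions_nm()
        puv = frame.project(pos)
        pres = frame.residuals(pos)
    else:
        puv = np.zeros((0, 2))
        pres = np.zeros(0)
    return PlaneProjection(frame, vuv, vres, puv, pres)


def surface_area_um2(surface: MembraneSurface) -> float:
    """Total triangle area in square micrometres (vertices are nm)."""
    areas_nm2 = np.linalg.norm(
        triangle_normals(surface.vertices, surface.faces), axis=1
    )
    return float(areas_nm2.sum() * 1e-6)


def flat_sheet_surface(
    extent_nm: tuple[float, float],
    z_nm: float = 0.0,
    spacing_nm: float = 4.0,
    normal_sign: int = 1,
    membrane_id: str = "",
    region_class: str | None = None,
    side: str | None = None,
) -> MembraneSurface:
    """Regular-grid triangulated rectangle at height ``z_nm`` (normals +/-z)."""
    ex, ey = extent_nm
    nx = max(int(round(ex / spacing_nm)) + 1, 2)
    ny = max(int(round(ey / spacing_nm)) + 1, 2)
    xs = np.linspace(0.0, ex, nx)
    ys = np.linspace(0.0, ey, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, float(z_nm))])
    idx = np.arange(nx * ny).reshape(nx, ny)
    a, b, c, d = idx[:-1, :-1], idx[1:, :-1], idx[:-1, 1:], idx[1:, 1:]
    faces = np.concatenate(
        [
            np.column_stack([a.ravel(), b.ravel(), d.ravel()]),
            np.column_stack([a.ravel(), d.ravel(), c.ravel()]),
        ]
    )
    if normal_sign < 0:
        faces = faces[:, ::-1]
    normals = np.tile(
        np.array([0.0, 0.0, float(np.sign(normal_sign) or 1)]), (len(verts), 1)
    )
    return MembraneSurface(
        verts, faces, normals, membrane_id=membrane_id, region_class=region_class, side=side
    )
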