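"""Membranograms: tomographic density sampled on a membrane surface.

The surface is parameterized by orthogonal projection onto its best-fit plane
(membrane regions analysed quantitatively are essentially flat). A regular 2D
grid in that plane is lifted back onto the surface by linear interpolation of
vertex positions and normals; the volume is sampled trilinearly at
``p + offset_nm * n_hat`` for each lifted point ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator
from skimage.filters import threshold_otsu

from mcart.errors import SamplingError
from mcart.io_formats.mesh import MembraneSurface
from mcart.io_formats.mrc import DensityVolume
from mcart.surface_geometry import PlanarFrame, fit_plane


@dataclass
class SurfaceParameterization:
    """Shared 2D grid over a surface: lifted 3D points + unit normals."""

    frame: PlanarFrame
    grid_origin_uv: np.ndarray
    pixel_size_nm: float
    shape: tuple[int, int]
    points_nm: np.ndarray  # (H, W, 3), NaN outside the surface
    normals: np.ndarray  # (H, W, 3), unit length where valid
    on_surface: np.ndarray  # (H, W) bool

    def uv_grid(self) -> tuple[np.ndarray, np.ndarray]:
        h, w = self.shape
        u = self.grid_origin_uv[0] + np.arange(h) * self.pixel_size_nm
        v = self.grid_origin_uv[1] + np.arange(w) * self.pixel_size_nm
        return u, v


def parameterize_surface(
    surface: MembraneSurface, pixel_size_nm: float
) -> SurfaceParameterization:
    """Build the planar parameterization used by all sampling calls."""
    surface = surface.with_normals()
    frame = fit_plane(surface.vertices)
    uv = frame.project(surface.vertices)
    lo = uv.min(axis=0)
    hi = uv.max(axis=0)
    h = max(int(np.ceil((hi[0] - lo[0]) / pixel_size_nm)) + 1, 2)
    w = max(int(np.ceil((hi[1] - lo[1]) / pixel_size_nm)) + 1, 2)
    gu = lo[0] + np.arange(h) * pixel_size_nm
    gv = lo[1] + np.arange(w) * pixel_size_nm
    guu, gvv = np.meshgrid(gu, gv, indexing="ij")
    query = np.column_stack([guu.ravel(), gvv.ravel()])

    values = np.concatenate([surface.vertices, surface.normals], axis=1)
    interp = LinearNDInterpolator(uv, values)
    sampled = interp(query).reshape(h, w, 6)
    points = sampled[..., :3]
    normals = sampled[..., 3:]
    on_surface = np.isfinite(points).all(axis=-1)
    lens = np.linalg.norm(normals, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        normals = np.where(lens > 0, normals / lens, normals)
    return SurfaceParameterization(
        frame=frame,
        grid_origin_uv=lo,
        pixel_size_nm=pixel_size_nm,
        shape=(h, w),
        points_nm=points,
        normals=normals,
        on_surface=on_surface,
    )


@dataclass
class Membranogram:
    """Scalar density image on a surface parameterization at one offset."""

    values: np.ndarray  # (H, W) float
    valid: np.ndarray  # (H, W) bool
    offset_nm: float
    param: SurfaceParameterization
    membrane_id: str = ""
    side: str | None = None

    @property
    def pixel_size_nm(self) -> float:
        return self.param.pixel_size_nm

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass
class MembranogramStack:
    """Membranograms at several offsets on one shared parameterization."""

    values: np.ndarray  # (K, H, W)
    offsets_nm: np.ndarray  # (K,)
    valid: np.ndarray  # (K, H, W)
    param: SurfaceParameterization
    membrane_id: str = ""
    side: str | None = None

    def __len__(self) -> int:
        return len(self.offsets_nm)

    def layer(self, k: int) -> Membranogram:
        return Membranogram(
            self.values[k],
            self.valid[k],
            float(self.offsets_nm[k]),
            self.param,
            self.membrane_id,
            self.side,
        )


def _sample_at(
    volume: DensityVolume, points_nm: np.ndarray, nearest: bool = False
) -> np.ndarray:
    """Trilinear (or nearest) interpolation of the volume at (x,y,z) nm points."""
    idx_xyz = volume.index_from_nm(points_nm.reshape(-1, 3))
    coords = idx_xyz[:, ::-1].T  # map_coordinates wants (z, y, x)
    out = ndimage.map_coordinates(
        volume.data.astype(np.float64),
        coords,
        order=0 if nearest else 1,
        mode="constant",
        cval=np.nan,
    )
    return out.reshape(points_nm.shape[:-1])


def sample_density(
    volume: DensityVolume,
    surface: MembraneSurface,
    offset_nm: float = 2.0,
    pixel_size_nm: float | None = None,
    param: SurfaceParameterization | None = None,
    nearest: bool = False,
    max_oob_fraction: float = 0.5,
) -> Membranogram:
    """Sample the volume on the surface at a signed normal offset.

    The default pixel size is half the tomogram voxel (2x oversampling).
    Samples falling outside the volume are marked invalid; if more than
    ``max_oob_fraction`` of on-surface samples are out of bounds, a
    :class:`SamplingError` signals a surface/volume mismatch.
    """
    if param is None:
        if pixel_size_nm is None:
            pixel_size_nm = volume.voxel_size_nm / 2.0
        param = parameterize_surface(surface, pixel_size_nm)
    pts = param.points_nm + offset_nm * param.normals
    with np.errstate(invalid="ignore"):
        values = _sample_at(volume, np.nan_to_num(pts, nan=-1e9), nearest=nearest)
    valid = param.on_surface & np.isfinite(values)
    n_surf = int(param.on_surface.sum())
    if n_surf == 0:
        raise SamplingError("surface parameterization produced no valid samples")
    oob = 1.0 - valid.sum() / n_surf
    if oob > max_oob_fraction:
        raise SamplingError(
            f"{oob:.0%} of samples fall outside the volume; "
            "surface and volume do not match"
        )
    values = np.where(valid, values, 0.0)
    return Membranogram(
        values, valid, float(offset_nm), param, surface.membrane_id, surface.side
    )


def sweep_offsets(
    volume: DensityVolume,
    surface: MembraneSurface,
    offsets_nm,
    pixel_size_nm: float | None = None,
    nearest: bool = False,
) -> MembranogramStack:
    """One membranogram per offset on a single shared parameterization."""
    offsets = np.asarray(list(offsets_nm), dtype=float)
    if pixel_size_nm is None:
        pixel_size_nm = volume.voxel_size_nm / 2.0
    param = parameterize_surface(surface, pixel_size_nm)
    if len(offsets) == 0:
        empty = np.zeros((0,) + param.shape)
        return MembranogramStack(
            empty, offsets, empty.astype(bool), param, surface.membrane_id, surface.side
        )
    layers = [
        sample_density(volume, surface, o, param=param, nearest=nearest)
        for o in offsets
    ]
    return MembranogramStack(
        np.stack([m.values for m in layers]),
        offsets,
        np.stack([m.valid for m in layers]),
        param,
        surface.membrane_id,
        surface.side,
    )


@dataclass
class BinaryDensityMap:
    """Thresholded membranogram with an edge-cropped validity mask."""

    foreground: np.ndarray  # (H, W) bool
    valid: np.ndarray  # (H, W) bool, crop margin removed
    threshold: float
    crop_margin_px: int
    pixel_size_nm: float
    membrane_id: str = ""

    def __post_init__(self) -> None:
        self.foreground = np.asarray(self.foreground).astype(bool) & self.valid

    @property
    def foreground_fraction(self) -> float:
        n_valid = int(self.valid.sum())
        if n_valid == 0:
            return 0.0
        return float((self.foreground & self.valid).sum() / n_valid)


def threshold_map(
    membranogram: Membranogram,
    method: str | float = "otsu",
    crop_margin_px: int = 3,
) -> BinaryDensityMap:
    """Binarize a membranogram and crop its border.

    ``method`` is ``"otsu"`` or an explicit threshold value. The crop erodes
    the validity mask by ``crop_margin_px`` pixels (edge effects excluded from
    all downstream statistics).
    """
    vals = membranogram.valid_values()
    if vals.size == 0:
        raise SamplingError("membranogram has no valid samples to threshold")
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown threshold method {method!r}")
        if np.ptp(vals) == 0:
            raise SamplingError(
                "cannot Otsu-threshold a constant image; pass a manual threshold"
            )
        thr = float(threshold_otsu(vals))
    else:
        thr = float(method)
    valid = membranogram.valid
    if crop_margin_px > 0:
        # Pad so image borders also count as edges to erode away from.
        padded = np.pad(valid, 1, constant_values=False)
        eroded = ndimage.binary_erosion(padded, iterations=crop_margin_px)
        valid = eroded[1:-1, 1:-1]
    fg = (membranogram.values > thr) & valid
    return BinaryDensityMap(
        fg, valid, thr, crop_margin_px, membranogram.pixel_size_nm,
        membranogram.membrane_id,
    )


def luminal_density_fraction(density_map: BinaryDensityMap) -> float:
    """Percentage of valid surface pixels covered by foreground density."""
    if int(density_map.valid.sum()) == 0:
        raise SamplingError("no valid pixels left after cropping")
    return 100.0 * density_map.foreground_fraction


def shift_map(density_map: BinaryDensityMap, shift_px: tuple[int, int]) -> BinaryDensityMap:
    """Integer-pixel translation of a binary map (registration helper)."""
    di, dj = shift_px
    fg = np.roll(density_map.foreground, (di, dj), axis=(0, 1))
    valid = np.roll(density_map.valid, (di, dj), axis=(0, 1))
    # rolled-in borders are invalid
    if di > 0:
        valid[:di] = False
    elif di < 0:
        valid[di:] = False
    if dj > 0:
        valid[:, :dj] = False
    elif dj < 0:
        valid[:, dj:] = False
    return replace(density_map, foreground=fg & valid, valid=valid)
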