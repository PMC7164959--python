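"""Ground-truthed synthetic tomograms of stacked membrane sheets.

Scenes emulate thylakoid geometry: flat membrane slabs (~4 nm thick, bright)
stacked with a ~9 nm lumen inside each sheet pair and a ~3 nm stromal gap
between appressed pairs, decorated with class-specific surface protrusions at
stated concentrations, plus additive Gaussian noise.

Protrusions are rendered as truncated Gaussian blobs: lateral FWHM equals the
class footprint diameter; the axial profile has 3*sigma_z equal to the
protrusion height, so a density vanishes at exactly its nominal height above
the membrane (the feature the picking heuristics key on). Dimers are two
lobes with centres one lobe diameter apart.

A simple protrusion detector closes the loop for recovery tests: it
thresholds the smallest-offset membranogram, measures per-component vanishing
height, footprint area and principal axis across an offset sweep, and
classifies against the same features measured on rendered templates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from mcart.errors import PackingError
from mcart.io_formats.mesh import MembraneSurface
from mcart.io_formats.mrc import DensityVolume
from mcart.io_formats.particles import ParticleRecord, ParticleSet
from mcart.membranogram import MembranogramStack, sweep_offsets
from mcart.random_packing import make_rng, sequential_pack
from mcart.structure_models import dimer_footprint_density, disk_footprint_density
from mcart.surface_geometry import SegmentationMask, flat_sheet_surface

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> FWHM factor


@dataclass(frozen=True)
class ClassSpec:
    """Geometry + abundance of one particle class."""

    name: str
    concentration_um2: float
    height_nm: float
    diameter_nm: float  # lateral FWHM of one lobe
    dimer: bool
    side: str  # "stromal" | "luminal"
    amplitude: float = 1.0
    collision_scale: float = 1.25  # packing diameter = scale * rendered extent

    @property
    def sigma_xy(self) -> float:
        return self.diameter_nm / _FWHM

    @property
    def z_center_nm(self) -> float:
        """Axial blob centre above the membrane plane.

        Surface-hugging protrusions (height <= diameter) are centred on the
        membrane; taller complexes (ATP synthase F1, ribosomes) are rendered
        as a head centred near the top of their reach, leaving only a faint
        tail at the membrane.
        """
        return max(0.0, self.height_nm - self.diameter_nm / 2.0)

    @property
    def sigma_z(self) -> float:
        """Axial spread; 3*sigma_z spans the height (surface blobs) or the
        head diameter (raised blobs), so densities vanish at their height."""
        if self.z_center_nm > 0:
            return self.diameter_nm / 3.0
        return self.height_nm / 3.0

    @property
    def separation_nm(self) -> float:
        return self.diameter_nm if self.dimer else 0.0

    def packing_density(self, pixel_size_nm: float):
        d = self.collision_scale * self.diameter_nm
        if self.dimer:
            return dimer_footprint_density(
                d, self.separation_nm, pixel_size_nm, tag=self.name
            )
        return disk_footprint_density(d, pixel_size_nm, tag=self.name)


#: Default classes mirroring the measured appressed/non-appressed layout.
PSII = ClassSpec("PSII", 1122.0, 4.0, 6.0, True, "luminal", collision_scale=1.4)
CYTB6F_APPRESSED = ClassSpec("CYTB6F", 631.0, 3.0, 4.0, True, "luminal", collision_scale=1.4)
CYTB6F_NONAPPRESSED = ClassSpec("CYTB6F", 501.0, 3.0, 4.0, True, "luminal", collision_scale=1.4)
PSI = ClassSpec("PSI", 1049.0, 3.0, 6.0, False, "stromal")
ATPS = ClassSpec("ATPS", 1652.0, 15.0, 10.0, False, "stromal")
RIBO = ClassSpec("RIBO", 113.0, 25.0, 25.0, False, "stromal")

DEFAULT_TEMPLATES: tuple[ClassSpec, ...] = (
    PSII,
    CYTB6F_APPRESSED,
    PSI,
    ATPS,
    RIBO,
)


@dataclass
class SheetSpec:
    """One flat membrane in the stack."""

    membrane_id: str
    z_nm: float
    region_class: str  # "appressed" | "non_appressed"
    stromal_sign: int  # +1 if the stromal side faces +z
    classes: tuple[ClassSpec, ...] = ()


@dataclass
class SceneSpec:
    """Full synthetic scene description."""

    extent_nm: tuple[float, float] = (250.0, 200.0)
    sheets: tuple[SheetSpec, ...] = ()
    voxel_size_A: float = 13.68
    membrane_thickness_nm: float = 4.0
    membrane_amplitude: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    z_pad_nm: float = 5.0

    def __post_init__(self) -> None:
        if self.voxel_size_A <= 0:
            raise ValueError("voxel size must be positive")
        diam = [c.diameter_nm for s in self.sheets for c in s.classes]
        if diam and self.voxel_size_A / 10.0 > min(diam) / 2.0:
            raise ValueError(
                "voxel size must be at most half the smallest footprint diameter"
            )

    @property
    def area_um2(self) -> float:
        return self.extent_nm[0] * self.extent_nm[1] * 1e-6


def table1_scene(
    extent_nm: tuple[float, float] = (250.0, 200.0),
    lumen_nm: float = 9.0,
    gap_nm: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    include_nonappressed: bool = True,
) -> SceneSpec:
    """Stack emulating the measured membrane layout.

    Two appressed membranes facing each other across the stromal gap, each
    backed by its lumen partner; the two outermost membranes are non-appressed
    (stromal classes) when ``include_nonappressed`` is set.
    """
    nap_low = (PSI, ATPS, RIBO, replace(CYTB6F_NONAPPRESSED, side="luminal"))
    app = (PSII, CYTB6F_APPRESSED)
    z0 = 0.0
    z1 = z0 + lumen_nm  # top of sheet 1 (appressed, faces gap above)
    z2 = z1 + gap_nm  # bottom of sheet 2 (appressed)
    z3 = z2 + lumen_nm  # top of sheet 2 (non-appressed)
    sheets = [
        SheetSpec(
            "M1",
            z0,
            "non_appressed",
            stromal_sign=-1,
            classes=nap_low if include_nonappressed else (),
        ),
        SheetSpec("M2", z1, "appressed", stromal_sign=+1, classes=app),
        SheetSpec("M3", z2, "appressed", stromal_sign=-1, classes=app),
        SheetSpec(
            "M4",
            z3,
            "non_appressed",
            stromal_sign=+1,
            classes=nap_low if include_nonappressed else (),
        ),
    ]
    return SceneSpec(
        extent_nm=extent_nm, sheets=tuple(sheets), noise_sd=noise_sd, seed=seed
    )


@dataclass
class GroundTruth:
    """Everything the generator knows about a scene."""

    particles: ParticleSet
    masks: list[SegmentationMask]
    sheets: list[SheetSpec]
    spec: SceneSpec
    expected_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def sheet(self, membrane_id: str) -> SheetSpec:
        for s in self.sheets:
            if s.membrane_id == membrane_id:
                return s
        raise KeyError(membrane_id)

    def region_of_membrane(self) -> dict[str, str]:
        return {s.membrane_id: s.region_class for s in self.sheets}

    def region_areas_um2(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for s in self.sheets:
            out[s.region_class] = out.get(s.region_class, 0.0) + self.spec.area_um2
        return out

    def surface(self, membrane_id: str, side: str) -> MembraneSurface:
        """Flat mesh of one membrane, normals pointing toward ``side``."""
        s = self.sheet(membrane_id)
        sign = s.stromal_sign if side == "stromal" else -s.stromal_sign
        surf = flat_sheet_surface(
            self.spec.extent_nm,
            z_nm=s.z_nm,
            normal_sign=sign,
            membrane_id=membrane_id,
            region_class=s.region_class,
            side=side,
        )
        return surf


def _blob_value(spec: ClassSpec, du: np.ndarray, dv: np.ndarray, dz: np.ndarray):
    """Density of one particle at lateral offsets (du, dv) from its centre and
    height dz above the membrane plane (dz already on the particle's side).

    The dimer axis lies along +u at angle 0; callers rotate coordinates.
    """
    sxy, sz = spec.sigma_xy, spec.sigma_z
    zprof = np.exp(-((dz - spec.z_center_nm) ** 2) / (2 * sz**2)) * (
        (dz >= 0) & (dz <= spec.height_nm)
    )
    if spec.dimer:
        s = spec.separation_nm / 2.0
        lat = np.exp(-(((du - s) ** 2) + dv**2) / (2 * sxy**2)) + np.exp(
            -(((du + s) ** 2) + dv**2) / (2 * sxy**2)
        )
    else:
        lat = np.exp(-((du**2) + dv**2) / (2 * sxy**2))
    r2 = du**2 + dv**2
    lat = lat * (r2 <= (3 * sxy + spec.separation_nm / 2.0) ** 2)
    return spec.amplitude * zprof * lat


def generate_scene(spec: SceneSpec) -> tuple[DensityVolume, GroundTruth]:
    """Render a scene and return its volume plus full ground truth.

    Per membrane, realized particle counts are ``round(concentration * area)``;
    positions come from collision-resolving random packing on the membrane
    voxel grid (largest footprints placed first).
    """
    vs_nm = spec.voxel_size_A / 10.0
    ex, ey = spec.extent_nm
    pad_lat = 2 * vs_nm
    if not spec.sheets:
        raise ValueError("scene needs at least one membrane sheet")
    hmax_lo = max(
        (
            c.height_nm
            for s in spec.sheets
            for c in s.classes
            if (s.stromal_sign if c.side == "stromal" else -s.stromal_sign) < 0
        ),
        default=0.0,
    )
    hmax_hi = max(
        (
            c.height_nm
            for s in spec.sheets
            for c in s.classes
            if (s.stromal_sign if c.side == "stromal" else -s.stromal_sign) > 0
        ),
        default=0.0,
    )
    zs = [s.z_nm for s in spec.sheets]
    z_lo = min(zs) - hmax_lo - spec.z_pad_nm
    z_hi = max(zs) + hmax_hi + spec.z_pad_nm

    nx = int(round((ex + 2 * pad_lat) / vs_nm)) + 1
    ny = int(round((ey + 2 * pad_lat) / vs_nm)) + 1
    nz = int(round((z_hi - z_lo) / vs_nm)) + 1
    origin_nm = np.array([-pad_lat, -pad_lat, z_lo])
    data = np.zeros((nz, ny, nx), dtype=np.float32)
    zc = origin_nm[2] + np.arange(nz) * vs_nm  # voxel-centre z in nm
    xc = origin_nm[0] + np.arange(nx) * vs_nm
    yc = origin_nm[1] + np.arange(ny) * vs_nm

    # membrane slabs
    sigma_m = spec.membrane_thickness_nm / _FWHM
    for s in spec.sheets:
        prof = spec.membrane_amplitude * np.exp(
            -((zc - s.z_nm) ** 2) / (2 * sigma_m**2)
        )
        prof[np.abs(zc - s.z_nm) > 3 * sigma_m] = 0.0
        data += prof[:, None, None].astype(np.float32)

    rng = make_rng(spec.seed)
    particles = ParticleSet()
    masks: list[SegmentationMask] = []
    expected: dict[tuple[str, str], int] = {}

    # lateral packing grid covers [0, ex] x [0, ey] at the volume voxel size
    npx = int(round(ex / vs_nm)) + 1
    npy = int(round(ey / vs_nm)) + 1
    membrane_grid = np.ones((npx, npy), dtype=bool)
    area = spec.area_um2

    for s in spec.sheets:
        requests = []
        for c in sorted(s.classes, key=lambda c: -c.diameter_nm):
            n = int(round(c.concentration_um2 * area))
            expected[(s.membrane_id, c.name)] = n
            if n:
                requests.append((c.name, n, c.packing_density(vs_nm)))
        try:
            placed = sequential_pack(membrane_grid, requests, rng)
        except PackingError as exc:
            raise PackingError(f"membrane {s.membrane_id}: {exc}") from exc
        by_name = {c.name: c for c in s.classes}
        for name, i, j, angle in placed:
            c = by_name[name]
            sign = s.stromal_sign if c.side == "stromal" else -s.stromal_sign
            x, y = i * vs_nm, j * vs_nm
            particles.add(
                ParticleRecord(
                    particle_class=name,
                    position_nm=(x, y, s.z_nm),
                    angle=angle,
                    membrane_id=s.membrane_id,
                    side=c.side,
                )
            )
            _render_blob(data, xc, yc, zc, c, x, y, s.z_nm, angle, sign)

        kz = int(round((s.z_nm - z_lo) / vs_nm))
        mask = np.zeros_like(data, dtype=bool)
        i0 = int(round((0 - origin_nm[0]) / vs_nm))
        j0 = int(round((0 - origin_nm[1]) / vs_nm))
        mask[kz, j0 : j0 + npy, i0 : i0 + npx] = True
        masks.append(
            SegmentationMask(
                mask,
                spec.voxel_size_A,
                origin_nm * 10.0,
                region_class=s.region_class,
                membrane_id=s.membrane_id,
            )
        )

    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape).astype(np.float32)

    volume = DensityVolume(data, spec.voxel_size_A, origin_nm * 10.0)
    truth = GroundTruth(particles, masks, list(spec.sheets), spec, expected)
    return volume, truth


def _render_blob(data, xc, yc, zc, cspec: ClassSpec, x, y, z_mem, angle, sign):
    """Add one particle's density into the volume (local patch only)."""
    reach = 3 * cspec.sigma_xy + cspec.separation_nm / 2.0
    i0 = np.searchsorted(xc, x - reach)
    i1 = np.searchsorted(xc, x + reach) + 1
    j0 = np.searchsorted(yc, y - reach)
    j1 = np.searchsorted(yc, y + reach) + 1
    if sign > 0:
        k0 = np.searchsorted(zc, z_mem)
        k1 = np.searchsorted(zc, z_mem + cspec.height_nm) + 1
    else:
        k0 = np.searchsorted(zc, z_mem - cspec.height_nm)
        k1 = np.searchsorted(zc, z_mem) + 1
    if i1 <= i0 or j1 <= j0 or k1 <= k0:
        return
    dx = xc[i0:i1] - x
    dy = yc[j0:j1] - y
    dz = sign * (zc[k0:k1] - z_mem)
    ca, sa = math.cos(angle), math.sin(angle)
    # rotate lateral coords into the particle frame (dimer axis along +u)
    gu = ca * dx[None, None, :] + sa * dy[None, :, None]
    gv = -sa * dx[None, None, :] + ca * dy[None, :, None]
    vals = _blob_value(cspec, gu, gv, dz[:, None, None])
    data[k0:k1, j0:j1, i0:i1] += vals.astype(np.float32)


def free_space_nm(truth: GroundTruth, membrane_id: str, side: str) -> float:
    """Unobstructed normal extent from a membrane surface toward ``side``.

    Distance to the nearest other sheet on that side minus half a membrane
    thickness and a 1 nm safety margin; infinite on open sides. A protrusion
    taller than this cannot exist (or be seen) in the gap — e.g. nothing
    stromal fits between appressed membranes.
    """
    s = truth.sheet(membrane_id)
    sign = s.stromal_sign if side == "stromal" else -s.stromal_sign
    dists = [
        sign * (o.z_nm - s.z_nm)
        for o in truth.sheets
        if o.membrane_id != membrane_id and sign * (o.z_nm - s.z_nm) > 0
    ]
    if not dists:
        return math.inf
    return min(dists) - truth.spec.membrane_thickness_nm / 2.0 - 1.0


def visible_templates(
    truth: GroundTruth, membrane_id: str, side: str, templates=DEFAULT_TEMPLATES
) -> list[ClassSpec]:
    """Templates of that side whose height fits the membrane's free space."""
    free = free_space_nm(truth, membrane_id, side)
    return [t for t in templates if t.side == side and t.height_nm <= free]


def sweep_for(
    volume: DensityVolume,
    truth: GroundTruth,
    membrane_id: str,
    side: str,
    templates=DEFAULT_TEMPLATES,
    base_offset_nm: float = 1.5,
    step_nm: float = 0.5,
) -> MembranogramStack:
    """Offset sweep spanning the template heights for one membrane side."""
    side_templates = [t for t in templates if t.side == side]
    hmax = max((t.height_nm for t in side_templates), default=4.0)
    free = free_space_nm(truth, membrane_id, side)
    top = min(hmax + 2.0, free)
    offsets = np.concatenate(
        [[base_offset_nm], np.arange(2.0, top + step_nm / 2, step_nm)]
    )
    offsets = np.unique(offsets[offsets <= top])
    surf = truth.surface(membrane_id, side)
    return sweep_offsets(volume, surf, offsets)


def _signal_at(template: ClassSpec, offset: float) -> float:
    """Peak (single-lobe) template intensity at a given membrane offset."""
    if offset > template.height_nm:
        return 0.0
    return template.amplitude * math.exp(
        -((offset - template.z_center_nm) ** 2) / (2 * template.sigma_z**2)
    )


def _component_pose(values, bg, comp_mask):
    """Intensity-weighted centroid + principal-axis angle of one component."""
    weights = np.clip(values - bg, 0.0, None) * comp_mask
    ii, jj = np.nonzero(comp_mask)
    w = weights[ii, jj]
    total = w.sum()
    if total <= 0:
        w = np.ones_like(w)
        total = w.sum()
    ci = float((ii * w).sum() / total)
    cj = float((jj * w).sum() / total)
    di, dj = ii - ci, jj - cj
    cov = (
        np.array(
            [
                [(w * di * di).sum(), (w * di * dj).sum()],
                [(w * di * dj).sum(), (w * dj * dj).sum()],
            ]
        )
        / total
    )
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    return (ci, cj), math.atan2(axis[1], axis[0]) % math.pi


def detect_protrusions(
    stack: MembranogramStack,
    templates=DEFAULT_TEMPLATES,
    side: str | None = None,
    membrane_id: str | None = None,
    threshold_fraction: float = 0.5,
) -> ParticleSet:
    """Detect and classify protruding densities in an offset sweep.

    Classes are found tallest-first, mirroring height-ordered manual picking:
    each template is detected in the sweep layer halfway between its own
    height and the next-lower template height on the same side, where taller
    classes have already been found (and are excluded around their centres)
    and shorter classes have vanished. Components above
    ``background + threshold_fraction * template signal`` become particles;
    dimer axes come from intensity-weighted second moments in that layer.
    """
    if len(stack) == 0:
        raise ValueError("empty membranogram stack")
    side = side or stack.side or "stromal"
    membrane_id = membrane_id or stack.membrane_id
    side_templates = sorted(
        [t for t in templates if t.side == side], key=lambda t: -t.height_nm
    )
    if not side_templates:
        return ParticleSet()
    offsets = stack.offsets_nm
    if offsets.max() < max(t.height_nm for t in side_templates):
        raise ValueError(
            "offset sweep does not span template heights "
            f"(max offset {offsets.max()} nm)"
        )

    valid = stack.valid.all(axis=0)
    px = stack.param.pixel_size_nm
    bg = np.array([np.median(stack.values[k][valid]) for k in range(len(stack))])

    # Partition descending heights into groups of near-equal height (ratio
    # < 1.5); each group is detected in one layer halfway between the group's
    # lowest height and the next group's tallest (or the sweep base), and
    # classified within the group by footprint area.
    groups: list[list[ClassSpec]] = []
    for t in side_templates:
        if groups and groups[-1][-1].height_nm < 1.5 * t.height_nm:
            groups[-1].append(t)
        else:
            groups.append([t])
    plan: list[tuple[list[ClassSpec], int]] = []
    for gi, group in enumerate(groups):
        if gi + 1 < len(groups):
            target = 0.5 * (group[-1].height_nm + groups[gi + 1][0].height_nm)
        else:
            target = offsets.min()
        plan.append((group, int(np.argmin(np.abs(offsets - target)))))

    def thr_radius_nm(t: ClassSpec, offset: float, thr: float) -> float:
        """Lateral radius where one lobe of ``t`` drops to ``thr``."""
        s = _signal_at(t, offset)
        if s <= thr:
            return 0.0
        return t.sigma_xy * math.sqrt(2.0 * math.log(s / thr))

    out = ParticleSet()
    found: list[tuple[ClassSpec, float, float]] = []  # (template, ci, cj) px
    for group, k in plan:
        layer = stack.values[k]
        offset = float(offsets[k])
        signals = [_signal_at(t, offset) for t in group]
        if min(signals) <= 0:
            continue
        thr = threshold_fraction * min(signals)

        # exclude taller particles already found: radius where their residual
        # signal in this layer still exceeds the threshold
        exclusion = np.zeros_like(valid)
        ii = np.arange(exclusion.shape[0])[:, None]
        jj = np.arange(exclusion.shape[1])[None, :]
        for prev, pci, pcj in found:
            r_nm = thr_radius_nm(prev, offset, thr) + prev.separation_nm / 2.0 + px
            r = r_nm / px
            exclusion |= (ii - pci) ** 2 + (jj - pcj) ** 2 <= r**2

        fg = (layer - bg[k] > thr) & valid & ~exclusion
        # expected footprint area per template at this layer/threshold
        exp_area = {}
        for t in group:
            r_nm = thr_radius_nm(t, offset, thr)
            a = math.pi * r_nm**2 + 2.0 * r_nm * t.separation_nm
            exp_area[t.name] = max(a / px**2, 1.0)
        min_area = max(3, int(0.3 * min(exp_area.values())))
        labels, n_comp = ndimage.label(fg)
        for lab in range(1, n_comp + 1):
            comp = labels == lab
            area = int(comp.sum())
            if area < min_area:
                continue
            best = min(group, key=lambda t: abs(math.log(area / exp_area[t.name])))
            (ci, cj), angle_uv = _component_pose(layer, bg[k], comp)
            found.append((best, ci, cj))
            uv = stack.param.grid_origin_uv + np.array([ci, cj]) * px
            pos = stack.param.frame.lift(uv)[0]
            axis3 = (
                math.cos(angle_uv) * stack.param.frame.e1
                + math.sin(angle_uv) * stack.param.frame.e2
            )
            angle = math.atan2(axis3[1], axis3[0]) % math.pi if best.dimer else 0.0
            out.add(
                ParticleRecord(
                    particle_class=best.name,
                    position_nm=tuple(pos),
                    angle=float(angle),
                    membrane_id=membrane_id,
                    side=side,
                )
            )
    return out


def measure_scene(
    volume: DensityVolume,
    truth: GroundTruth,
    templates=DEFAULT_TEMPLATES,
) -> ParticleSet:
    """Run the full sweep + detection pipeline over every membrane side."""
    picked = ParticleSet()
    for sheet in truth.sheets:
        for side in ("stromal", "luminal"):
            vis = visible_templates(truth, sheet.membrane_id, side, templates)
            if not vis:
                continue
            stack = sweep_for(volume, truth, sheet.membrane_id, side, vis)
            picked.extend(
                detect_protrusions(
                    stack, vis, side=side, membrane_id=sheet.membrane_id
                )
            )
    return picked


def recovery_report(
    truth: GroundTruth | ParticleSet,
    picked: ParticleSet,
    tolerance_nm: float = 10.0,
):
    """Greedy one-to-one matching of picked to true particles per class.

    Returns a DataFrame with per-class precision, recall and localization
    RMSE over matched pairs.
    """
    import pandas as pd

    if tolerance_nm <= 0:
        raise ValueError("tolerance must be positive")
    true_ps = truth.particles if isinstance(truth, GroundTruth) else truth
    classes = sorted(
        set(true_ps.classes().tolist()) | set(picked.classes().tolist())
    )
    rows = []
    for cname in classes:
        t = true_ps.filter(particle_class=cname)
        p = picked.filter(particle_class=cname)
        tpos, ppos = t.positions_nm(), p.positions_nm()
        pairs = []
        for i in range(len(tpos)):
            for j in range(len(ppos)):
                if t[i].membrane_id != p[j].membrane_id:
                    continue
                d = float(np.linalg.norm(tpos[i] - ppos[j]))
                if d <= tolerance_nm:
                    pairs.append((d, i, j))
        pairs.sort()
        used_t, used_p, matched = set(), set(), []
        for d, i, j in pairs:
            if i in used_t or j in used_p:
                continue
            used_t.add(i)
            used_p.add(j)
            matched.append(d)
        n_match = len(matched)
        rows.append(
            {
                "class": cname,
                "n_true": len(t),
                "n_picked": len(p),
                "n_matched": n_match,
                "precision": n_match / len(p) if len(p) else np.nan,
                "recall": n_match / len(t) if len(t) else np.nan,
                "rmse_nm": float(np.sqrt(np.mean(np.square(matched))))
                if matched
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
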