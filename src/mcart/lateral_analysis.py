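"""Lateral-organization statistics: concentrations, stoichiometry,
nearest-neighbor distances, and intermembrane overlap.

Reference per-class concentrations measured on native Chlamydomonas thylakoid
membranes (particles per square micrometre, averaged over 84 membrane
regions) are shipped as :data:`REFERENCE_CONCENTRATIONS`; they drive the
synthetic presets and serve as documented inputs for reproduction runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from mcart.errors import GeometryError, SamplingError
from mcart.io_formats.particles import PARTICLE_CLASSES, ParticleSet
from mcart.membranogram import BinaryDensityMap, shift_map
from mcart.structure_models import MembraneModel

#: particles / um^2 by membrane region class. PSII entries are dimers.
REFERENCE_CONCENTRATIONS: dict[str, dict[str, float]] = {
    "non_appressed": {
        "PSII": 24.0,
        "CYTB6F": 501.0,
        "PSI": 1049.0,
        "ATPS": 1652.0,
        "RIBO": 113.0,
        "UNKNOWN": 1568.0,
    },
    "appressed": {
        "PSII": 1122.0,
        "CYTB6F": 631.0,
        "PSI": 2.0,
        "ATPS": 0.0,
        "RIBO": 0.0,
        "UNKNOWN": 170.0,
    },
}


@dataclass
class ConcentrationTable:
    """Per-region class concentrations (particles / um^2) with row totals."""

    table: pd.DataFrame  # index: region, columns: classes + "TOTAL"

    @classmethod
    def from_concentrations(cls, conc: dict[str, dict[str, float]]) -> "ConcentrationTable":
        df = pd.DataFrame(conc).T.reindex(columns=list(PARTICLE_CLASSES)).fillna(0.0)
        df["TOTAL"] = df[list(PARTICLE_CLASSES)].sum(axis=1)
        return cls(df)

    @classmethod
    def reference(cls) -> "ConcentrationTable":
        return cls.from_concentrations(REFERENCE_CONCENTRATIONS)

    def concentration(self, region: str, particle_class: str) -> float:
        return float(self.table.loc[region, particle_class])

    def total(self, region: str) -> float:
        return float(self.table.loc[region, "TOTAL"])

    @property
    def regions(self) -> list[str]:
        return list(self.table.index)


def class_concentrations(
    particles: ParticleSet, areas_um2: dict[str, float] | float,
    region_of_membrane: dict[str, str] | None = None,
) -> ConcentrationTable:
    """Count particles per class and normalize by region area.

    ``areas_um2`` is either a single area (all particles pooled into one
    region called ``"all"``) or a mapping region -> area; in the latter case
    ``region_of_membrane`` maps each membrane_id to its region.
    """
    if isinstance(areas_um2, (int, float)):
        areas = {"all": float(areas_um2)}
        region_of_membrane = None
    else:
        areas = {k: float(v) for k, v in areas_um2.items()}
    for region, area in areas.items():
        if area <= 0:
            raise ValueError(f"region {region!r} has non-positive area {area}")

    counts = {region: {c: 0 for c in PARTICLE_CLASSES} for region in areas}
    for rec in particles:
        if region_of_membrane is None:
            region = "all"
        else:
            region = region_of_membrane.get(rec.membrane_id)
            if region is None:
                raise KeyError(f"membrane {rec.membrane_id!r} has no region mapping")
        counts[region][rec.particle_class] += 1
    conc = {
        region: {c: counts[region][c] / areas[region] for c in PARTICLE_CLASSES}
        for region in areas
    }
    return ConcentrationTable.from_concentrations(conc)


def psii_psi_stoichiometry(
    table: ConcentrationTable, region_areas_um2: dict[str, float] | None = None
) -> float:
    """Monomeric PSII/PSI ratio, area-weighted over regions.

    PSII concentrations count dimers, hence the factor 2. With no areas given
    all regions are weighted equally.
    """
    regions = table.regions
    if region_areas_um2 is None:
        region_areas_um2 = {r: 1.0 for r in regions}
    psii = sum(table.concentration(r, "PSII") * region_areas_um2[r] for r in regions)
    psi = sum(table.concentration(r, "PSI") * region_areas_um2[r] for r in regions)
    if psi <= 0:
        raise ValueError("PSI concentration is zero everywhere; ratio undefined")
    return 2.0 * psii / psi


def nearest_neighbor_distances(
    coords_2d_nm: np.ndarray,
    classes: np.ndarray | None = None,
    exclusion_mask: np.ndarray | None = None,
    exclusion_pixel_nm: float = 1.0,
    within_class: bool = True,
) -> pd.DataFrame:
    """Euclidean nearest-neighbor distance per particle in the plane.

    Particles inside the (optional) binary exclusion mask — e.g. regions
    blanked for poly-ribosome clusters — are removed before computation.
    Distances are within-class unless ``within_class=False``. Classes with
    fewer than 2 surviving particles yield no rows (with a warning).
    """
    import warnings

    coords = np.atleast_2d(np.asarray(coords_2d_nm, dtype=float))
    if coords.shape[0] == 0:
        return pd.DataFrame(columns=["class", "u", "v", "nn_distance_nm"])
    if classes is None:
        classes = np.array(["all"] * len(coords))
    classes = np.asarray(classes)

    if exclusion_mask is not None:
        em = np.asarray(exclusion_mask).astype(bool)
        ij = np.floor(coords / exclusion_pixel_nm).astype(int)
        inside = (
            (ij[:, 0] >= 0)
            & (ij[:, 0] < em.shape[0])
            & (ij[:, 1] >= 0)
            & (ij[:, 1] < em.shape[1])
        )
        excluded = np.zeros(len(coords), dtype=bool)
        excluded[inside] = em[ij[inside, 0], ij[inside, 1]]
        coords = coords[~excluded]
        classes = classes[~excluded]

    rows = []
    groups = [(c, classes == c) for c in np.unique(classes)] if within_class else [
        ("all", np.ones(len(coords), dtype=bool))
    ]
    for cname, sel in groups:
        pts = coords[sel]
        if len(pts) < 2:
            warnings.warn(
                f"class {cname!r}: fewer than 2 particles after exclusion; "
                "no NN distances",
                stacklevel=2,
            )
            continue
        dist, _ = cKDTree(pts).query(pts, k=2)
        for (u, v), d in zip(pts, dist[:, 1]):
            rows.append({"class": cname, "u": u, "v": v, "nn_distance_nm": d})
    return pd.DataFrame(rows, columns=["class", "u", "v", "nn_distance_nm"])


@dataclass
class OverlayResult:
    """Voxel bookkeeping of a two-membrane superposition.

    white: masked by complexes/density from both membranes (counted once);
    green / magenta: masked only by membrane 1 / membrane 2.
    """

    white: int
    green: int
    magenta: int
    gap_type: str = "stromal_gap"  # or "lumen"

    @property
    def percentage(self) -> float:
        total = self.white + self.green + self.magenta
        if total == 0:
            return 0.0
        return 100.0 * self.white / total


def overlay_em_density(
    map1: BinaryDensityMap,
    map2: BinaryDensityMap,
    shift_px: tuple[int, int] = (0, 0),
    gap_type: str = "stromal_gap",
    min_valid_overlap: float = 0.5,
) -> OverlayResult:
    """Overlap of thresholded membranogram densities from two membranes.

    The maps must share a parameterization grid (same pixel size); ``shift_px``
    registers map2 onto map1. Counting happens on the intersection of the two
    cropped validity masks.
    """
    if map1.foreground.shape != map2.foreground.shape:
        raise GeometryError(
            f"maps have different grids {map1.foreground.shape} vs "
            f"{map2.foreground.shape}; resample to a common grid first"
        )
    if abs(map1.pixel_size_nm - map2.pixel_size_nm) > 1e-9:
        raise GeometryError("maps have different pixel sizes")
    if shift_px != (0, 0):
        map2 = shift_map(map2, shift_px)
    common = map1.valid & map2.valid
    denom = min(int(map1.valid.sum()), int(map2.valid.sum()))
    if denom == 0 or common.sum() < min_valid_overlap * denom:
        raise SamplingError(
            "valid-region overlap below "
            f"{min_valid_overlap:.0%}; membranes appear mis-registered"
        )
    f1 = map1.foreground & common
    f2 = map2.foreground & common
    return OverlayResult(
        white=int((f1 & f2).sum()),
        green=int((f1 & ~f2).sum()),
        magenta=int((f2 & ~f1).sum()),
        gap_type=gap_type,
    )


def overlay_models(
    model1: MembraneModel,
    model2: MembraneModel,
    tag: str = "FULL",
    gap_type: str = "stromal_gap",
) -> OverlayResult:
    """Overlap of placed-structure footprints between two parallel membranes.

    Instance footprints are extruded along the common membrane normal, so on
    the shared lateral grid the masked area from each membrane is its occupied
    mask restricted to its membrane voxels. Counts pool the masked voxels of
    both membranes (white — masked from both — counted once), matching the
    stated denominator "all masked voxels".
    """
    if model1.membrane.shape != model2.membrane.shape:
        raise GeometryError(
            "membrane models must share a lateral grid "
            f"({model1.membrane.shape} vs {model2.membrane.shape})"
        )
    if abs(model1.pixel_size_nm - model2.pixel_size_nm) > 1e-9:
        raise GeometryError("membrane models have different pixel sizes")
    occ1 = model1.occupied_mask(tag) & model1.membrane
    occ2 = model2.occupied_mask(tag) & model2.membrane
    return OverlayResult(
        white=int((occ1 & occ2).sum()),
        green=int((occ1 & ~occ2).sum()),
        magenta=int((occ2 & ~occ1).sum()),
        gap_type=gap_type,
    )
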