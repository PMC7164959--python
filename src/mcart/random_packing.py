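"""Collision-resolving random placement null model.

Particles are placed one-by-one at positions drawn uniformly over membrane
voxels with in-plane angles uniform over [0, 2*pi). When a new particle's
footprint overlaps an existing one, fresh random angles are tried at the same
position (up to ``max_rotation_attempts``); if all fail the particle is moved
to a fresh random position (up to ``max_relocation_attempts``). Exhausting the
budget raises — never silent under-packing.

The RNG is a counter-based Philox generator; one integer seed reproduces the
whole pipeline bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from mcart.errors import PackingError
from mcart.io_formats.particles import ParticleRecord, ParticleSet
from mcart.structure_models import (
    MembraneModel,
    Placement,
    StructureDensity,
    rotated_footprint,
)

_TWO_PI = 2.0 * math.pi


def make_rng(seed: int) -> np.random.Generator:
    """Counter-based generator used by every stochastic routine."""
    return np.random.Generator(np.random.Philox(seed))


@dataclass
class PackingConfig:
    n_particles: int
    max_rotation_attempts: int = 20
    max_relocation_attempts: int = 10_000
    seed: int = 0
    n_replicates: int = 100

    def __post_init__(self) -> None:
        if self.max_rotation_attempts < 1 or self.max_relocation_attempts < 1:
            raise ValueError("attempt budgets must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")


class _FootprintCache:
    """Rotated footprints quantized to 0.25 degrees (raster granularity only;
    the recorded particle angle stays continuous)."""

    def __init__(self, density: StructureDensity, step_deg: float = 0.25):
        self.density = density
        self.step = math.radians(step_deg)
        self._cache: dict[int, np.ndarray] = {}

    def mask(self, angle_rad: float) -> np.ndarray:
        key = int(round((angle_rad % _TWO_PI) / self.step))
        m = self._cache.get(key)
        if m is None:
            m = rotated_footprint(self.density, key * self.step)
            self._cache[key] = m
        return m


def _try_place(occupied, mask, i, j, wrap=False):
    """Check collision/containment; stamp and return True if placeable.

    With ``wrap`` the footprint wraps around the grid edges (toroidal
    membrane); otherwise it must fit inside the grid.
    """
    h, w = mask.shape
    i0 = i - (h - 1) // 2
    j0 = j - (w - 1) // 2
    if not wrap:
        if i0 < 0 or j0 < 0 or i0 + h > occupied.shape[0] or j0 + w > occupied.shape[1]:
            return False
        window = occupied[i0 : i0 + h, j0 : j0 + w]
        if (window & mask).any():
            return False
        window |= mask
        return True
    sel = np.ix_(
        np.arange(i0, i0 + h) % occupied.shape[0],
        np.arange(j0, j0 + w) % occupied.shape[1],
    )
    if (occupied[sel] & mask).any():
        return False
    occupied[sel] |= mask
    return True


def random_placement(
    membrane_mask: np.ndarray,
    pixel_size_nm: float,
    density: StructureDensity | dict[str, StructureDensity],
    config: PackingConfig,
    rng: np.random.Generator | None = None,
    membrane_id: str = "random",
    max_area_fraction: float = 0.9,
    wrap: bool = False,
    _caches: dict[str, "_FootprintCache"] | None = None,
) -> MembraneModel:
    """Place ``config.n_particles`` non-overlapping instances at random.

    Footprints must fit inside the lateral grid; collisions are tested against
    the union of previously placed footprints (same iso-thresholded footprints
    as occupancy measurement). Returns a :class:`MembraneModel` whose
    placements carry every requested tag.
    """
    if isinstance(density, StructureDensity):
        densities = {density.tag: density}
    else:
        densities = dict(density)
    primary_tag = "FULL" if "FULL" in densities else next(iter(densities))
    primary = densities[primary_tag]

    membrane_mask = np.asarray(membrane_mask).astype(bool)
    area_needed = config.n_particles * int(primary.footprint().sum())
    if area_needed > max_area_fraction * int(membrane_mask.sum()):
        raise PackingError(
            f"requested footprint area ({area_needed} px) exceeds "
            f"{max_area_fraction:.0%} of the membrane ({int(membrane_mask.sum())} px); "
            "packing is infeasible"
        )
    rng = rng if rng is not None else make_rng(config.seed)
    if _caches is None:
        _caches = {tag: _FootprintCache(d) for tag, d in densities.items()}
    cache = _caches[primary_tag]
    part_caches = {tag: c for tag, c in _caches.items() if tag != primary_tag}

    voxels = np.argwhere(membrane_mask)
    occupied = np.zeros_like(membrane_mask)
    model = MembraneModel(
        membrane_mask, pixel_size_nm, membrane_id=membrane_id, wrap=wrap
    )
    for n in range(config.n_particles):
        placed = False
        for _ in range(config.max_relocation_attempts):
            i, j = voxels[rng.integers(len(voxels))]
            angle = rng.uniform(0.0, _TWO_PI)
            if _try_place(occupied, cache.mask(angle), i, j, wrap):
                placed = True
            else:
                for _ in range(config.max_rotation_attempts):
                    angle = rng.uniform(0.0, _TWO_PI)
                    if _try_place(occupied, cache.mask(angle), i, j, wrap):
                        placed = True
                        break
            if placed:
                footprints = {primary_tag: cache.mask(angle)}
                for tag, pc in part_caches.items():
                    footprints[tag] = pc.mask(angle)
                model.placements.append(Placement((int(i), int(j)), float(angle), footprints))
                break
        if not placed:
            raise PackingError(
                f"relocation budget exhausted after placing {n} of "
                f"{config.n_particles} particles"
            )
    return model


def sequential_pack(
    membrane_mask: np.ndarray,
    requests: list[tuple[str, int, StructureDensity]],
    rng: np.random.Generator,
    max_rotation_attempts: int = 20,
    max_relocation_attempts: int = 10_000,
) -> list[tuple[str, int, int, float]]:
    """Pack several particle classes onto one shared occupancy grid.

    ``requests`` is a list of ``(class_name, count, footprint_density)``;
    classes are placed in the given order with the same rotate-then-relocate
    collision rule as :func:`random_placement`. Returns
    ``(class_name, i, j, angle)`` tuples in placement order.
    """
    membrane_mask = np.asarray(membrane_mask).astype(bool)
    voxels = np.argwhere(membrane_mask)
    occupied = np.zeros_like(membrane_mask)
    out: list[tuple[str, int, int, float]] = []
    for name, count, dens in requests:
        cache = _FootprintCache(dens)
        for n in range(count):
            placed = False
            for _ in range(max_relocation_attempts):
                i, j = voxels[rng.integers(len(voxels))]
                angle = rng.uniform(0.0, _TWO_PI)
                if _try_place(occupied, cache.mask(angle), i, j):
                    placed = True
                else:
                    for _ in range(max_rotation_attempts):
                        angle = rng.uniform(0.0, _TWO_PI)
                        if _try_place(occupied, cache.mask(angle), i, j):
                            placed = True
                            break
                if placed:
                    out.append((name, int(i), int(j), float(angle)))
                    break
            if not placed:
                raise PackingError(
                    f"class {name}: relocation budget exhausted after placing "
                    f"{n} of {count} particles"
                )
    return out


def model_particles(model: MembraneModel, particle_class: str = "PSII",
                    side: str = "luminal") -> ParticleSet:
    """Export a model's placements as a particle table."""
    ps = ParticleSet()
    for p in model.placements:
        ps.add(
            ParticleRecord(
                particle_class=particle_class,
                position_nm=(
                    p.center_px[0] * model.pixel_size_nm,
                    p.center_px[1] * model.pixel_size_nm,
                    0.0,
                ),
                angle=p.angle,
                membrane_id=model.membrane_id,
                side=side,
            )
        )
    return ps


@dataclass
class OverlapDistribution:
    """Replicate intermembrane overlap percentages from the null model."""

    percentages: np.ndarray
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.percentages))

    @property
    def sd(self) -> float:
        return float(np.std(self.percentages, ddof=1)) if len(self.percentages) > 1 else 0.0

    @property
    def n(self) -> int:
        return len(self.percentages)


def simulate_random_overlap(
    mask1: np.ndarray,
    mask2: np.ndarray,
    n1: int,
    n2: int,
    density: StructureDensity | dict[str, StructureDensity],
    config: PackingConfig,
    tag: str = "FULL",
    rerandomize: str = "both",
    wrap: bool = False,
) -> OverlapDistribution:
    """Null distribution of intermembrane overlap between two parallel membranes.

    Per replicate, ``n1``/``n2`` instances are randomly packed on each
    membrane (``rerandomize='both'``) or only on the second membrane
    (``'second'``; the first is packed once and held fixed), footprints are
    extruded along the common normal, and the overlap percentage
    ``100 * white / (white + green + magenta)`` is recorded.
    """
    from mcart.lateral_analysis import overlay_models  # cycle-free at runtime

    if rerandomize not in ("both", "second"):
        raise ValueError("rerandomize must be 'both' or 'second'")
    if isinstance(density, StructureDensity):
        caches = {density.tag: _FootprintCache(density)}
    else:
        caches = {t: _FootprintCache(d) for t, d in density.items()}
    rng = make_rng(config.seed)
    pct = np.empty(config.n_replicates)
    fixed_model = None
    if rerandomize == "second":
        cfg1 = PackingConfig(
            n1, config.max_rotation_attempts, config.max_relocation_attempts,
            config.seed, config.n_replicates,
        )
        fixed_model = random_placement(mask1, 1.0, density, cfg1, rng, "m1", wrap=wrap, _caches=caches)
    for r in range(config.n_replicates):
        try:
            if rerandomize == "both":
                cfg1 = PackingConfig(
                    n1, config.max_rotation_attempts, config.max_relocation_attempts
                )
                m1 = random_placement(mask1, 1.0, density, cfg1, rng, "m1", wrap=wrap, _caches=caches)
            else:
                m1 = fixed_model
            cfg2 = PackingConfig(
                n2, config.max_rotation_attempts, config.max_relocation_attempts
            )
            m2 = random_placement(mask2, 1.0, density, cfg2, rng, "m2", wrap=wrap, _caches=caches)
        except PackingError as exc:
            raise PackingError(f"replicate {r}: {exc}") from exc
        pct[r] = overlay_models(m1, m2, tag=tag).percentage
    return OverlapDistribution(pct, config.seed)


@dataclass
class WelchResult:
    """Welch's unequal-variance two-sample t-test."""

    t: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p_value": self.p_value,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sd_a": self.sd_a,
            "sd_b": self.sd_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def welch_t_test(sample_a, sample_b) -> WelchResult:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(
                0.0, float(len(a) + len(b) - 2), 1.0,
                float(a.mean()), float(b.mean()), 0.0, 0.0, len(a), len(b),
            )
        raise ValueError("both samples have zero variance and unequal means")
    sa2, sb2 = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(sa2 + sb2)
    df = (sa2 + sb2) ** 2 / (
        sa2**2 / (len(a) - 1) + sb2**2 / (len(b) - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(
        float(t), float(df), p,
        float(a.mean()), float(b.mean()),
        float(a.std(ddof=1)), float(b.std(ddof=1)),
        len(a), len(b),
    )
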