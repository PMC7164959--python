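"""Particle annotation tables (CSV-first, JSON mirror).

A particle is one picked macromolecular complex: class label, 3D position in
nanometres (volume frame), in-plane rotation about the local surface normal,
host membrane and membrane side.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from mcart.errors import FormatError

PARTICLE_CLASSES = ("PSII", "CYTB6F", "PSI", "ATPS", "RIBO", "UNKNOWN")
SIDES = ("stromal", "luminal")
CONFIDENCES = ("high", "low")

_COLUMNS = ["class", "x", "y", "z", "angle", "membrane_id", "side", "confidence"]
_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ParticleRecord:
    """One picked complex. Position in nm; angle in radians, [0, 2*pi)."""

    particle_class: str
    position_nm: tuple[float, float, float]
    angle: float = 0.0
    membrane_id: str = ""
    side: str = "stromal"
    confidence: str = "high"

    def __post_init__(self) -> None:
        if self.particle_class not in PARTICLE_CLASSES:
            raise FormatError(
                f"unknown particle class {self.particle_class!r}; "
                f"expected one of {PARTICLE_CLASSES}"
            )
        if self.side not in SIDES:
            raise FormatError(f"unknown side {self.side!r}; expected one of {SIDES}")
        if self.confidence not in CONFIDENCES:
            raise FormatError(f"unknown confidence {self.confidence!r}")
        if not (0.0 <= self.angle < _TWO_PI):
            warnings.warn(
                f"angle {self.angle} outside [0, 2*pi); normalizing", stacklevel=3
            )
            object.__setattr__(self, "angle", self.angle % _TWO_PI)


@dataclass
class ParticleSet:
    """Ordered collection of :class:`ParticleRecord`."""

    records: list[ParticleRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticleRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def add(self, record: ParticleRecord) -> None:
        self.records.append(record)

    def extend(self, records: Iterable[ParticleRecord]) -> None:
        self.records.extend(records)

    def filter(self, particle_class=None, membrane_id=None, side=None) -> "ParticleSet":
        out = [
            r
            for r in self.records
            if (particle_class is None or r.particle_class == particle_class)
            and (membrane_id is None or r.membrane_id == membrane_id)
            and (side is None or r.side == side)
        ]
        return ParticleSet(out)

    def positions_nm(self) -> np.ndarray:
        if not self.records:
            return np.zeros((0, 3))
        return np.array([r.position_nm for r in self.records], dtype=float)

    def angles(self) -> np.ndarray:
        return np.array([r.angle for r in self.records], dtype=float)

    def classes(self) -> np.ndarray:
        return np.array([r.particle_class for r in self.records])

    def membrane_ids(self) -> list[str]:
        return sorted({r.membrane_id for r in self.records})

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.particle_class] = out.get(r.particle_class, 0) + 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "class": r.particle_class,
                "x": r.position_nm[0],
                "y": r.position_nm[1],
                "z": r.position_nm[2],
                "angle": r.angle,
                "membrane_id": r.membrane_id,
                "side": r.side,
                "confidence": r.confidence,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ParticleSet":
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"particle table is missing columns: {missing}")
        records = [
            ParticleRecord(
                particle_class=str(row["class"]),
                position_nm=(float(row["x"]), float(row["y"]), float(row["z"])),
                angle=float(row["angle"]),
                membrane_id=str(row["membrane_id"]),
                side=str(row["side"]),
                confidence=str(row["confidence"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(records)

    def translated(self, shift_nm) -> "ParticleSet":
        s = np.asarray(shift_nm, dtype=float)
        return ParticleSet(
            [
                replace(r, position_nm=tuple(np.asarray(r.position_nm) + s))
                for r in self.records
            ]
        )


def read_particles(path: str | Path) -> ParticleSet:
    """Read a particle table from CSV (with header) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload.get("particles", []), columns=_COLUMNS)
    else:
        df = pd.read_csv(path, dtype={"class": str, "membrane_id": str})
        if len(df) == 0:
            missing = [c for c in _COLUMNS if c not in df.columns]
            if missing:
                raise FormatError(f"particle table is missing columns: {missing}")
    return ParticleSet.from_dataframe(df)


def write_particles(particles: ParticleSet, path: str | Path) -> None:
    """Write a particle table to CSV or JSON (chosen by extension)."""
    path = Path(path)
    df = particles.to_dataframe()
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps({"particles": df.to_dict(orient="records")}, indent=1)
        )
    else:
        df.to_csv(path, index=False)
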