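"""Stimulation-point (DES seed) tables.

A seed is one direct-electrical-stimulation site: an MNI mm coordinate, the
functional category whose testing it disrupted, and whether it was delivered
cortically or subcortically.  Twelve functional categories form the closed
vocabulary of the intraoperative battery; synthetic categories (prefix
``synthetic``) and caller-supplied extras are accepted for generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "LOCATIONS",
    "CategoryError",
    "SeedPoint",
    "SeedSet",
    "read_seed_table",
    "write_seed_table",
]

#: The twelve functional categories assessed during awake-surgery mapping.
CATEGORIES: tuple[str, ...] = (
    "anomia",
    "semantic_paraphasia",
    "phonological_paraphasia",
    "semantic_association",
    "motor",
    "sensory",
    "mentalizing",
    "movement_arrest",
    "spatial_perception",
    "speech_arrest",
    "verbal_apraxia",
    "visual",
)

LOCATIONS = ("cortical", "subcortical")


class CategoryError(ValueError):
    """A category label outside the declared vocabulary."""


def _check_category(category: str, extra: Sequence[str] = ()) -> None:
    if category in CATEGORIES or category in extra:
        return
    if category.startswith("synthetic"):
        return
    raise CategoryError(
        f"unknown functional category {category!r}; expected one of "
        f"{CATEGORIES} (or a 'synthetic*' label)"
    )


@dataclass(frozen=True)
class SeedPoint:
    """One stimulation site in MNI millimetre space."""

    xyz_mm: tuple[float, float, float]
    category: str
    location: str = "cortical"
    patient_id: str = "unknown"

    def __post_init__(self) -> None:
        xyz = tuple(float(v) for v in self.xyz_mm)
        if len(xyz) != 3 or not all(np.isfinite(xyz)):
            raise ValueError(f"xyz_mm must be 3 finite reals, got {self.xyz_mm}")
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}")
        object.__setattr__(self, "xyz_mm", xyz)


@dataclass
class SeedSet:
    """An ordered collection of :class:`SeedPoint` with provenance."""

    points: list[SeedPoint]
    provenance: str = ""
    extra_categories: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.points = list(self.points)
        for p in self.points:
            _check_category(p.category, self.extra_categories)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[SeedPoint]:
        return iter(self.points)

    def __getitem__(self, i: int) -> SeedPoint:
        return self.points[i]

    @property
    def categories(self) -> list[str]:
        """Distinct categories in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.points:
            seen.setdefault(p.category, None)
        return list(seen)

    def subset(self, category: str | None = None, location: str | None = None) -> "SeedSet":
        pts = [
            p
            for p in self.points
            if (category is None or p.category == category)
            and (location is None or p.location == location)
        ]
        return SeedSet(pts, provenance=self.provenance, extra_categories=self.extra_categories)

    def coords(self) -> np.ndarray:
        return np.array([p.xyz_mm for p in self.points], dtype=float).reshape(-1, 3)


_COLUMNS = ("x", "y", "z", "category", "location", "patient_id")


def read_seed_table(path, extra_categories: Iterable[str] = ()) -> SeedSet:
    """Read a TSV/CSV seed table with columns x,y,z,category,location,patient_id.

    Parsing is order-preserving; an unknown category label is rejected.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"seed table {path} is missing columns {missing}")
    extra = tuple(extra_categories)
    points = [
        SeedPoint(
            xyz_mm=(row.x, row.y, row.z),
            category=str(row.category),
            location=str(row.location),
            patient_id=str(row.patient_id),
        )
        for row in df.itertuples(index=False)
    ]
    return SeedSet(points, provenance=str(path), extra_categories=extra)


def write_seed_table(path, seeds: SeedSet) -> None:
    rows = [
        {
            "x": p.xyz_mm[0],
            "y": p.xyz_mm[1],
            "z": p.xyz_mm[2],
            "category": p.category,
            "location": p.location,
            "patient_id": p.patient_id,
        }
        for p in seeds
    ]
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(path, sep=sep, index=False)
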