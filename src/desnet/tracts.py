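"""Streamline handling: structure-function coupling of subcortical points.

A subcortical stimulation point is coupled to the cortical networks by (1)
selecting tractogram streamlines that pass within a seed radius of the point
— using segment-aware sphere intersection, so a streamline whose polyline
crosses the sphere between two vertices still counts — and (2) computing the
percentage of selected streamlines whose endpoints terminate in the positive
vs negative network territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np

from .grid import MaskVolume, VolumeGrid

__all__ = [
    "Tractogram",
    "ConnectionSummary",
    "select_streamlines",
    "connection_percentages",
    "cohort_connection_summary",
    "read_tractogram",
    "write_tractogram",
]


@dataclass
class Tractogram:
    """Streamlines as (N_i, 3) mm polylines plus provenance."""

    streamlines: list[np.ndarray]
    subject_id: str = ""
    space: str = "mm"

    def __post_init__(self) -> None:
        checked = []
        for s in self.streamlines:
            arr = np.asarray(s, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError("each streamline needs >= 2 points of 3 coords")
            if not np.all(np.isfinite(arr)):
                raise ValueError("streamline coordinates must be finite")
            if np.any(np.all(np.diff(arr, axis=0) == 0, axis=1)):
                raise ValueError("consecutive streamline points must be distinct")
            checked.append(arr)
        self.streamlines = checked
        if self.space != "mm":
            raise ValueError("tractograms must be in mm (RAS) space before analysis")

    def __len__(self) -> int:
        return len(self.streamlines)


def _min_dist_to_segments(poly: np.ndarray, point: np.ndarray) -> float:
    """Minimum Euclidean distance from ``point`` to the polyline (segments
    included, not just vertices)."""
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    ap = point[None, :] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", ap, ab) / denom, 0.0, 1.0)
    closest = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(closest - point[None, :], axis=1)))


def select_streamlines(tractogram: Tractogram, point, radius_mm: float) -> Tractogram:
    """Streamlines passing within ``radius_mm`` of the point (segment test)."""
    if len(tractogram) == 0:
        raise ValueError("empty tractogram")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    xyz = np.asarray(getattr(point, "xyz_mm", point), dtype=float)
    kept = [
        s
        for s in tractogram.streamlines
        if _min_dist_to_segments(s, xyz) <= radius_mm
    ]
    return Tractogram(kept, subject_id=tractogram.subject_id, space=tractogram.space)


@dataclass
class ConnectionSummary:
    """Percent of selected streamlines reaching each network territory."""

    n_selected: int
    pct_pos: float | None
    pct_neg: float | None
    defined: bool = True
    n_undefined_excluded: int = 0

    def __post_init__(self) -> None:
        if self.defined:
            for pct in (self.pct_pos, self.pct_neg):
                if pct is None or not 0 <= pct <= 100:
                    raise ValueError("percentages must lie in [0, 100]")
            if self.pct_pos + self.pct_neg > 100 + 1e-9:
                raise ValueError("pct_pos + pct_neg cannot exceed 100")


def _endpoint_in_mask(endpoint: np.ndarray, mask: MaskVolume) -> bool:
    grid = mask.grid
    cont = np.linalg.solve(
        grid.affine[:3, :3], endpoint - grid.affine[:3, 3]
    )
    idx = np.trunc(cont + np.copysign(0.5, cont)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.dims)):
        return False  # endpoints outside the grid belong to no network
    return bool(mask.values[tuple(idx)])


def connection_percentages(
    selected: Tractogram, pos_mask: MaskVolume, neg_mask: MaskVolume
) -> ConnectionSummary:
    """Endpoint-based membership: a streamline counts for a network iff either
    endpoint's containing voxel is in that network's mask.

    With no selected streamlines the summary is flagged undefined rather than
    reported as 0 percent.
    """
    pos_mask.grid.check_same(neg_mask.grid, "connection_percentages")
    if np.any(pos_mask.values & neg_mask.values):
        raise ValueError("positive and negative network masks must be disjoint")
    n = len(selected)
    if n == 0:
        return ConnectionSummary(0, None, None, defined=False)
    n_pos = n_neg = 0
    for s in selected.streamlines:
        ends = (s[0], s[-1])
        if any(_endpoint_in_mask(e, pos_mask) for e in ends):
            n_pos += 1
        if any(_endpoint_in_mask(e, neg_mask) for e in ends):
            n_neg += 1
    return ConnectionSummary(n, 100.0 * n_pos / n, 100.0 * n_neg / n)


def cohort_connection_summary(
    summaries: Sequence[ConnectionSummary],
) -> ConnectionSummary:
    """Mean of per-subject percentages; undefined subjects are excluded and
    counted."""
    defined = [s for s in summaries if s.defined]
    if not defined:
        raise ValueError("all per-subject summaries are undefined")
    return ConnectionSummary(
        n_selected=int(np.sum([s.n_selected for s in defined])),
        pct_pos=float(np.mean([s.pct_pos for s in defined])),
        pct_neg=float(np.mean([s.pct_neg for s in defined])),
        n_undefined_excluded=len(summaries) - len(defined),
    )


def read_tractogram(path, subject_id: str = "") -> Tractogram:
    """Read TRK/TCK; streamlines are returned in mm (RAS) space."""
    tf = nib.streamlines.load(str(path))  # applies affine_to_rasmm
    return Tractogram([np.asarray(s) for s in tf.streamlines], subject_id=subject_id)


def write_tractogram(path, tractogram: Tractogram, grid: VolumeGrid | None = None) -> None:
    """Write TRK/TCK with streamlines already in mm (RAS) space."""
    sl = nib.streamlines.Tractogram(
        tractogram.streamlines, affine_to_rasmm=np.eye(4)
    )
    header = {}
    if str(path).endswith(".trk") and grid is not None:
        header = {
            "voxel_to_rasmm": grid.affine.astype(np.float32),
            "voxel_sizes": grid.voxel_size.astype(np.float32),
            "dimensions": np.asarray(grid.dims, dtype=np.int16),
        }
    nib.streamlines.save(sl, str(path), header=header)
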