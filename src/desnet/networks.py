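"""Category-level network construction.

Per-seed significance masks are aggregated into *frequency maps* — at each
voxel, the percentage of a category's seeds whose map is significant there —
separately for the positively and negatively coupled tail.  The two polarities
are then resolved into a bipartite voxel labelling, and the grey-matter
coverage of the network is compared against a points-only probabilistic atlas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid import MaskVolume, ScalarVolume, VolumeGrid, sphere_mask
from .seeds import SeedSet

__all__ = [
    "FrequencyMap",
    "BipartiteNetwork",
    "CoverageReport",
    "frequency_map",
    "bipartite_assign",
    "probabilistic_des_atlas",
    "coverage_report",
    "threshold_network",
    "positive_percentile_cutoff",
]

POLARITIES = ("positive", "negative")


@dataclass
class FrequencyMap:
    """Voxelwise percentage of seeds with significant connectivity."""

    grid: VolumeGrid
    freq: np.ndarray  # percent, in [0, 100]
    polarity: str
    category: str
    n_seeds: int

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        freq = np.asarray(self.freq, dtype=float)
        if freq.shape != self.grid.dims:
            raise ValueError("freq shape does not match grid")
        if freq.min() < 0 or freq.max() > 100:
            raise ValueError("frequencies must lie in [0, 100]")
        self.freq = freq

    @property
    def support(self) -> np.ndarray:
        return self.freq > 0


@dataclass
class BipartiteNetwork:
    """Voxel labels: +1 positive network, -1 negative network, 0 unassigned."""

    grid: VolumeGrid
    label: np.ndarray
    category: str

    def __post_init__(self) -> None:
        lab = np.asarray(self.label)
        if lab.shape != self.grid.dims:
            raise ValueError("label shape does not match grid")
        if not np.all(np.isin(np.unique(lab), (-1, 0, 1))):
            raise ValueError("labels must be in {-1, 0, +1}")
        self.label = lab.astype(np.int8)


@dataclass
class CoverageReport:
    pct_gm_network: float
    pct_gm_atlas: float
    fold_increase: float | None  # None when the atlas covers no grey matter


def frequency_map(
    per_seed_masks: Sequence[MaskVolume], polarity: str, category: str
) -> FrequencyMap:
    """freq_v = 100 * (#masks with voxel v set) / n_seeds."""
    if len(per_seed_masks) == 0:
        raise ValueError("need at least one per-seed mask")
    grid = per_seed_masks[0].grid
    counts = np.zeros(grid.dims, dtype=np.int64)
    for m in per_seed_masks:
        m.grid.check_same(grid, "frequency_map")
        counts += m.values
    freq = 100.0 * counts / len(per_seed_masks)
    return FrequencyMap(grid, freq, polarity, category, n_seeds=len(per_seed_masks))


def bipartite_assign(pos: FrequencyMap, neg: FrequencyMap) -> BipartiteNetwork:
    """Label +1 where pos > neg (and pos > 0), -1 where neg > pos (and neg > 0),
    0 on ties and double zeros."""
    if pos.polarity != "positive" or neg.polarity != "negative":
        raise ValueError("expected a (positive, negative) frequency-map pair")
    if pos.category != neg.category:
        raise ValueError("frequency maps belong to different categories")
    pos.grid.check_same(neg.grid, "bipartite_assign")
    label = np.zeros(pos.grid.dims, dtype=np.int8)
    label[(pos.freq > neg.freq) & (pos.freq > 0)] = 1
    label[(neg.freq > pos.freq) & (neg.freq > 0)] = -1
    return BipartiteNetwork(pos.grid, label, pos.category)


def probabilistic_des_atlas(
    seeds: SeedSet, atlas_radius_mm: float, grid: VolumeGrid
) -> ScalarVolume:
    """Points-only probabilistic atlas: percentage of seed spheres covering
    each voxel; support is the union of the spheres."""
    if len(seeds) == 0:
        raise ValueError("empty seed set")
    counts = np.zeros(grid.dims, dtype=np.int64)
    for p in seeds:
        counts += sphere_mask(p.xyz_mm, atlas_radius_mm, grid).values
    return ScalarVolume(grid, 100.0 * counts / len(seeds))


def coverage_report(
    freq: FrequencyMap, atlas: ScalarVolume, gm_mask: MaskVolume
) -> CoverageReport:
    """Percent of grey-matter voxels covered (value > 0) by network vs atlas."""
    freq.grid.check_same(atlas.grid, "coverage_report")
    freq.grid.check_same(gm_mask.grid, "coverage_report")
    n_gm = gm_mask.n_true
    if n_gm == 0:
        raise ValueError("empty grey-matter mask")
    pct_net = 100.0 * np.count_nonzero(freq.freq[gm_mask.values] > 0) / n_gm
    pct_atl = 100.0 * np.count_nonzero(atlas.values[gm_mask.values] > 0) / n_gm
    fold = pct_net / pct_atl if pct_atl > 0 else None
    return CoverageReport(pct_net, pct_atl, fold)


def positive_percentile_cutoff(
    freq: FrequencyMap, percentile: float, gm_mask: MaskVolume | None = None
) -> float:
    """Linear-interpolation percentile of the strictly positive (in-GM)
    frequencies.  Shared by network thresholding, hub selection and resection
    scoring so all cutoffs agree."""
    vals = freq.freq if gm_mask is None else freq.freq[gm_mask.values]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("no strictly positive frequencies to take a percentile of")
    return float(np.percentile(vals, percentile))


def threshold_network(
    freq: FrequencyMap,
    mode: str,
    value: float,
    gm_mask: MaskVolume | None = None,
) -> MaskVolume:
    """Binarize a frequency map.

    mode='absolute': mask = freq >= value (percent).
    mode='percentile': cutoff = value-th percentile of strictly positive
    in-GM frequencies; mask = freq >= cutoff.
    """
    if not 0 <= value <= 100:
        raise ValueError("value must be in [0, 100]")
    if mode == "absolute":
        cutoff = value
    elif mode == "percentile":
        cutoff = positive_percentile_cutoff(freq, value, gm_mask)
    else:
        raise ValueError("mode must be 'absolute' or 'percentile'")
    return MaskVolume(freq.grid, freq.freq >= max(cutoff, np.nextafter(0, 1)))
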