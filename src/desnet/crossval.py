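"""Leave-one-out predictive validation of stimulation-derived networks.

For every stimulation point, the category's positive/negative frequency maps
are rebuilt *without* that point (an exact decrement of the aggregation
counts) and the left-out point is classified as predictive when its mean
concordance with the positive network exceeds that with the negative network.
Exceedance curves summarize how strongly correctly classified points load on
their network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .grid import MaskVolume, sphere_mask
from .networks import FrequencyMap
from .seeds import SeedPoint, SeedSet

__all__ = [
    "LooResult",
    "ExceedanceCurve",
    "concordance_rate",
    "loo_frequency_map",
    "loo_validate",
    "exceedance_curve",
]


def loo_frequency_map(
    per_seed_masks: Sequence[MaskVolume],
    leave_out: int,
    polarity: str,
    category: str,
    counts: np.ndarray | None = None,
) -> FrequencyMap:
    """Frequency map over all masks except ``leave_out``, by count decrement.

    Passing the precomputed aggregation ``counts`` makes every left-out map an
    O(voxels) recount; the result is voxel-exact equal to rebuilding from the
    explicit n-1 subset.
    """
    n = len(per_seed_masks)
    if n < 2:
        raise ValueError("need at least 2 masks to leave one out")
    grid = per_seed_masks[0].grid
    if counts is None:
        counts = np.zeros(grid.dims, dtype=np.int64)
        for m in per_seed_masks:
            m.grid.check_same(grid, "loo_frequency_map")
            counts = counts + m.values
    freq = 100.0 * (counts - per_seed_masks[leave_out].values) / (n - 1)
    return FrequencyMap(grid, freq, polarity, category, n_seeds=n - 1)


def concordance_rate(point: SeedPoint, freq: FrequencyMap, radius_mm: float) -> float:
    """Mean frequency (as a fraction in [0, 1]) over the point's sphere voxels.

    Radius 0 reads the single voxel containing the point.
    """
    sph = sphere_mask(point.xyz_mm, radius_mm, freq.grid)
    return float(freq.freq[sph.values].mean() / 100.0)


@dataclass
class LooResult:
    """Per-point leave-one-out classification and pooled accuracy.

    ``table`` has one row per point: category, c_pos, c_neg, predictive.
    ``accuracy`` pools every point of every category with equal weight.
    """

    table: pd.DataFrame
    accuracy: float
    per_category_accuracy: dict[str, float]

    @property
    def median_c_pos(self) -> float:
        return float(self.table["c_pos"].median())

    @property
    def median_c_neg(self) -> float:
        return float(self.table["c_neg"].median())


def loo_validate(
    seed_set: SeedSet,
    per_seed_pos_masks: Sequence[MaskVolume],
    per_seed_neg_masks: Sequence[MaskVolume],
    config: AnalysisConfig,
) -> LooResult:
    """Classify every point against networks built from the other n-1 points.

    The LOO frequency map for point i is the aggregation count minus point
    i's own mask, over n-1 — exactly equal to rebuilding from the subset.
    A point is predictive iff c_pos > c_neg (ties are not predictive).
    """
    n = len(seed_set)
    if not (n == len(per_seed_pos_masks) == len(per_seed_neg_masks)):
        raise ValueError("one positive and one negative mask required per seed")
    records = []
    for category in seed_set.categories:
        idx = [i for i, p in enumerate(seed_set) if p.category == category]
        if len(idx) < 2:
            raise ValueError(
                f"category {category!r} has {len(idx)} point(s); "
                "leave-one-out needs at least 2"
            )
        grid = per_seed_pos_masks[idx[0]].grid
        pos_count = np.zeros(grid.dims, dtype=np.int64)
        neg_count = np.zeros(grid.dims, dtype=np.int64)
        for i in idx:
            per_seed_pos_masks[i].grid.check_same(grid, "loo_validate")
            per_seed_neg_masks[i].grid.check_same(grid, "loo_validate")
            pos_count += per_seed_pos_masks[i].values
            neg_count += per_seed_neg_masks[i].values
        cat_pos = [per_seed_pos_masks[i] for i in idx]
        cat_neg = [per_seed_neg_masks[i] for i in idx]
        for local_i, i in enumerate(idx):
            point = seed_set[i]
            loo_pos = loo_frequency_map(cat_pos, local_i, "positive", category,
                                        counts=pos_count)
            loo_neg = loo_frequency_map(cat_neg, local_i, "negative", category,
                                        counts=neg_count)
            c_pos = concordance_rate(point, loo_pos, config.seed_radius_mm)
            c_neg = concordance_rate(point, loo_neg, config.seed_radius_mm)
            records.append(
                {
                    "point_index": i,
                    "patient_id": point.patient_id,
                    "category": category,
                    "c_pos": c_pos,
                    "c_neg": c_neg,
                    "predictive": c_pos > c_neg,
                }
            )
    table = pd.DataFrame.from_records(records)
    accuracy = float(table["predictive"].mean())
    per_cat = {
        cat: float(sub["predictive"].mean())
        for cat, sub in table.groupby("category", sort=False)
    }
    return LooResult(table=table, accuracy=accuracy, per_category_accuracy=per_cat)


@dataclass
class ExceedanceCurve:
    """Survival function of c_pos over correctly classified points."""

    thresholds: np.ndarray  # frequency fractions in [0, 1]
    prob: np.ndarray
    category: str
    empty: bool = False


def exceedance_curve(
    loo: LooResult, category: str, n_thresholds: int = 101
) -> ExceedanceCurve:
    """P(c_pos >= x) over the category's correctly classified points,
    evaluated on a uniform grid of x in [0, 1]."""
    sub = loo.table[(loo.table["category"] == category) & loo.table["predictive"]]
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    if len(sub) == 0:
        return ExceedanceCurve(thresholds, np.zeros(n_thresholds), category, empty=True)
    c = sub["c_pos"].to_numpy()
    prob = (c[None, :] >= thresholds[:, None]).mean(axis=1)
    return ExceedanceCurve(thresholds, prob, category)
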