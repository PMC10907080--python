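"""Clinical validation statistics.

Three independent checks that stimulation-derived networks carry clinical
signal: (1) *specificity* — stimulation sites that did NOT disrupt behaviour
(from depth-electrode SEEG mapping) should sit in peripheral, low-frequency
territory of the positive network; (2) *resection importance* — how much
high-frequency network territory a surgical cavity removed, summarized as the
90th percentile of the network's frequency inside the cavity's share of each
bipartite compartment, correlated with post-operative behavioural scores;
(3) *map similarity* corrected for spatial autocorrelation via
variogram-matched surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import MaskVolume, OutOfBoundsError, ScalarVolume, mm_to_voxel
from .networks import BipartiteNetwork, FrequencyMap
from .seeds import SeedSet
from .surrogates import SurrogateGenerator

__all__ = [
    "SpecificityResult",
    "ResectionImportance",
    "ImportanceCorrelation",
    "CorrectedSimilarity",
    "seeg_specificity",
    "resection_importance",
    "correlate_importance",
    "corrected_similarity",
    "group_map_similarity",
]

#: percentile of in-cavity network frequencies defining resection importance
IMPORTANCE_PERCENTILE = 90.0


@dataclass
class SpecificityResult:
    """Distribution of negative-response sites in the two networks."""

    table: pd.DataFrame  # per surviving point: freq_in_pos, freq_in_neg (fractions)
    median_pos: float
    median_neg: float
    statistic: float  # Wilcoxon signed-rank statistic (default test)
    p_value: float
    ranksum_statistic: float  # rank-sum variant, also reported
    ranksum_p: float
    n_input: int
    n_duplicates_removed: int
    n_outside_gm: int
    n_zero_differences: int


def seeg_specificity(
    points: SeedSet,
    pos: FrequencyMap,
    neg: FrequencyMap,
    gm_mask: MaskVolume,
) -> SpecificityResult:
    """Paired comparison of per-point frequencies in the positive vs negative
    network.

    Exact-coordinate duplicates are removed (first occurrence kept) and points
    whose voxel falls outside the grey-matter mask are dropped; both counts
    are reported.  The default test is the Wilcoxon signed-rank on the paired
    differences with zeros dropped (exact null for n <= 25 without ties,
    normal approximation otherwise); the rank-sum variant is also emitted.
    """
    pos.grid.check_same(neg.grid, "seeg_specificity")
    pos.grid.check_same(gm_mask.grid, "seeg_specificity")
    seen: set[tuple[float, float, float]] = set()
    rows = []
    n_dup = n_out = 0
    for p in points:
        if p.xyz_mm in seen:
            n_dup += 1
            continue
        seen.add(p.xyz_mm)
        try:
            idx = mm_to_voxel(p.xyz_mm, pos.grid)
        except OutOfBoundsError:
            n_out += 1
            continue
        if not gm_mask.values[idx]:
            n_out += 1
            continue
        rows.append(
            {
                "x": p.xyz_mm[0],
                "y": p.xyz_mm[1],
                "z": p.xyz_mm[2],
                "freq_in_pos": pos.freq[idx] / 100.0,
                "freq_in_neg": neg.freq[idx] / 100.0,
            }
        )
    if not rows:
        raise ValueError("all points were filtered out (duplicates / outside GM)")
    table = pd.DataFrame(rows)
    fpos = table["freq_in_pos"].to_numpy()
    fneg = table["freq_in_neg"].to_numpy()
    diffs = fpos - fneg
    nonzero = diffs[diffs != 0]
    n_zero = len(diffs) - len(nonzero)
    if len(nonzero) == 0:
        stat, p_val = 0.0, 1.0  # all paired differences zero: no signal
    else:
        ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
        method = "exact" if (len(nonzero) <= 25 and not ties) else "approx"
        res = stats.wilcoxon(nonzero, zero_method="wilcox", method=method)
        stat, p_val = float(res.statistic), float(res.pvalue)
    rs = stats.ranksums(fpos, fneg)
    return SpecificityResult(
        table=table,
        median_pos=float(np.median(fpos)),
        median_neg=float(np.median(fneg)),
        statistic=stat,
        p_value=p_val,
        ranksum_statistic=float(rs.statistic),
        ranksum_p=float(rs.pvalue),
        n_input=len(points),
        n_duplicates_removed=n_dup,
        n_outside_gm=n_out,
        n_zero_differences=n_zero,
    )


@dataclass
class ResectionImportance:
    """Network importance removed by one surgical cavity."""

    importance_pos: float
    importance_neg: float
    perfect_bipartite: bool
    score: float | None = None


def resection_importance(
    cavity: MaskVolume,
    bipartite: BipartiteNetwork,
    pos: FrequencyMap,
    neg: FrequencyMap,
) -> ResectionImportance:
    """90th percentile (linear interpolation) of each network's frequency over
    the cavity's intersection with that network's bipartite compartment.

    An empty intersection contributes importance 0; a cavity intersecting
    exactly one compartment is flagged ``perfect_bipartite``.
    """
    cavity.grid.check_same(bipartite.grid, "resection_importance")
    cavity.grid.check_same(pos.grid, "resection_importance")
    cavity.grid.check_same(neg.grid, "resection_importance")
    if cavity.n_true == 0:
        raise ValueError("empty cavity mask")
    in_pos = cavity.values & (bipartite.label == 1)
    in_neg = cavity.values & (bipartite.label == -1)
    imp_pos = (
        float(np.percentile(pos.freq[in_pos], IMPORTANCE_PERCENTILE))
        if in_pos.any()
        else 0.0
    )
    imp_neg = (
        float(np.percentile(neg.freq[in_neg], IMPORTANCE_PERCENTILE))
        if in_neg.any()
        else 0.0
    )
    perfect = in_pos.any() != in_neg.any()
    return ResectionImportance(imp_pos, imp_neg, perfect)


@dataclass
class ImportanceCorrelation:
    rho_pos: float
    p_pos: float
    rho_neg: float
    p_neg: float
    n_used: int
    n_excluded_perfect: int
    pos_defined: bool = True
    neg_defined: bool = True


def correlate_importance(
    table: pd.DataFrame, exclude_perfect: bool = False
) -> ImportanceCorrelation:
    """Spearman correlation of importance_pos / importance_neg against the
    behavioural score (tie-corrected p).

    ``table`` needs columns importance_pos, importance_neg, perfect_bipartite,
    score.  With ``exclude_perfect`` the perfect-bipartite patients are
    removed first.  A constant column yields an undefined (NaN) correlation,
    flagged in the result.
    """
    sub = table[~table["perfect_bipartite"]] if exclude_perfect else table
    n_excl = len(table) - len(sub)
    if len(sub) < 5:
        raise ValueError(f"need >= 5 patients after exclusion, have {len(sub)}")
    out = {}
    flags = {}
    for side in ("pos", "neg"):
        col = sub[f"importance_{side}"].to_numpy()
        if np.all(col == col[0]) or sub["score"].nunique() == 1:
            out[side] = (float("nan"), float("nan"))
            flags[side] = False
        else:
            rho, p = stats.spearmanr(col, sub["score"].to_numpy())
            out[side] = (float(rho), float(p))
            flags[side] = True
    return ImportanceCorrelation(
        rho_pos=out["pos"][0],
        p_pos=out["pos"][1],
        rho_neg=out["neg"][0],
        p_neg=out["neg"][1],
        n_used=len(sub),
        n_excluded_perfect=n_excl,
        pos_defined=flags["pos"],
        neg_defined=flags["neg"],
    )


@dataclass
class CorrectedSimilarity:
    """Pearson similarity with a surrogate-based (autocorrelation-aware) p."""

    r: float
    p_corrected: float
    n_surrogates: int


def corrected_similarity(
    map_a: ScalarVolume,
    map_b: ScalarVolume,
    gm_mask: MaskVolume,
    n_surrogates: int = 1000,
    rng_seed: int = 0,
    generator: SurrogateGenerator | None = None,
) -> CorrectedSimilarity:
    """Pearson r over GM voxels; p from variogram-matched surrogates of map_a.

    p = (1 + #{|r_surrogate| >= |r|}) / (n_surrogates + 1), so p is never 0
    and self-similarity attains the floor 1/(n_surrogates + 1).
    """
    map_a.grid.check_same(map_b.grid, "corrected_similarity")
    map_a.grid.check_same(gm_mask.grid, "corrected_similarity")
    if gm_mask.n_true < 100:
        raise ValueError("GM support must contain at least 100 voxels")
    a = map_a.values[gm_mask.values]
    b = map_b.values[gm_mask.values]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate (constant) map over the GM support")
    r = float(np.corrcoef(a, b)[0, 1])
    if generator is None:
        coords = map_a.grid.voxel_centers_mm()[gm_mask.values]
        generator = SurrogateGenerator(coords)
    rng = np.random.default_rng(rng_seed)
    surr = generator(a, n_surrogates, rng)
    bc = b - b.mean()
    bn = np.linalg.norm(bc)
    sc = surr - surr.mean(axis=1, keepdims=True)
    r_surr = (sc @ bc) / (np.linalg.norm(sc, axis=1) * bn)
    p = (1 + int(np.sum(np.abs(r_surr) >= abs(r)))) / (n_surrogates + 1)
    return CorrectedSimilarity(r=r, p_corrected=p, n_surrogates=n_surrogates)


def group_map_similarity(
    patient_maps: dict[str, ScalarVolume],
    reference_maps: dict[str, ScalarVolume],
    gm_mask: MaskVolume,
    n_surrogates: int = 1000,
    rng_seed: int = 0,
) -> tuple[dict[str, CorrectedSimilarity], float]:
    """Per-seed corrected similarity between two sets of group-average maps
    (matched by seed id), plus the average r across seeds."""
    if set(patient_maps) != set(reference_maps):
        raise ValueError(
            "patient and reference map sets must share the same seed ids"
        )
    coords = gm_mask.grid.voxel_centers_mm()[gm_mask.values]
    gen = SurrogateGenerator(coords)
    results: dict[str, CorrectedSimilarity] = {}
    for i, sid in enumerate(patient_maps):
        results[sid] = corrected_similarity(
            patient_maps[sid],
            reference_maps[sid],
            gm_mask,
            n_surrogates=n_surrogates,
            rng_seed=rng_seed + i,
            generator=gen,
        )
    mean_r = float(np.mean([res.r for res in results.values()]))
    return results, mean_r
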