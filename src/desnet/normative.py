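"""Single-subject normative modelling over network hubs.

Stimulation points falling in *hub territory* (the top decile of a category's
positive frequency map) anchor a per-subject feature vector: the spatial
correlation, over grey matter, between the subject's own seed map at each hub
and the reference cohort's mean seed map there.  A robust-Mahalanobis
one-class model fitted on the reference cohort (with leave-one-out scoring)
labels *strong outliers* — subjects beyond the median of the reference
population's outlier-side scores — and a bootstrap of Cohen's d compares a
clinical sample against the reference distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.covariance import MinCovDet

from .grid import MaskVolume, sphere_mask
from .networks import FrequencyMap, positive_percentile_cutoff
from .seedmap import SeedConnectivityMap, SubjectSeries, cohort_seed_zmaps
from .seeds import SeedSet

__all__ = [
    "HubSet",
    "ReferenceModel",
    "BootstrapComparison",
    "select_hubs",
    "subject_features",
    "fit_reference",
    "score_subject",
    "bootstrap_cohens_d",
    "cohens_d",
]


@dataclass
class HubSet:
    """Stimulation points inside hub territory of one category."""

    points: SeedSet
    cutoff: float  # frequency (percent) at the hub percentile
    category: str

    def __len__(self) -> int:
        return len(self.points)


def select_hubs(
    seed_set: SeedSet,
    pos_freq: FrequencyMap,
    hub_percentile: float = 90.0,
    gm_mask: MaskVolume | None = None,
) -> HubSet:
    """Retain points whose centre voxel frequency reaches the hub cutoff.

    The cutoff is the ``hub_percentile``-th percentile of the strictly
    positive in-GM frequencies (same convention as network thresholding).
    """
    cutoff = positive_percentile_cutoff(pos_freq, hub_percentile, gm_mask)
    from .grid import mm_to_voxel  # local import to avoid cycles in typing

    kept = [
        p
        for p in seed_set
        if pos_freq.freq[mm_to_voxel(p.xyz_mm, pos_freq.grid)] >= cutoff
    ]
    if not kept:
        warnings.warn(
            f"no points reach the hub cutoff {cutoff:.1f} for "
            f"category {pos_freq.category!r}",
            stacklevel=2,
        )
    return HubSet(
        points=SeedSet(kept, provenance=f"hubs >= P{hub_percentile:g}",
                       extra_categories=seed_set.extra_categories),
        cutoff=cutoff,
        category=pos_freq.category,
    )


def subject_features(
    subject: SubjectSeries,
    hubs: HubSet,
    group_maps: Sequence[SeedConnectivityMap],
    gm_mask: MaskVolume,
    radius_mm: float = 3.0,
) -> np.ndarray:
    """One feature per hub: Pearson r between the subject's seed map at that
    hub and the reference cohort's mean seed map, over GM voxels excluding
    the hub sphere itself.

    A degenerate (zero-variance) subject map yields feature 0.  Ordering
    follows the hub set and is stable across calls.
    """
    if len(group_maps) != len(hubs):
        raise ValueError("need one group-mean map per hub")
    # one standardization pass for all hubs (identical to per-hub seed maps)
    z = cohort_seed_zmaps([subject], hubs.points.points, radius_mm, gm_mask)[:, 0, :]
    feats = np.empty(len(hubs))
    for h, (point, gmap) in enumerate(zip(hubs.points, group_maps)):
        sphere = sphere_mask(point.xyz_mm, radius_mm, subject.grid)
        keep = ~sphere.values[gm_mask.values]
        x = z[h][keep]
        y = gmap.z_values[gm_mask.values][keep]
        if x.std() == 0 or y.std() == 0:
            feats[h] = 0.0
        else:
            feats[h] = np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0)
    return feats


def _fit_mcd(X: np.ndarray, random_state: int = 0) -> MinCovDet:
    """Robust location/scatter; ridge-regularize a singular scatter."""
    mcd = MinCovDet(random_state=random_state).fit(X)
    cov = mcd.covariance_
    if np.linalg.matrix_rank(cov) < cov.shape[0] or np.linalg.cond(cov) > 1e12:
        eps = 1e-6 * np.trace(cov) / cov.shape[0]
        warnings.warn(
            f"singular robust scatter; ridge-regularizing with eps={eps:.3g}",
            stacklevel=3,
        )
        mcd.covariance_ = cov + eps * np.eye(cov.shape[0])
        mcd.precision_ = np.linalg.inv(mcd.covariance_)
    return mcd


@dataclass
class ReferenceModel:
    """Robust one-class scorer with leave-one-out reference distribution.

    score = robust Mahalanobis distance − chi-square calibration radius at
    level ``alpha``; score > 0 is the outlier side.  ``strong_outlier_cutoff``
    is the median of the outlier-side LOO scores (max of all LOO scores when
    no reference subject lands on the outlier side, so nobody is labellable).
    """

    mcd: MinCovDet = field(repr=False)
    n_features: int
    alpha: float
    calibration_radius: float
    loo_scores: np.ndarray = field(repr=False)
    strong_outlier_cutoff: float
    cutoff_rule: str = "outlier_median"


def _score_points(mcd: MinCovDet, X: np.ndarray, radius: float) -> np.ndarray:
    d = np.sqrt(mcd.mahalanobis(np.atleast_2d(X)))
    return d - radius


def fit_reference(
    reference_features: np.ndarray,
    alpha: float = 0.05,
    random_state: int = 0,
    cutoff_rule: str = "outlier_median",
) -> ReferenceModel:
    """Fit the one-class model on the reference cohort with LOO scoring.

    ``cutoff_rule`` selects the strong-outlier threshold: ``outlier_median``
    (default) uses the median of the outlier-side (positive) LOO scores;
    ``negative_median`` is the mirror reading — the median of the
    negative-side scores.
    """
    X = np.asarray(reference_features, dtype=float)
    if X.ndim != 2:
        raise ValueError("reference_features must be (subjects, hubs)")
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 reference subjects")
    if p < 1:
        raise ValueError("need at least one hub feature")
    radius = float(np.sqrt(stats.chi2.ppf(1 - alpha, df=p)))
    mcd = _fit_mcd(X, random_state)
    loo = np.empty(n)
    for i in range(n):
        mcd_i = _fit_mcd(np.delete(X, i, axis=0), random_state)
        loo[i] = _score_points(mcd_i, X[i], radius)[0]
    if cutoff_rule == "outlier_median":
        outlier_side = loo[loo > 0]
        cutoff = float(np.median(outlier_side)) if outlier_side.size else float(loo.max())
    elif cutoff_rule == "negative_median":
        inlier_side = loo[loo < 0]
        cutoff = float(np.median(inlier_side)) if inlier_side.size else float(loo.max())
    else:
        raise ValueError("cutoff_rule must be 'outlier_median' or 'negative_median'")
    return ReferenceModel(
        mcd=mcd,
        n_features=p,
        alpha=alpha,
        calibration_radius=radius,
        loo_scores=loo,
        strong_outlier_cutoff=cutoff,
        cutoff_rule=cutoff_rule,
    )


def score_subject(model: ReferenceModel, features: np.ndarray) -> tuple[float, bool]:
    """(score, strong_outlier) for one subject; strong iff score exceeds the
    reference cutoff."""
    f = np.asarray(features, dtype=float).ravel()
    if f.shape != (model.n_features,):
        raise ValueError(
            f"feature dimension {f.shape} does not match model ({model.n_features},)"
        )
    score = float(_score_points(model.mcd, f, model.calibration_radius)[0])
    return score, score > model.strong_outlier_cutoff


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with pooled unbiased SD; NaN when the
    pooled variance is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


@dataclass
class BootstrapComparison:
    """Bootstrap distribution of Cohen's d, reference vs clinical."""

    d_values: np.ndarray  # defined iterations only
    n_iter: int
    sample_size: int
    n_excluded: int  # iterations with zero pooled variance

    def fraction_below(self, d0: float) -> float:
        """Fraction of defined iterations with |d| <= d0."""
        if self.d_values.size == 0:
            raise ValueError("no defined bootstrap iterations")
        return float(np.mean(np.abs(self.d_values) <= d0))

    def abs_percentile(self, q: float) -> float:
        return float(np.percentile(np.abs(self.d_values), q))


def bootstrap_cohens_d(
    reference_scores: np.ndarray,
    clinical_scores: np.ndarray,
    n_iter: int = 100_000,
    sample_size: int = 66,
    rng_seed: int = 0,
) -> BootstrapComparison:
    """Per iteration: draw ``sample_size`` reference subjects with replacement,
    compute the two-sample t effect size (Cohen's d, pooled SD) against the
    fixed clinical sample; direction is reference minus clinical.

    Iterations with zero pooled variance are excluded and counted.
    """
    ref = np.asarray(reference_scores, dtype=float)
    clin = np.asarray(clinical_scores, dtype=float)
    if len(clin) != sample_size:
        raise ValueError(
            f"clinical sample size {len(clin)} must equal sample_size {sample_size}"
        )
    if len(ref) < sample_size:
        raise ValueError("reference pool smaller than sample_size")
    rng = np.random.default_rng(rng_seed)
    m_clin = clin.mean()
    ss_clin = (sample_size - 1) * clin.var(ddof=1)
    d_all = np.empty(n_iter)
    block = 2000
    for start in range(0, n_iter, block):
        b = min(block, n_iter - start)
        draws = ref[rng.integers(0, len(ref), size=(b, sample_size))]
        m = draws.mean(axis=1)
        ss = draws.var(axis=1, ddof=1) * (sample_size - 1)
        pooled = (ss + ss_clin) / (2 * sample_size - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            d_all[start : start + b] = (m - m_clin) / np.sqrt(pooled)
    defined = np.isfinite(d_all)
    return BootstrapComparison(
        d_values=d_all[defined],
        n_iter=n_iter,
        sample_size=sample_size,
        n_excluded=int((~defined).sum()),
    )
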