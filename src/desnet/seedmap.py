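"""Seed-based connectivity maps and group-level sign-flip permutation testing.

Each stimulation point is treated as a transient lesion: its sphere's mean
time series is correlated with every voxel of a normative subject's 4-D scan,
Fisher-z transformed, and the per-subject z-maps enter a one-sample test whose
familywise error is controlled by the maximum-statistic sign-flip permutation
distribution, separately for the positive and negative tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import AnalysisConfig
from .grid import MaskVolume, ScalarVolume, VolumeGrid, sphere_mask
from .seeds import SeedPoint

__all__ = [
    "DegenerateSeedError",
    "SubjectSeries",
    "SeedConnectivityMap",
    "SignificanceResult",
    "subject_seed_map",
    "cohort_seed_zmaps",
    "group_onesample_permtest",
    "seed_network_pair",
]

#: Fisher-z clipping bound: |r| is clipped to 1 - Z_CLIP so atanh stays finite.
Z_CLIP = 1e-6


class DegenerateSeedError(ValueError):
    """The seed sphere's mean time series has zero variance."""


@dataclass
class SubjectSeries:
    """One subject's 4-D functional data on the common grid (x, y, z, t)."""

    grid: VolumeGrid
    data: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 4 or data.shape[:3] != self.grid.dims:
            raise ValueError(
                f"data shape {data.shape} incompatible with grid {self.grid.dims}"
            )
        self.data = data

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class SeedConnectivityMap:
    """Fisher-z map of one subject against one seed; zeros outside the mask."""

    grid: VolumeGrid
    z_values: np.ndarray
    seed: SeedPoint
    analysis_mask: MaskVolume | None = None


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean rows and return (centered, row L2 norms); float64 output."""
    Xc = X.astype(np.float64) - X.mean(axis=-1, keepdims=True, dtype=np.float64)
    norms = np.linalg.norm(Xc, axis=-1)
    return Xc, norms


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1 + Z_CLIP, 1 - Z_CLIP))


def subject_seed_map(
    series: SubjectSeries,
    seed: SeedPoint,
    radius_mm: float,
    analysis_mask: MaskVolume,
) -> SeedConnectivityMap:
    """Correlate the seed sphere's mean time series with every in-mask voxel.

    Voxels outside ``analysis_mask`` are set to 0 (excluded).  Raises
    :class:`DegenerateSeedError` for a zero-variance seed signal.
    """
    series.grid.check_same(analysis_mask.grid, "subject_seed_map")
    if series.n_timepoints < 10:
        raise ValueError("need at least 10 timepoints for seed correlation")
    sph = sphere_mask(seed.xyz_mm, radius_mm, series.grid)
    if not (sph.values & analysis_mask.values).any():
        raise ValueError("seed sphere does not overlap the analysis mask")
    seed_ts = series.data[sph.values].mean(axis=0, dtype=np.float64)
    sc = seed_ts - seed_ts.mean()
    snorm = np.linalg.norm(sc)
    if snorm == 0:
        raise DegenerateSeedError(
            f"seed at {seed.xyz_mm} has a constant mean time series"
        )
    X = series.data[analysis_mask.values]  # (V_mask, T)
    Xc, norms = _standardize_rows(X)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ sc) / (norms * snorm)
    r[~np.isfinite(r)] = 0.0  # zero-variance voxels carry no correlation
    z = np.zeros(series.grid.dims)
    z[analysis_mask.values] = _fisher_z(r)
    return SeedConnectivityMap(series.grid, z, seed, analysis_mask)


def cohort_seed_zmaps(
    cohort: Sequence[SubjectSeries],
    seeds: Sequence[SeedPoint],
    radius_mm: float,
    analysis_mask: MaskVolume,
) -> np.ndarray:
    """All (seed, subject) Fisher-z maps over the analysis mask.

    Returns an array of shape (n_seeds, n_subjects, n_mask_voxels); the voxel
    axis enumerates ``analysis_mask.indices()`` in C order.  One pass per
    subject standardizes the data once and correlates all seeds jointly.
    """
    grid = analysis_mask.grid
    spheres = [sphere_mask(s.xyz_mm, radius_mm, grid).values for s in seeds]
    for s, sph in zip(seeds, spheres):
        if not (sph & analysis_mask.values).any():
            raise ValueError(f"seed {s.xyz_mm} sphere outside the analysis mask")
    out = np.empty((len(seeds), len(cohort), analysis_mask.n_true))
    for j, subj in enumerate(cohort):
        subj.grid.check_same(grid, "cohort_seed_zmaps")
        S = np.stack(
            [subj.data[sph].mean(axis=0, dtype=np.float64) for sph in spheres]
        )
        Sc, snorms = _standardize_rows(S)
        if np.any(snorms == 0):
            bad = int(np.flatnonzero(snorms == 0)[0])
            raise DegenerateSeedError(
                f"seed {seeds[bad].xyz_mm} constant in subject {j}"
            )
        Xc, norms = _standardize_rows(subj.data[analysis_mask.values])
        with np.errstate(invalid="ignore", divide="ignore"):
            R = (Xc @ Sc.T) / (norms[:, None] * snorms[None, :])
        R[~np.isfinite(R)] = 0.0
        out[:, j, :] = _fisher_z(R).T
    return out


@dataclass
class SignificanceResult:
    """Voxelwise one-sample permutation test with max-stat FWE control."""

    t_map: ScalarVolume
    pos_mask: MaskVolume
    neg_mask: MaskVolume
    alpha: float
    n_perm: int
    p_mode: str  # 'exhaustive' or 'sampled'


def _sign_matrix(n_subjects: int, n_perm: int, rng_seed: int) -> tuple[np.ndarray, str]:
    """Sign-flip patterns: exhaustive when 2^n fits within n_perm, else sampled
    (identity pattern always first)."""
    if n_subjects <= 62 and 2**n_subjects <= n_perm:
        codes = np.arange(2**n_subjects, dtype=np.uint64)
        bits = (codes[:, None] >> np.arange(n_subjects, dtype=np.uint64)) & 1
        return 1.0 - 2.0 * bits.astype(np.float64), "exhaustive"
    rng = np.random.default_rng(rng_seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subjects))
    signs[0] = 1.0  # identity included: p >= 1/n_perm
    return signs, "sampled"


def _t_from_signs(S: np.ndarray, X: np.ndarray, sumsq: np.ndarray) -> np.ndarray:
    """One-sample t per voxel for each sign pattern (rows of S)."""
    n = X.shape[0]
    M = (S @ X) / n
    var = (sumsq[None, :] - n * M**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = M / np.sqrt(var / n)
    # zero variance: identical values -> t is +/-inf by sign of the mean, 0 if mean 0
    degenerate = var == 0
    if degenerate.any():
        with np.errstate(invalid="ignore"):
            t[degenerate] = np.sign(M[degenerate]) * np.inf
        t[degenerate & (M == 0)] = 0.0
    return t


def group_onesample_permtest(
    z_maps: Sequence[SeedConnectivityMap] | np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    rng_seed: int = 0,
    analysis_mask: MaskVolume | None = None,
    block: int = 128,
) -> SignificanceResult:
    """Sign-flip one-sample test with per-tail max-statistic FWE control.

    A voxel is significant in a tail when its permutation p-value — the
    fraction of sign patterns whose *maximum* statistic over voxels meets or
    exceeds the observed value — is at most ``alpha``.  With ``2^n <= n_perm``
    all sign patterns are enumerated exactly and the seed is ignored.
    """
    if isinstance(z_maps, np.ndarray):
        if analysis_mask is None:
            raise ValueError("analysis_mask required with array input")
        X = np.asarray(z_maps, dtype=np.float64)
        grid = analysis_mask.grid
    else:
        if len(z_maps) < 2:
            raise ValueError("need at least 2 subjects")
        grid = z_maps[0].grid
        if analysis_mask is None:
            analysis_mask = z_maps[0].analysis_mask
        if analysis_mask is None:
            raise ValueError("no analysis mask available")
        for m in z_maps:
            m.grid.check_same(grid, "group_onesample_permtest")
        X = np.stack([m.z_values[analysis_mask.values] for m in z_maps])
    n, V = X.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    sumsq = (X**2).sum(axis=0)
    signs, p_mode = _sign_matrix(n, n_perm, rng_seed)
    t_obs = _t_from_signs(np.ones((1, n)), X, sumsq)[0]
    max_pos = np.empty(len(signs))
    max_neg = np.empty(len(signs))
    for start in range(0, len(signs), block):
        t_blk = _t_from_signs(signs[start : start + block], X, sumsq)
        max_pos[start : start + block] = t_blk.max(axis=1)
        max_neg[start : start + block] = (-t_blk).max(axis=1)
    n_total = len(signs)
    p_pos = (max_pos[None, :] >= t_obs[:, None]).sum(axis=1) / n_total
    p_neg = (max_neg[None, :] >= -t_obs[:, None]).sum(axis=1) / n_total
    pos = p_pos <= alpha
    neg = p_neg <= alpha
    overlap = pos & neg  # cannot occur for a one-sample two-tailed split
    pos &= ~overlap
    neg &= ~overlap
    if not np.any(X):
        warnings.warn("all z-maps are zero; returning empty masks", stacklevel=2)
    t_vol = np.zeros(grid.dims)
    t_finite = np.where(np.isfinite(t_obs), t_obs, np.sign(t_obs) * 1e6)
    t_vol[analysis_mask.values] = t_finite
    pos_vol = np.zeros(grid.dims, dtype=bool)
    neg_vol = np.zeros(grid.dims, dtype=bool)
    pos_vol[analysis_mask.values] = pos
    neg_vol[analysis_mask.values] = neg
    return SignificanceResult(
        t_map=ScalarVolume(grid, t_vol),
        pos_mask=MaskVolume(grid, pos_vol),
        neg_mask=MaskVolume(grid, neg_vol),
        alpha=alpha,
        n_perm=n_total,
        p_mode=p_mode,
    )


def seed_network_pair(
    cohort: Sequence[SubjectSeries],
    seed: SeedPoint,
    config: AnalysisConfig,
    analysis_mask: MaskVolume,
) -> tuple[MaskVolume, MaskVolume]:
    """Per-seed binary positive/negative significance masks for one cohort."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    maps = [
        subject_seed_map(s, seed, config.seed_radius_mm, analysis_mask)
        for s in cohort
    ]
    res = group_onesample_permtest(
        maps, alpha=config.alpha, n_perm=config.n_perm, rng_seed=config.rng_seed
    )
    return res.pos_mask, res.neg_mask
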