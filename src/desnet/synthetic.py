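"""Synthetic cohorts, stimulation points, tractograms and patient outcomes.

The generator plants the exact structure the analysis assumes, so every stage
of the pipeline can be exercised and checked against a known truth without
any data download:

* a small pseudo-MNI grid with an ellipsoidal "grey matter" brain mask;
* K spatially compact latent networks (plateau-plus-taper spherical loadings)
  whose temporal signals are unit-variance Gaussian, with chosen pairs
  negatively coupled at a stated correlation rho_anti;
* subject 4-D series: voxel v at time t mixes the K signals through the
  loadings, scaled by signal_sd, plus iid Gaussian noise of sd noise_sd;
* stimulation points sampled inside a chosen network's high-loading territory;
* straight-polyline tractograms with an exact planted fraction of streamlines
  terminating in the positive-network territory;
* patient cavities (random spheres) with behavioural scores generated as a
  noisy linear function of the resection importance of the positive network.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .clinical import resection_importance
from .grid import MaskVolume, ScalarVolume, VolumeGrid, sphere_mask, voxel_to_mm
from .networks import BipartiteNetwork, FrequencyMap
from .seedmap import SubjectSeries
from .seeds import SeedPoint, SeedSet
from .tracts import Tractogram

__all__ = [
    "LatentNetworkModel",
    "CohortSpec",
    "TractogramSpec",
    "default_grid",
    "make_brain_mask",
    "make_latent_networks",
    "simulate_subject_series",
    "simulate_cohort",
    "sample_des_points",
    "simulate_tractogram",
    "simulate_patient_outcomes",
    "make_smooth_map",
]


def default_grid(dims=(24, 28, 24), voxel_mm: float = 4.0) -> VolumeGrid:
    """The default desk-scale pseudo-MNI grid (24x28x24 at 4 mm), centred."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(dims) - 1) / 2.0
    return VolumeGrid(tuple(dims), affine)


def make_brain_mask(grid: VolumeGrid, scale: float = 0.92) -> MaskVolume:
    """Ellipsoid inscribed in the grid, standing in for a grey-matter mask."""
    centers = grid.voxel_centers_mm()
    half_extent = (np.asarray(grid.dims) * grid.voxel_size) / 2.0 * scale
    mid = voxel_to_mm((np.asarray(grid.dims) - 1) / 2.0, grid)
    u = (centers - mid) / half_extent
    return MaskVolume(grid, (u**2).sum(axis=-1) <= 1.0)


@dataclass
class LatentNetworkModel:
    """K compact network loading maps plus their temporal coupling scheme."""

    grid: VolumeGrid
    weight_maps: list[ScalarVolume]
    anti_pairs: tuple[tuple[int, int], ...]
    rho_anti: float
    gm_mask: MaskVolume
    centers_mm: np.ndarray = field(repr=False)

    @property
    def n_networks(self) -> int:
        return len(self.weight_maps)

    def territory(self, k: int, loading_min: float = 0.5) -> MaskVolume:
        """Voxels of network k with loading > loading_min (the planted truth)."""
        return MaskVolume(self.grid, self.weight_maps[k].values > loading_min)


@dataclass
class CohortSpec:
    """Normative-cohort dimensions and noise level."""

    n_subjects: int = 40
    n_timepoints: int = 200
    noise_sd: float = 2.0
    signal_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if self.noise_sd < 0 or self.signal_sd <= 0:
            raise ValueError("noise_sd >= 0 and signal_sd > 0 required")


@dataclass
class TractogramSpec:
    """Planted connection proportions for one subcortical point."""

    n_streamlines: int = 100
    planted_fraction_pos: float = 0.7
    step_mm: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if not 0 <= self.planted_fraction_pos <= 1:
            raise ValueError("planted_fraction_pos must be in [0, 1]")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be > 0")


def _blob_profile(dist_mm: np.ndarray, radius_mm: float, plateau_frac: float) -> np.ndarray:
    """Loading profile: 1 on the plateau, cosine taper to 0 at the radius.

    The narrow taper keeps the loading > 0.5 territory and the statistically
    detectable territory nearly coincident, which is what makes planted-truth
    Dice scores meaningful.
    """
    w = np.zeros_like(dist_mm)
    r0 = plateau_frac * radius_mm
    w[dist_mm <= r0] = 1.0
    band = (dist_mm > r0) & (dist_mm <= radius_mm)
    w[band] = 0.5 * (1.0 + np.cos(np.pi * (dist_mm[band] - r0) / (radius_mm - r0)))
    return w


def make_latent_networks(
    grid: VolumeGrid,
    K: int = 4,
    anti_pairs: Sequence[tuple[int, int]] = ((0, 1),),
    rng_seed: int = 0,
    blob_radius_mm: float = 14.0,
    plateau_frac: float = 0.8,
    rho_anti: float = -0.6,
    gm_scale: float = 0.92,
    max_tries: int = 5000,
) -> LatentNetworkModel:
    """Place K disjoint compact network blobs inside the brain mask.

    Centres are rejection-sampled among in-mask voxel centres with pairwise
    separation > 2.2 * blob_radius_mm, so supports are disjoint (pairwise
    Dice = 0 at loading > 0.5).  Deterministic given ``rng_seed``.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if not -1 <= rho_anti < 0:
        raise ValueError("rho_anti must be in [-1, 0)")
    for a, b in anti_pairs:
        if not (0 <= a < K and 0 <= b < K and a != b):
            raise ValueError(f"invalid anti-pair ({a}, {b}) for K={K}")
    rng = np.random.default_rng(rng_seed)
    gm = make_brain_mask(grid, scale=gm_scale)
    centers_all = grid.voxel_centers_mm()
    # candidate centres: deep enough inside the mask that the blob fits
    mid = voxel_to_mm((np.asarray(grid.dims) - 1) / 2.0, grid)
    half_extent = (np.asarray(grid.dims) * grid.voxel_size) / 2.0 * gm_scale
    u = (centers_all - mid) / np.maximum(half_extent - blob_radius_mm, 1e-9)
    candidates = centers_all[((u**2).sum(axis=-1) <= 1.0) & gm.values]
    if len(candidates) == 0:
        raise ValueError("grid too small to place any network blob")
    min_sep = 2.2 * blob_radius_mm
    chosen: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = candidates[rng.integers(len(candidates))]
        if all(np.linalg.norm(cand - c) > min_sep for c in chosen):
            chosen.append(cand)
            if len(chosen) == K:
                break
    if len(chosen) < K:
        raise ValueError(
            f"could only place {len(chosen)} of {K} compact networks on this grid"
        )
    centers = np.array(chosen)
    weight_maps = []
    for k in range(K):
        dist = np.linalg.norm(centers_all - centers[k], axis=-1)
        w = _blob_profile(dist, blob_radius_mm, plateau_frac)
        w[~gm.values] = 0.0
        weight_maps.append(ScalarVolume(grid, w))
    return LatentNetworkModel(
        grid=grid,
        weight_maps=weight_maps,
        anti_pairs=tuple((int(a), int(b)) for a, b in anti_pairs),
        rho_anti=float(rho_anti),
        gm_mask=gm,
        centers_mm=centers,
    )


def _latent_signals(
    model: LatentNetworkModel, T: int, rng: np.random.Generator
) -> np.ndarray:
    """(K, T) unit-variance Gaussian signals; anti-paired second members are
    rho_anti * first + sqrt(1 - rho_anti^2) * independent noise."""
    s = rng.standard_normal((model.n_networks, T))
    rho = model.rho_anti
    for a, b in model.anti_pairs:
        s[b] = rho * s[a] + np.sqrt(1.0 - rho**2) * s[b]
    return s


def simulate_subject_series(
    model: LatentNetworkModel,
    spec: CohortSpec,
    subject_index: int,
    coupling: Sequence[float] | None = None,
    dtype=np.float64,
) -> SubjectSeries:
    """One subject's 4-D series: voxel v, time t =
    sum_k coupling_k * w_kv * signal_sd * s_k(t) + noise_sd * eps_vt.

    Deterministic given (spec.rng_seed, subject_index).  ``coupling`` scales
    each network's expression in this subject (default all ones); halving an
    entry emulates a subject whose coupling to that network is weakened.
    """
    rng = np.random.default_rng([spec.rng_seed, subject_index])
    T = spec.n_timepoints
    s = _latent_signals(model, T, rng)
    coup = np.ones(model.n_networks) if coupling is None else np.asarray(coupling, float)
    if coup.shape != (model.n_networks,):
        raise ValueError("coupling needs one scale per network")
    W = np.stack([wm.values for wm in model.weight_maps], axis=-1)  # (x,y,z,K)
    data = np.tensordot(W * coup, s, axes=([3], [0])) * spec.signal_sd
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)
    return SubjectSeries(model.grid, data.astype(dtype), subject_id=f"sub-{subject_index:04d}")


def simulate_cohort(
    model: LatentNetworkModel, spec: CohortSpec, dtype=np.float32
) -> list[SubjectSeries]:
    """The full normative cohort (float32 by default to keep memory modest)."""
    return [
        simulate_subject_series(model, spec, i, dtype=dtype)
        for i in range(spec.n_subjects)
    ]


def sample_des_points(
    model: LatentNetworkModel,
    network_k: int,
    n_points: int,
    loading_min: float = 0.5,
    rng_seed: int = 0,
    category: str | None = None,
    location: str = "cortical",
) -> SeedSet:
    """n distinct points uniformly sampled among voxel centres with loading
    >= loading_min in network k (inside the brain mask)."""
    rng = np.random.default_rng(rng_seed)
    w = model.weight_maps[network_k].values
    qualifying = np.argwhere((w >= loading_min) & model.gm_mask.values)
    if len(qualifying) < n_points:
        raise ValueError(
            f"only {len(qualifying)} voxels with loading >= {loading_min}, "
            f"cannot sample {n_points} points"
        )
    picks = qualifying[rng.choice(len(qualifying), size=n_points, replace=False)]
    cat = category or f"synthetic_net{network_k}"
    points = [
        SeedPoint(
            xyz_mm=tuple(voxel_to_mm(idx, model.grid)),
            category=cat,
            location=location,
            patient_id=f"sim-{i:03d}",
        )
        for i, idx in enumerate(picks)
    ]
    return SeedSet(points, provenance=f"sampled from network {network_k}")


def _straight_polyline(start: np.ndarray, end: np.ndarray, step_mm: float) -> np.ndarray:
    length = np.linalg.norm(end - start)
    n_seg = max(1, int(np.ceil(length / step_mm)))
    t = np.linspace(0.0, 1.0, n_seg + 1)
    return start[None, :] + t[:, None] * (end - start)[None, :]


def simulate_tractogram(
    spec: TractogramSpec,
    subcortical_point: SeedPoint,
    pos_mask: MaskVolume,
    neg_mask: MaskVolume,
    subject_id: str = "",
) -> Tractogram:
    """Straight streamlines from the subcortical point into the two network
    territories: exactly round(n * planted_fraction_pos) end in ``pos_mask``,
    the rest in ``neg_mask``.  Every streamline starts at the point itself.
    """
    pos_mask.grid.check_same(neg_mask.grid, "simulate_tractogram")
    if np.any(pos_mask.values & neg_mask.values):
        raise ValueError("pos_mask and neg_mask must be disjoint")
    if pos_mask.n_true == 0 or neg_mask.n_true == 0:
        raise ValueError("both network masks must be non-empty")
    rng = np.random.default_rng(spec.rng_seed)
    grid = pos_mask.grid
    start = np.asarray(subcortical_point.xyz_mm, dtype=float)
    n_pos = int(round(spec.n_streamlines * spec.planted_fraction_pos))
    targets = []
    for mask, count in ((pos_mask, n_pos), (neg_mask, spec.n_streamlines - n_pos)):
        vox = mask.indices()
        picks = vox[rng.integers(len(vox), size=count)]
        targets.extend(voxel_to_mm(idx, grid) for idx in picks)
    streamlines = [_straight_polyline(start, np.asarray(t), spec.step_mm) for t in targets]
    return Tractogram(streamlines, subject_id=subject_id)


def simulate_patient_outcomes(
    n_patients: int,
    bipartite: BipartiteNetwork,
    pos_freq: FrequencyMap,
    neg_freq: FrequencyMap,
    slope: float = 1.0,
    intercept: float = 100.0,
    noise_sd: float = 10.0,
    rng_seed: int = 0,
    cavity_radius_mm: tuple[float, float] = (8.0, 16.0),
) -> tuple[list[MaskVolume], pd.DataFrame]:
    """Random two-lobed surgical cavities plus behavioural scores.

    Each cavity is the union of two spheres, one placed with random jitter
    around a random positive-network voxel and one independently around a
    random negative-network voxel — emulating irregular resections that
    remove a variable, *independently varying* share of each bipartite
    compartment.  The score is
    ``intercept - slope * importance_pos + N(0, noise_sd)`` where
    importance_pos is the resection importance of the positive network.
    Deterministic given ``rng_seed``.
    """
    grid = bipartite.grid
    rng = np.random.default_rng(rng_seed)
    if not np.any(bipartite.label != 0):
        raise ValueError("bipartite network has no labelled voxels")
    cavities, rows = [], []
    jitter_sd = cavity_radius_mm[1] / 2.0
    for i in range(n_patients):
        lobes = np.zeros(grid.dims, dtype=bool)
        for side in (1, -1):
            vox = np.argwhere(bipartite.label == side)
            if len(vox) == 0:
                continue
            center = voxel_to_mm(vox[rng.integers(len(vox))], grid)
            center = center + rng.normal(0.0, jitter_sd, size=3)
            radius = rng.uniform(*cavity_radius_mm)
            try:
                lobes |= sphere_mask(center, radius, grid).values
            except Exception:  # jittered centre off-grid: lobe skipped
                continue
        if not lobes.any():  # degenerate draw: fall back to an on-grid lobe
            vox = np.argwhere(bipartite.label != 0)
            center = voxel_to_mm(vox[rng.integers(len(vox))], grid)
            lobes = sphere_mask(center, cavity_radius_mm[0], grid).values
        cavity = MaskVolume(grid, lobes)
        entry = resection_importance(cavity, bipartite, pos_freq, neg_freq)
        score = intercept - slope * entry.importance_pos + rng.normal(0.0, noise_sd)
        cavities.append(cavity)
        rows.append(
            {
                "patient_id": f"pat-{i:03d}",
                "importance_pos": entry.importance_pos,
                "importance_neg": entry.importance_neg,
                "perfect_bipartite": entry.perfect_bipartite,
                "score": score,
            }
        )
    return cavities, pd.DataFrame(rows)


def make_smooth_map(
    grid: VolumeGrid, rng_seed: int = 0, smooth_vox: float = 2.0
) -> ScalarVolume:
    """A spatially autocorrelated Gaussian random field (white noise smoothed
    with a Gaussian kernel); used to exercise surrogate-based map comparison."""
    rng = np.random.default_rng(rng_seed)
    vals = gaussian_filter(rng.standard_normal(grid.dims), smooth_vox)
    return ScalarVolume(grid, vals)
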