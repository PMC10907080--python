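"""Build stimulation-derived functional networks from a synthetic cohort.

Simulates a small normative cohort whose voxel time series mix latent network
signals, samples stimulation points inside one network's territory, seeds
each point, thresholds with the sign-flip max-statistic test, and aggregates
the per-seed masks into positive/negative frequency maps.
"""

import numpy as np

from desnet import AnalysisConfig, frequency_map, group_onesample_permtest
from desnet.networks import coverage_report, probabilistic_des_atlas, threshold_network
from desnet.seedmap import cohort_seed_zmaps
from desnet.synthetic import (
    CohortSpec,
    default_grid,
    make_latent_networks,
    sample_des_points,
    simulate_subject_series,
)

cfg = AnalysisConfig(n_perm=256, rng_seed=0)
model = make_latent_networks(default_grid((16, 18, 16)), K=2, rng_seed=0,
                             blob_radius_mm=10.0)
spec = CohortSpec(n_subjects=16, n_timepoints=160, rng_seed=0)
cohort = [simulate_subject_series(model, spec, i, dtype=np.float32)
          for i in range(spec.n_subjects)]
seeds = sample_des_points(model, 0, 6, rng_seed=1)

z = cohort_seed_zmaps(cohort, seeds.points, cfg.seed_radius_mm, model.gm_mask)
pos_masks, neg_masks = [], []
for s in range(len(seeds)):
    res = group_onesample_permtest(z[s], cfg.alpha, cfg.n_perm, cfg.rng_seed,
                                   analysis_mask=model.gm_mask)
    pos_masks.append(res.pos_mask)
    neg_masks.append(res.neg_mask)

pos = frequency_map(pos_masks, "positive", seeds[0].category)
neg = frequency_map(neg_masks, "negative", seeds[0].category)
atlas = probabilistic_des_atlas(seeds, cfg.atlas_radius_mm, model.grid)
cov = coverage_report(pos, atlas, model.gm_mask)
core = threshold_network(pos, "absolute", 50.0)

print(f"{len(seeds)} stimulation points, {spec.n_subjects} normative subjects")
print(f"positive network support: {np.sum(pos.freq > 0)} voxels "
      f"(frequency = % of seeds significant per voxel)")
print(f"network covers {cov.pct_gm_network:.1f}% of grey matter vs "
      f"{cov.pct_gm_atlas:.1f}% for the points-only atlas "
      f"({cov.fold_increase:.1f}-fold gain)")
print(f"at the 50% frequency threshold the core network keeps "
      f"{core.n_true} voxels - the territory shared by most seeds")
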