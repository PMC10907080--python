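"""Clinical scoring: resection importance vs outcome, and SEEG specificity.

Simulates patients whose post-operative score degrades with the resected
positive-network importance, recovers the negative Spearman correlation, and
shows that stimulation sites producing no behavioural response sit in
peripheral (low-frequency) positive-network territory.
"""

from desnet.clinical import correlate_importance, seeg_specificity
from desnet.networks import FrequencyMap, bipartite_assign
from desnet.synthetic import (
    default_grid,
    make_latent_networks,
    sample_des_points,
    simulate_patient_outcomes,
)

model = make_latent_networks(default_grid((16, 18, 16)), K=2, rng_seed=3,
                             blob_radius_mm=10.0)
pos = FrequencyMap(model.grid, 100.0 * model.weight_maps[0].values,
                   "positive", "synthetic_net0", 20)
neg = FrequencyMap(model.grid, 100.0 * model.weight_maps[1].values,
                   "negative", "synthetic_net0", 20)
bip = bipartite_assign(pos, neg)

cavities, patients = simulate_patient_outcomes(
    40, bip, pos, neg, slope=1.0, intercept=100.0, noise_sd=10.0, rng_seed=2
)
corr = correlate_importance(patients)
print(f"{corr.n_used} patients; score = 100 - importance_pos + noise")
print(f"Spearman rho (positive network importance vs score): "
      f"{corr.rho_pos:.2f} (p = {corr.p_pos:.2g})")
print(f"Spearman rho (negative network importance vs score): "
      f"{corr.rho_neg:.2f} (p = {corr.p_neg:.2g})")
print("only removing positive-network territory predicts the deficit\n")

seeg = sample_des_points(model, 1, 25, loading_min=0.5, rng_seed=4,
                         category="synthetic_seeg_negative")
res = seeg_specificity(seeg, pos, neg, model.gm_mask)
print(f"{len(res.table)} negative-response SEEG sites")
print(f"median frequency at those sites: {res.median_pos:.2f} in the positive "
      f"network vs {res.median_neg:.2f} in the negative network")
print(f"signed-rank p = {res.p_value:.2g} (rank-sum p = {res.ranksum_p:.2g})")
print("no-response sites avoid the positive network's core - the network is "
      "specific, not just sensitive")
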