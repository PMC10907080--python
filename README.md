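# desnet

Causal functional network mapping from direct electrical stimulation (DES)
points, using a normative functional connectome.

## The problem

Intraoperative DES during awake surgery is the gold standard for localizing
brain function causally: stimulating a site and observing a behavioural
disruption (anomia, speech arrest, motor response, ...) ties that site to that
function. But stimulation points are sparse — a point cloud, not a map.
`desnet` implements the lesion-network-mapping route from points to whole-brain
networks: each stimulation point is treated as a transient lesion and used as a
seed in a large healthy-subject resting-state cohort, so that the distributed
network *shared* by the points of one functional category emerges from their
joint connectivity.

The core object is the **frequency map**. For a category with seeds
$s_1,\dots,s_n$, each seed's Fisher-z map $z_i(v) = \mathrm{atanh}\,r_i(v)$ is
tested across the cohort with a one-sample sign-flip permutation test whose
familywise error is controlled by the maximum-statistic null, separately for
the positively and negatively correlated tail. The frequency map is then

$$F(v) = 100 \cdot \tfrac{1}{n} \#\{\, i : v \in \text{significant mask of } s_i \,\}$$

— the percentage of seeds whose network significantly includes voxel $v$ —
computed for the positive (correlated) and negative (anti-correlated) network.
Around this sit the validation and clinical layers:

- **bipartite labelling** of voxels into positive / negative / unassigned
  territory, and grey-matter coverage versus a points-only probabilistic atlas;
- **leave-one-out prediction**: a held-out point is classified as predictive
  when its mean in-sphere concordance with the positive network exceeds the
  negative one; exceedance curves summarize how strongly correct points load;
- **structure–function coupling**: percentage of tractogram streamlines from a
  subcortical point terminating in each network territory;
- **single-subject normative modelling**: robust-Mahalanobis one-class scoring
  of hub-connectivity features with leave-one-out reference scores, strong
  outlier labelling, and a bootstrap Cohen's-d comparison of clinical vs
  reference populations;
- **clinical statistics**: specificity of negative-response (SEEG) sites,
  resection importance (90th percentile of network frequency within the
  resected bipartite compartment) correlated with post-operative scores, and
  Pearson map similarity corrected for spatial autocorrelation with
  variogram-matched surrogates.

A first-class synthetic-data module generates cohorts with planted latent
networks (including anti-correlated pairs), stimulation points, tractograms
with exact planted connection fractions, and patient outcomes — so the whole
pipeline is testable against known truth with no data download.

## Worked example

```bash
python examples/02_leave_one_out.py
```

builds a 16-subject synthetic cohort with two anti-correlated latent networks,
seeds 12 stimulation points sampled inside network 1, constructs the
positive/negative frequency maps and runs leave-one-out validation. It prints
(abridged):

```
pooled accuracy: 100.0% (fraction of held-out points landing in their own network)
median concordance: positive 0.55, negative 0.00 - a wide separation means the
network, not chance, predicts unseen points
exceedance P(c >= 0.5) = 0.50 (probability an unseen point lies above that frequency)
```

Accuracy is the fraction of held-out points whose positive-network concordance
beats the negative one; the median separation (0.55 vs 0.00) shows that unseen
points fall squarely in high-frequency territory of their own network. The
other examples cover network construction and coverage (`01`), streamline
coupling (`03`, recovering a planted 70/30 split exactly), single-subject
outlier detection (`04`) and clinical scoring (`05`).

A thin CLI drives the same stages on dataset directories:

```bash
desnet simulate --out ds --seed 0
desnet build-networks --dataset ds --out net
desnet crossval --dataset ds --networks net --out cv
```

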