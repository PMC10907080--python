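"""End-to-end stage orchestration with manifests.

Each stage consumes a directory written by an upstream stage, writes its
outputs plus a ``manifest.json`` recording the configuration snapshot, seeds,
package version and SHA-256 digests of inputs and outputs.  Deterministic
stages re-run to identical digests.  Volumes are written as uncompressed
NIfTI so digests are stable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import corrected_similarity, correlate_importance, seeg_specificity
from .config import AnalysisConfig
from .crossval import exceedance_curve, loo_validate
from .grid import MaskVolume, ScalarVolume, VolumeGrid, read_volume, write_volume
from .networks import (
    FrequencyMap,
    BipartiteNetwork,
    bipartite_assign,
    coverage_report,
    frequency_map,
    probabilistic_des_atlas,
)
from .normative import (
    bootstrap_cohens_d,
    fit_reference,
    score_subject,
    select_hubs,
    subject_features,
)
from .seedmap import SeedConnectivityMap, cohort_seed_zmaps, group_onesample_permtest
from .seeds import SeedPoint, SeedSet, read_seed_table, write_seed_table
from .synthetic import (
    CohortSpec,
    TractogramSpec,
    default_grid,
    make_latent_networks,
    sample_des_points,
    simulate_patient_outcomes,
    simulate_subject_series,
    simulate_tractogram,
)
from .tracts import (
    cohort_connection_summary,
    connection_percentages,
    read_tractogram,
    select_streamlines,
    write_tractogram,
)

log = logging.getLogger("desnet")

__all__ = [
    "DependencyError",
    "simulate_dataset",
    "build_networks",
    "crossval_stage",
    "structfunc_stage",
    "normative_stage",
    "clinical_stage",
    "report_stage",
    "validate_dataset",
    "read_manifest",
]


class DependencyError(RuntimeError):
    """A required upstream stage output is missing."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(
    out_dir: Path,
    stage: str,
    config: AnalysisConfig,
    inputs: list[Path],
    params: dict | None = None,
) -> None:
    outputs = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "stage": stage,
        "version": __version__,
        "config": config.to_dict(),
        "params": params or {},
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {str(p.relative_to(out_dir)): _sha256(p) for p in outputs},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(stage_dir: Path | str) -> dict:
    path = Path(stage_dir) / "manifest.json"
    if not path.exists():
        raise DependencyError(f"no manifest in {stage_dir}")
    with open(path) as fh:
        return json.load(fh)


def _require_stage(stage_dir: Path | str, stage: str, command: str) -> dict:
    try:
        manifest = read_manifest(stage_dir)
    except DependencyError:
        raise DependencyError(
            f"missing upstream output in {stage_dir}: run `desnet {command}` first"
        ) from None
    if manifest.get("stage") != stage:
        raise DependencyError(
            f"{stage_dir} holds stage {manifest.get('stage')!r}, expected "
            f"{stage!r}: run `desnet {command}` first"
        )
    return manifest


def _prepare_out(out_dir: Path, force: bool) -> Path:
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"{out_dir} exists and is not empty; pass force=True/--force"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir


def _logkv(stage: str, **kv) -> None:
    for key, value in kv.items():
        log.info("stage=%s %s=%s", stage, key, value)


# ---------------------------------------------------------------- simulate

def simulate_dataset(
    out_dir,
    config: AnalysisConfig,
    n_subjects: int = 40,
    n_timepoints: int = 200,
    K: int = 4,
    n_points: int = 20,
    n_subcortical: int = 2,
    n_patients: int = 40,
    n_seeg: int = 30,
    force: bool = False,
) -> Path:
    """Write a complete synthetic dataset: cohort NIfTI volumes, seed tables,
    tractograms, patient cavities/scores, planted-truth masks, manifest."""
    out = _prepare_out(Path(out_dir), force)
    grid = default_grid()
    model = make_latent_networks(grid, K=K, rng_seed=config.rng_seed)
    spec = CohortSpec(
        n_subjects=n_subjects, n_timepoints=n_timepoints, rng_seed=config.rng_seed
    )
    write_volume(out / "gm_mask.nii", model.gm_mask.values.astype(np.uint8), grid)
    for k, wm in enumerate(model.weight_maps):
        write_volume(out / f"truth_network_{k}.nii", wm.values, grid)
    cohort_dir = out / "cohort"
    cohort_dir.mkdir()
    for i in range(n_subjects):
        subj = simulate_subject_series(model, spec, i, dtype=np.float32)
        write_volume(cohort_dir / f"sub-{i:04d}.nii", subj.data, grid)
    seeds = sample_des_points(
        model, network_k=0, n_points=n_points, rng_seed=config.rng_seed + 1
    )
    write_seed_table(out / "seeds.tsv", seeds)
    # subcortical points midway between the anti-paired blobs, with tractograms
    a, b = model.anti_pairs[0]
    mid = (model.centers_mm[a] + model.centers_mm[b]) / 2.0
    sub_points = SeedSet(
        [
            SeedPoint(tuple(mid), category=seeds[0].category,
                      location="subcortical", patient_id=f"sub-pt-{i}")
            for i in range(n_subcortical)
        ],
        provenance="synthetic subcortical points",
    )
    write_seed_table(out / "subcortical_seeds.tsv", sub_points)
    tract_dir = out / "tractograms"
    tract_dir.mkdir()
    pos_t = model.territory(a)
    neg_t = model.territory(b)
    for i, pt in enumerate(sub_points):
        tg = simulate_tractogram(
            TractogramSpec(rng_seed=config.rng_seed + 10 + i), pt, pos_t, neg_t
        )
        write_tractogram(tract_dir / f"point-{i}.trk", tg, grid)
    # SEEG negative responses: sampled in the anti-network territory
    seeg = sample_des_points(
        model, network_k=b, n_points=n_seeg, loading_min=0.5,
        rng_seed=config.rng_seed + 2, category="synthetic_seeg_negative",
    )
    write_seed_table(out / "seeg_negative.tsv", seeg)
    _write_manifest(
        out, "simulate", config, inputs=[],
        params={
            "n_subjects": n_subjects, "n_timepoints": n_timepoints, "K": K,
            "n_points": n_points, "n_subcortical": n_subcortical,
            "n_patients": n_patients, "n_seeg": n_seeg,
        },
    )
    _logkv("simulate", out=out, n_subjects=n_subjects, n_points=n_points)
    return out


def validate_dataset(dataset_dir) -> None:
    """Check a dataset directory has every file the pipeline consumes."""
    d = Path(dataset_dir)
    manifest = _require_stage(d, "simulate", "simulate")
    required = ["gm_mask.nii", "seeds.tsv", "subcortical_seeds.tsv", "seeg_negative.tsv"]
    missing = [f for f in required if not (d / f).exists()]
    n_sub = manifest["params"]["n_subjects"]
    cohort = sorted((d / "cohort").glob("sub-*.nii")) if (d / "cohort").exists() else []
    if len(cohort) != n_sub:
        missing.append(f"cohort ({len(cohort)}/{n_sub} subjects)")
    if not list((d / "tractograms").glob("*.trk")):
        missing.append("tractograms/*.trk")
    if missing:
        raise FileNotFoundError(f"dataset {d} incomplete: {missing}")


def _load_dataset(dataset_dir: Path):
    from .seedmap import SubjectSeries

    d = Path(dataset_dir)
    gm_vals, grid = read_volume(d / "gm_mask.nii")
    gm = MaskVolume(grid, gm_vals)
    cohort = []
    for p in sorted((d / "cohort").glob("sub-*.nii")):
        vals, _ = read_volume(p, grid)
        cohort.append(SubjectSeries(grid, vals.astype(np.float32), subject_id=p.stem))
    seeds = read_seed_table(d / "seeds.tsv")
    return grid, gm, cohort, seeds


# ----------------------------------------------------------- build-networks

def build_networks(dataset_dir, out_dir, config: AnalysisConfig, force: bool = False) -> Path:
    """Per-seed significance masks, frequency maps, bipartite labels, atlas
    and grey-matter coverage for every category in the dataset's seed table."""
    d = Path(dataset_dir)
    _require_stage(d, "simulate", "simulate")
    out = _prepare_out(Path(out_dir), force)
    grid, gm, cohort, seeds = _load_dataset(d)
    rows = []
    for category in seeds.categories:
        cat_seeds = seeds.subset(category=category)
        z = cohort_seed_zmaps(cohort, cat_seeds.points, config.seed_radius_mm, gm)
        pos_masks, neg_masks = [], []
        for s in range(len(cat_seeds)):
            res = group_onesample_permtest(
                z[s], alpha=config.alpha, n_perm=config.n_perm,
                rng_seed=config.rng_seed, analysis_mask=gm,
            )
            pos_masks.append(res.pos_mask)
            neg_masks.append(res.neg_mask)
        stack_pos = np.stack([m.values for m in pos_masks], axis=-1)
        stack_neg = np.stack([m.values for m in neg_masks], axis=-1)
        write_volume(out / f"{category}_per_seed_pos.nii", stack_pos.astype(np.uint8), grid)
        write_volume(out / f"{category}_per_seed_neg.nii", stack_neg.astype(np.uint8), grid)
        pos = frequency_map(pos_masks, "positive", category)
        neg = frequency_map(neg_masks, "negative", category)
        write_volume(out / f"{category}_freq_pos.nii", pos.freq, grid)
        write_volume(out / f"{category}_freq_neg.nii", neg.freq, grid)
        bip = bipartite_assign(pos, neg)
        write_volume(out / f"{category}_bipartite.nii", bip.label.astype(np.int8), grid)
        atlas = probabilistic_des_atlas(cat_seeds, config.atlas_radius_mm, grid)
        write_volume(out / f"{category}_atlas.nii", atlas.values, grid)
        cov = coverage_report(pos, atlas, gm)
        rows.append(
            {
                "category": category, "polarity": "positive",
                "pct_gm_network": cov.pct_gm_network,
                "pct_gm_atlas": cov.pct_gm_atlas,
                "fold_increase": cov.fold_increase,
            }
        )
        _logkv("build-networks", category=category,
               fold_increase=cov.fold_increase, n_seeds=len(cat_seeds))
    pd.DataFrame(rows).to_csv(out / "coverage.tsv", sep="\t", index=False)
    _write_manifest(out, "build-networks", config,
                    inputs=[d / "seeds.tsv", d / "gm_mask.nii"])
    return out


def _load_networks(networks_dir: Path, category: str, grid: VolumeGrid):
    nd = Path(networks_dir)
    pos_vals, _ = read_volume(nd / f"{category}_freq_pos.nii", grid)
    neg_vals, _ = read_volume(nd / f"{category}_freq_neg.nii", grid)
    stack_pos, _ = read_volume(nd / f"{category}_per_seed_pos.nii", grid)
    stack_neg, _ = read_volume(nd / f"{category}_per_seed_neg.nii", grid)
    n = stack_pos.shape[-1]
    pos = FrequencyMap(grid, pos_vals, "positive", category, n)
    neg = FrequencyMap(grid, neg_vals, "negative", category, n)
    pos_masks = [MaskVolume(grid, stack_pos[..., i]) for i in range(n)]
    neg_masks = [MaskVolume(grid, stack_neg[..., i]) for i in range(n)]
    bip_vals, _ = read_volume(nd / f"{category}_bipartite.nii", grid)
    bip = BipartiteNetwork(grid, bip_vals.astype(np.int8), category)
    return pos, neg, pos_masks, neg_masks, bip


# ----------------------------------------------------------------- crossval

def crossval_stage(dataset_dir, networks_dir, out_dir, config: AnalysisConfig,
                   force: bool = False) -> Path:
    d, nd = Path(dataset_dir), Path(networks_dir)
    _require_stage(nd, "build-networks", "build-networks")
    out = _prepare_out(Path(out_dir), force)
    grid, gm, _, seeds = _load_dataset(d)
    all_pos: list[MaskVolume] = []
    all_neg: list[MaskVolume] = []
    for category in seeds.categories:
        _, _, pos_masks, neg_masks, _ = _load_networks(nd, category, grid)
        all_pos.extend(pos_masks)
        all_neg.extend(neg_masks)
    loo = loo_validate(seeds, all_pos, all_neg, config)
    loo.table.to_csv(out / "loo.tsv", sep="\t", index=False)
    for category in seeds.categories:
        curve = exceedance_curve(loo, category)
        pd.DataFrame({"threshold": curve.thresholds, "prob": curve.prob}).to_csv(
            out / f"exceedance_{category}.tsv", sep="\t", index=False
        )
    summary = {"accuracy": loo.accuracy, "median_c_pos": loo.median_c_pos,
               "median_c_neg": loo.median_c_neg}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _logkv("crossval", **summary)
    _write_manifest(out, "crossval", config, inputs=[d / "seeds.tsv"])
    return out


# --------------------------------------------------------------- structfunc

def structfunc_stage(dataset_dir, networks_dir, out_dir, config: AnalysisConfig,
                     force: bool = False) -> Path:
    d, nd = Path(dataset_dir), Path(networks_dir)
    _require_stage(nd, "build-networks", "build-networks")
    out = _prepare_out(Path(out_dir), force)
    gm_vals, grid = read_volume(d / "gm_mask.nii")
    sub_points = read_seed_table(d / "subcortical_seeds.tsv")
    category = sub_points[0].category
    _, _, _, _, bip = _load_networks(nd, category, grid)
    pos_mask = MaskVolume(grid, bip.label == 1)
    neg_mask = MaskVolume(grid, bip.label == -1)
    rows = []
    summaries = []
    for i, (pt, path) in enumerate(
        zip(sub_points, sorted((d / "tractograms").glob("*.trk")))
    ):
        tg = read_tractogram(path, subject_id=path.stem)
        sel = select_streamlines(tg, pt, max(config.seed_radius_mm, 1.0))
        summ = connection_percentages(sel, pos_mask, neg_mask)
        summaries.append(summ)
        rows.append(
            {"point": i, "n_selected": summ.n_selected,
             "pct_pos": summ.pct_pos, "pct_neg": summ.pct_neg}
        )
    cohort_summ = cohort_connection_summary(summaries)
    rows.append({"point": "cohort", "n_selected": cohort_summ.n_selected,
                 "pct_pos": cohort_summ.pct_pos, "pct_neg": cohort_summ.pct_neg})
    pd.DataFrame(rows).to_csv(out / "structfunc.tsv", sep="\t", index=False)
    _logkv("structfunc", pct_pos=cohort_summ.pct_pos, pct_neg=cohort_summ.pct_neg)
    _write_manifest(out, "structfunc", config, inputs=[d / "subcortical_seeds.tsv"])
    return out


# ---------------------------------------------------------------- normative

def normative_stage(dataset_dir, networks_dir, out_dir, config: AnalysisConfig,
                    n_clinical: int = 10, force: bool = False) -> Path:
    """Hub selection, reference fitting with LOO, clinical scoring and the
    bootstrap effect-size comparison, on the dataset's own cohort (reference)
    plus freshly simulated perturbed subjects (clinical stand-ins)."""
    d, nd = Path(dataset_dir), Path(networks_dir)
    sim_manifest = _require_stage(d, "simulate", "simulate")
    _require_stage(nd, "build-networks", "build-networks")
    out = _prepare_out(Path(out_dir), force)
    grid, gm, cohort, seeds = _load_dataset(d)
    category = seeds.categories[0]
    pos, _, _, _, _ = _load_networks(nd, category, grid)
    hubs = select_hubs(seeds.subset(category=category), pos,
                       config.hub_percentile, gm)
    if len(hubs) == 0:
        raise ValueError("no hub points; cannot run the single-subject stage")
    z = cohort_seed_zmaps(cohort, hubs.points.points, config.seed_radius_mm, gm)
    group_maps = []
    for h, pt in enumerate(hubs.points):
        mean_vol = np.zeros(grid.dims)
        mean_vol[gm.values] = z[h].mean(axis=0)
        group_maps.append(SeedConnectivityMap(grid, mean_vol, pt, gm))
    feats = np.empty((len(cohort), len(hubs)))
    for j, subj in enumerate(cohort):
        feats[j] = subject_features(subj, hubs, group_maps, gm,
                                    radius_mm=config.seed_radius_mm)
    model = fit_reference(feats, alpha=config.alpha, random_state=config.rng_seed)
    pd.DataFrame(feats, columns=[f"hub_{h}" for h in range(len(hubs))]).to_csv(
        out / "reference_features.tsv", sep="\t", index=False
    )
    pd.DataFrame({"loo_score": model.loo_scores}).to_csv(
        out / "reference_loo_scores.tsv", sep="\t", index=False
    )
    # clinical stand-ins: halved coupling to the hub network
    from .synthetic import make_latent_networks as _mk  # same model as simulate

    model_lat = _mk(grid, K=sim_manifest["params"]["K"], rng_seed=config.rng_seed)
    spec = CohortSpec(
        n_subjects=max(n_clinical, 2),
        n_timepoints=sim_manifest["params"]["n_timepoints"],
        rng_seed=config.rng_seed + 500,
    )
    coupling = np.ones(model_lat.n_networks)
    coupling[0] = 0.5
    clin_rows = []
    clin_scores = []
    for i in range(n_clinical):
        subj = simulate_subject_series(model_lat, spec, i, coupling=coupling,
                                       dtype=np.float32)
        f = subject_features(subj, hubs, group_maps, gm,
                             radius_mm=config.seed_radius_mm)
        score, strong = score_subject(model, f)
        clin_scores.append(score)
        clin_rows.append({"subject": i, "score": score, "strong_outlier": strong})
    pd.DataFrame(clin_rows).to_csv(out / "clinical_scores.tsv", sep="\t", index=False)
    sample_size = min(config.boot_sample_size, len(clin_scores))
    boot = bootstrap_cohens_d(
        model.loo_scores, np.asarray(clin_scores)[:sample_size],
        n_iter=min(config.n_boot, 20_000), sample_size=sample_size,
        rng_seed=config.rng_seed,
    ) if len(model.loo_scores) >= sample_size else None
    summary = {
        "n_hubs": len(hubs), "hub_cutoff": hubs.cutoff,
        "strong_outlier_cutoff": model.strong_outlier_cutoff,
        "n_strong_outliers_clinical": int(sum(r["strong_outlier"] for r in clin_rows)),
    }
    if boot is not None:
        summary["cohens_d_p80_abs"] = boot.abs_percentile(80)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _logkv("normative", **summary)
    _write_manifest(out, "normative", config, inputs=[d / "seeds.tsv"])
    return out


# ----------------------------------------------------------------- clinical

def clinical_stage(dataset_dir, networks_dir, out_dir, config: AnalysisConfig,
                   n_patients: int = 40, force: bool = False) -> Path:
    d, nd = Path(dataset_dir), Path(networks_dir)
    _require_stage(nd, "build-networks", "build-networks")
    out = _prepare_out(Path(out_dir), force)
    gm_vals, grid = read_volume(d / "gm_mask.nii")
    gm = MaskVolume(grid, gm_vals)
    seeds = read_seed_table(d / "seeds.tsv")
    category = seeds.categories[0]
    pos, neg, _, _, bip = _load_networks(nd, category, grid)
    seeg = read_seed_table(d / "seeg_negative.tsv")
    spec_res = seeg_specificity(seeg, pos, neg, gm)
    spec_res.table.to_csv(out / "seeg_points.tsv", sep="\t", index=False)
    _, patients = simulate_patient_outcomes(
        n_patients, bip, pos, neg, rng_seed=config.rng_seed + 900
    )
    patients.to_csv(out / "patients.tsv", sep="\t", index=False)
    corr = correlate_importance(patients)
    truth_vals, _ = read_volume(d / "truth_network_0.nii", grid)
    sim = corrected_similarity(
        ScalarVolume(grid, pos.freq), ScalarVolume(grid, truth_vals), gm,
        n_surrogates=min(config.n_surrogates, 200), rng_seed=config.rng_seed,
    )
    summary = {
        "seeg_median_pos": spec_res.median_pos,
        "seeg_median_neg": spec_res.median_neg,
        "seeg_signed_rank_p": spec_res.p_value,
        "seeg_ranksum_p": spec_res.ranksum_p,
        "spearman_rho_pos": corr.rho_pos, "spearman_p_pos": corr.p_pos,
        "spearman_rho_neg": corr.rho_neg, "spearman_p_neg": corr.p_neg,
        "similarity_r_vs_truth": sim.r, "similarity_p_corrected": sim.p_corrected,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _logkv("clinical", **summary)
    _write_manifest(out, "clinical", config,
                    inputs=[d / "seeg_negative.tsv", d / "seeds.tsv"])
    return out


# ------------------------------------------------------------------- report

def report_stage(out_dir, stage_dirs: list, force: bool = False) -> Path:
    """Collect every stage's summary.json / coverage.tsv into one report."""
    out = _prepare_out(Path(out_dir), force)
    report: dict = {}
    for sd in stage_dirs:
        sd = Path(sd)
        manifest = read_manifest(sd)
        entry: dict = {"dir": str(sd)}
        sj = sd / "summary.json"
        if sj.exists():
            with open(sj) as fh:
                entry["summary"] = json.load(fh)
        cov = sd / "coverage.tsv"
        if cov.exists():
            entry["coverage"] = pd.read_csv(cov, sep="\t").to_dict("records")
        report[manifest["stage"]] = entry
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return out
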