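"""Synthetic generators: planted structure, determinism, closed-form checks."""

import numpy as np
import pytest

from desnet.grid import MaskVolume
from desnet.synthetic import (
    CohortSpec,
    TractogramSpec,
    default_grid,
    make_brain_mask,
    make_latent_networks,
    sample_des_points,
    simulate_patient_outcomes,
    simulate_subject_series,
    simulate_tractogram,
    _latent_signals,
)


@pytest.fixture(scope="module")
def grid():
    return default_grid((16, 18, 16))


@pytest.fixture(scope="module")
def model(grid):
    return make_latent_networks(
        grid, K=2, anti_pairs=((0, 1),), rng_seed=3, blob_radius_mm=10.0
    )


class TestLatentNetworks:
    def test_deterministic_given_seed(self, grid):
        a = make_latent_networks(grid, K=2, rng_seed=5)
        b = make_latent_networks(grid, K=2, rng_seed=5)
        for wa, wb in zip(a.weight_maps, b.weight_maps):
            np.testing.assert_array_equal(wa.values, wb.values)

    def test_blobs_disjoint_at_half_loading(self):
        m = make_latent_networks(default_grid(), K=4, rng_seed=0)
        sets = [w.values > 0.5 for w in m.weight_maps]
        for i in range(4):
            for j in range(i + 1, 4):
                dice = 2 * np.sum(sets[i] & sets[j]) / (sets[i].sum() + sets[j].sum())
                assert dice < 0.2  # compact by construction: actually 0

    def test_anti_pair_signal_correlation_matches_rho(self, model):
        # long-series empirical correlation ~ rho_anti within +/- 0.05
        rng = np.random.default_rng(11)
        s = _latent_signals(model, 10_000, rng)
        r = np.corrcoef(s[0], s[1])[0, 1]
        assert abs(r - model.rho_anti) < 0.05

    def test_too_many_blobs_raises(self, grid):
        with pytest.raises(ValueError, match="place"):
            make_latent_networks(grid, K=30, rng_seed=0)


class TestSubjectSeries:
    def test_noiseless_unit_loading_voxel_equals_signal(self, model):
        spec = CohortSpec(n_subjects=2, n_timepoints=50, noise_sd=0.0, rng_seed=9)
        subj = simulate_subject_series(model, spec, 0)
        rng = np.random.default_rng([9, 0])
        s = _latent_signals(model, 50, rng)
        vox = np.argwhere(model.weight_maps[0].values == 1.0)[0]
        np.testing.assert_allclose(subj.data[tuple(vox)], s[0], atol=1e-12)

    def test_identical_loadings_identical_series_when_noiseless(self, model):
        spec = CohortSpec(n_subjects=2, n_timepoints=30, noise_sd=0.0, rng_seed=2)
        subj = simulate_subject_series(model, spec, 1)
        plateau = np.argwhere(model.weight_maps[0].values == 1.0)
        a, b = plateau[0], plateau[1]
        np.testing.assert_allclose(subj.data[tuple(a)], subj.data[tuple(b)], atol=1e-12)

    def test_deterministic_per_subject_index(self, model):
        spec = CohortSpec(n_subjects=2, n_timepoints=20, rng_seed=4)
        x = simulate_subject_series(model, spec, 0).data
        y = simulate_subject_series(model, spec, 0).data
        z = simulate_subject_series(model, spec, 1).data
        np.testing.assert_array_equal(x, y)
        assert not np.array_equal(x, z)

    def test_attenuated_anti_correlation_matches_closed_form(self, model):
        # analytic oracle: corr = rho * w_a * w_b * sig^2 /
        #   sqrt((w_a^2 sig^2 + noise^2)(w_b^2 sig^2 + noise^2))
        spec = CohortSpec(n_subjects=2, n_timepoints=2000, noise_sd=0.1, rng_seed=8)
        subj = simulate_subject_series(model, spec, 0)
        va = tuple(np.argwhere(model.weight_maps[0].values == 1.0)[0])
        vb = tuple(np.argwhere(model.weight_maps[1].values == 1.0)[0])
        expected = (
            model.rho_anti
            * spec.signal_sd**2
            / (spec.signal_sd**2 + spec.noise_sd**2)
        )
        r = np.corrcoef(subj.data[va], subj.data[vb])[0, 1]
        assert abs(r - expected) < 0.1


class TestDesPointSampling:
    def test_forced_single_voxel(self, model):
        # loading_min=1.0 restricts to the plateau; a single sample lies there
        seeds = sample_des_points(model, 0, 1, loading_min=1.0, rng_seed=0)
        w = model.weight_maps[0].values
        from desnet.grid import mm_to_voxel

        assert w[mm_to_voxel(seeds[0].xyz_mm, model.grid)] == 1.0

    def test_all_points_meet_loading_floor(self, model):
        from desnet.grid import mm_to_voxel

        seeds = sample_des_points(model, 0, 10, loading_min=0.6, rng_seed=1)
        w = model.weight_maps[0].values
        for p in seeds:
            assert w[mm_to_voxel(p.xyz_mm, model.grid)] >= 0.6

    def test_requesting_too_many_points_raises(self, model):
        with pytest.raises(ValueError, match="cannot sample"):
            sample_des_points(model, 0, 10_000, rng_seed=0)


class TestTractograms:
    def test_planted_counts_exact(self, model):
        pos = model.territory(0)
        neg = model.territory(1)
        point = _subcortical_point(model)
        tg = simulate_tractogram(
            TractogramSpec(n_streamlines=10, planted_fraction_pos=0.7, rng_seed=0),
            point,
            pos,
            neg,
        )
        assert len(tg) == 10
        n_pos = sum(_last_in(s, pos) for s in tg.streamlines)
        n_neg = sum(_last_in(s, neg) for s in tg.streamlines)
        assert (n_pos, n_neg) == (7, 3)

    def test_fraction_one_all_positive(self, model):
        point = _subcortical_point(model)
        tg = simulate_tractogram(
            TractogramSpec(n_streamlines=5, planted_fraction_pos=1.0, rng_seed=1),
            point,
            model.territory(0),
            model.territory(1),
        )
        assert all(_last_in(s, model.territory(0)) for s in tg.streamlines)

    def test_uniform_step_spacing(self, model):
        point = _subcortical_point(model)
        tg = simulate_tractogram(
            TractogramSpec(n_streamlines=3, step_mm=2.0, rng_seed=2),
            point,
            model.territory(0),
            model.territory(1),
        )
        for s in tg.streamlines:
            steps = np.linalg.norm(np.diff(s, axis=0), axis=1)
            assert steps.max() <= 2.0 + 1e-9
            np.testing.assert_allclose(steps, steps[0], atol=1e-9)

    def test_overlapping_masks_rejected(self, model):
        point = _subcortical_point(model)
        pos = model.territory(0)
        with pytest.raises(ValueError, match="disjoint"):
            simulate_tractogram(TractogramSpec(rng_seed=0), point, pos, pos)


@pytest.fixture(scope="module")
def networks(model):
    from desnet.networks import FrequencyMap, bipartite_assign

    pos = FrequencyMap(
        model.grid, 100.0 * model.weight_maps[0].values, "positive", "synthetic_net0", 10
    )
    neg = FrequencyMap(
        model.grid, 100.0 * model.weight_maps[1].values, "negative", "synthetic_net0", 10
    )
    return pos, neg, bipartite_assign(pos, neg)


class TestPatientOutcomes:
    def test_noiseless_score_is_linear_in_importance(self, networks):
        pos, neg, bip = networks
        _, table = simulate_patient_outcomes(
            8, bip, pos, neg, slope=1.0, intercept=10.0, noise_sd=0.0, rng_seed=3
        )
        np.testing.assert_allclose(
            table["score"], 10.0 - table["importance_pos"], atol=1e-9
        )

    def test_zero_slope_decouples_scores(self, networks):
        from scipy.stats import spearmanr

        pos, neg, bip = networks
        rhos = []
        for seed in (4, 5, 6):
            _, table = simulate_patient_outcomes(
                200, bip, pos, neg, slope=0.0, intercept=0.0, noise_sd=1.0,
                rng_seed=seed,
            )
            rhos.append(spearmanr(table["importance_pos"], table["score"]).statistic)
        # null sampling bound on the median of three independent replicates
        assert np.median(np.abs(rhos)) < 0.15

    def test_deterministic(self, networks):
        pos, neg, bip = networks
        _, t1 = simulate_patient_outcomes(5, bip, pos, neg, rng_seed=6)
        _, t2 = simulate_patient_outcomes(5, bip, pos, neg, rng_seed=6)
        assert t1.equals(t2)


def _subcortical_point(model):
    from desnet.seeds import SeedPoint

    mid = model.centers_mm.mean(axis=0)
    return SeedPoint(tuple(mid), "synthetic_net0", "subcortical", "sp")


def _last_in(streamline, mask: MaskVolume):
    from desnet.grid import mm_to_voxel

    return mask.values[mm_to_voxel(streamline[-1], mask.grid)]
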