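"""Frequency maps, bipartite labelling, atlas and coverage."""

import numpy as np
import pytest

from desnet.grid import MaskVolume, VolumeGrid, sphere_mask, voxel_to_mm
from desnet.networks import (
    FrequencyMap,
    bipartite_assign,
    coverage_report,
    frequency_map,
    probabilistic_des_atlas,
    threshold_network,
)
from desnet.seeds import SeedPoint, SeedSet


@pytest.fixture
def toy_grid():
    return VolumeGrid((5, 5, 5), np.eye(4))


def _random_masks(grid, n, rng, p=0.4):
    return [MaskVolume(grid, rng.random(grid.dims) < p) for _ in range(n)]


class TestFrequencyMap:
    def test_simple_count(self, toy_grid):
        masks = []
        for i in range(10):
            vals = np.zeros(toy_grid.dims)
            if i < 4:
                vals[2, 2, 2] = 1
            masks.append(MaskVolume(toy_grid, vals))
        fm = frequency_map(masks, "positive", "anomia")
        assert fm.freq[2, 2, 2] == 40.0
        assert fm.n_seeds == 10

    def test_identical_masks_give_zero_or_hundred(self, toy_grid, rng):
        m = MaskVolume(toy_grid, rng.random(toy_grid.dims) < 0.5)
        fm = frequency_map([m] * 7, "positive", "anomia")
        assert set(np.unique(fm.freq)) <= {0.0, 100.0}

    def test_matches_per_voxel_brute_force(self, toy_grid, rng):
        masks = _random_masks(toy_grid, 9, rng)
        fm = frequency_map(masks, "negative", "motor")
        for v in np.ndindex(*toy_grid.dims):
            count = sum(m.values[v] for m in masks)
            assert fm.freq[v] == pytest.approx(100.0 * count / 9)

    def test_permutation_invariance(self, toy_grid, rng):
        masks = _random_masks(toy_grid, 6, rng)
        a = frequency_map(masks, "positive", "anomia")
        b = frequency_map(masks[::-1], "positive", "anomia")
        np.testing.assert_array_equal(a.freq, b.freq)

    def test_empty_mask_dilutes_frequencies(self, toy_grid, rng):
        masks = _random_masks(toy_grid, 5, rng)
        a = frequency_map(masks, "positive", "anomia")
        b = frequency_map(masks + [MaskVolume(toy_grid, np.zeros(toy_grid.dims))],
                          "positive", "anomia")
        nz = a.freq > 0
        assert np.all(b.freq[nz] < a.freq[nz])

    def test_frequency_times_n_is_integral(self, toy_grid, rng):
        fm = frequency_map(_random_masks(toy_grid, 7, rng), "positive", "anomia")
        counts = fm.freq * fm.n_seeds / 100.0
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)


class TestBipartite:
    def _fm(self, grid, vals, polarity):
        return FrequencyMap(grid, vals, polarity, "anomia", 10)

    def test_rules_and_brute_force(self, toy_grid, rng):
        pos_v = rng.integers(0, 11, toy_grid.dims) * 10.0
        neg_v = rng.integers(0, 11, toy_grid.dims) * 10.0
        bip = bipartite_assign(self._fm(toy_grid, pos_v, "positive"),
                               self._fm(toy_grid, neg_v, "negative"))
        for v in np.ndindex(*toy_grid.dims):
            if pos_v[v] > neg_v[v] and pos_v[v] > 0:
                assert bip.label[v] == 1
            elif neg_v[v] > pos_v[v] and neg_v[v] > 0:
                assert bip.label[v] == -1
            else:
                assert bip.label[v] == 0

    def test_tie_is_unassigned(self, toy_grid):
        pos_v = np.full(toy_grid.dims, 30.0)
        bip = bipartite_assign(self._fm(toy_grid, pos_v, "positive"),
                               self._fm(toy_grid, pos_v.copy(), "negative"))
        assert np.all(bip.label == 0)

    def test_labels_partition_grid(self, toy_grid, rng):
        pos_v = rng.integers(0, 5, toy_grid.dims) * 25.0
        neg_v = rng.integers(0, 5, toy_grid.dims) * 25.0
        bip = bipartite_assign(self._fm(toy_grid, pos_v, "positive"),
                               self._fm(toy_grid, neg_v, "negative"))
        n = toy_grid.n_voxels
        sizes = [(bip.label == s).sum() for s in (-1, 0, 1)]
        assert sum(sizes) == n

    def test_wrong_polarity_rejected(self, toy_grid):
        a = self._fm(toy_grid, np.zeros(toy_grid.dims), "positive")
        with pytest.raises(ValueError, match="polarity|pair"):
            bipartite_assign(a, a)


class TestAtlasAndCoverage:
    def test_single_seed_support_is_sphere(self, toy_grid):
        seeds = SeedSet([SeedPoint((2.0, 2.0, 2.0), "anomia")])
        atlas = probabilistic_des_atlas(seeds, 1.5, toy_grid)
        sphere = sphere_mask((2.0, 2.0, 2.0), 1.5, toy_grid)
        np.testing.assert_array_equal(atlas.values > 0, sphere.values)
        assert np.all(atlas.values[sphere.values] == 100.0)

    def test_coincident_seeds_same_support(self, toy_grid):
        p = SeedPoint((2.0, 2.0, 2.0), "anomia")
        atlas = probabilistic_des_atlas(SeedSet([p, p]), 1.5, toy_grid)
        assert set(np.unique(atlas.values)) == {0.0, 100.0}

    def test_union_support_matches_brute_force(self, toy_grid):
        pts = [SeedPoint((1.0, 1.0, 1.0), "anomia"),
               SeedPoint((3.0, 3.0, 3.0), "anomia")]
        atlas = probabilistic_des_atlas(SeedSet(pts), 1.2, toy_grid)
        union = np.zeros(toy_grid.dims, dtype=bool)
        for p in pts:
            union |= sphere_mask(p.xyz_mm, 1.2, toy_grid).values
        np.testing.assert_array_equal(atlas.values > 0, union)

    def test_fold_increase(self, toy_grid):
        gm = MaskVolume(toy_grid, np.ones(toy_grid.dims))
        freq_v = np.zeros(toy_grid.dims)
        freq_v[:4] = 50.0  # 100 of 125 voxels
        atlas_v = np.zeros(toy_grid.dims)
        atlas_v[:2] = 10.0  # 50 of 125 voxels
        fm = FrequencyMap(toy_grid, freq_v, "positive", "anomia", 4)
        from desnet.grid import ScalarVolume

        rep = coverage_report(fm, ScalarVolume(toy_grid, atlas_v), gm)
        assert rep.fold_increase == pytest.approx(2.0)
        assert rep.pct_gm_network == pytest.approx(80.0)

    def test_identical_supports_fold_one(self, toy_grid):
        gm = MaskVolume(toy_grid, np.ones(toy_grid.dims))
        vals = np.zeros(toy_grid.dims)
        vals[2] = 60.0
        fm = FrequencyMap(toy_grid, vals, "positive", "anomia", 5)
        from desnet.grid import ScalarVolume

        rep = coverage_report(fm, ScalarVolume(toy_grid, vals), gm)
        assert rep.fold_increase == pytest.approx(1.0)

    def test_zero_atlas_flagged_not_infinite(self, toy_grid):
        gm = MaskVolume(toy_grid, np.ones(toy_grid.dims))
        vals = np.zeros(toy_grid.dims)
        vals[2] = 60.0
        fm = FrequencyMap(toy_grid, vals, "positive", "anomia", 5)
        from desnet.grid import ScalarVolume

        rep = coverage_report(fm, ScalarVolume(toy_grid, np.zeros(toy_grid.dims)), gm)
        assert rep.fold_increase is None


class TestThreshold:
    def test_absolute_any_positive_equals_support(self, toy_grid, rng):
        vals = rng.integers(0, 3, toy_grid.dims) * 50.0
        fm = FrequencyMap(toy_grid, vals, "positive", "anomia", 2)
        m = threshold_network(fm, "absolute", 0.0)
        np.testing.assert_array_equal(m.values, vals > 0)

    def test_absolute_hundred_keeps_unanimous_only(self, toy_grid, rng):
        vals = rng.integers(0, 3, toy_grid.dims) * 50.0
        fm = FrequencyMap(toy_grid, vals, "positive", "anomia", 2)
        m = threshold_network(fm, "absolute", 100.0)
        np.testing.assert_array_equal(m.values, vals == 100.0)

    def test_percentile_cutoff_order_statistic_oracle(self, toy_grid):
        # positive values 10..100; linear-interpolation P90 over them is 91
        vals = np.zeros(toy_grid.dims)
        flat = vals.reshape(-1)
        flat[:10] = np.arange(10, 101, 10)
        fm = FrequencyMap(toy_grid, vals, "positive", "anomia", 10)
        m = threshold_network(fm, "percentile", 90.0)
        assert np.percentile(np.arange(10, 101, 10), 90) == pytest.approx(91.0)
        assert m.n_true == 1  # only the voxel at 100 survives
        assert fm.freq[np.unravel_index(9, fm.grid.dims)] == 100.0

    def test_percentile_without_positive_values_raises(self, toy_grid):
        fm = FrequencyMap(toy_grid, np.zeros(toy_grid.dims), "positive", "anomia", 3)
        with pytest.raises(ValueError, match="positive"):
            threshold_network(fm, "percentile", 90.0)
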