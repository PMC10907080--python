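"""Clinical statistics: specificity, resection importance, corrected similarity."""

import itertools

import numpy as np
import pytest
from scipy import stats

from desnet.clinical import (
    corrected_similarity,
    correlate_importance,
    resection_importance,
    seeg_specificity,
)
from desnet.grid import MaskVolume, ScalarVolume, VolumeGrid, sphere_mask
from desnet.networks import BipartiteNetwork, FrequencyMap
from desnet.seeds import SeedPoint, SeedSet
from desnet.synthetic import make_brain_mask, make_smooth_map


@pytest.fixture
def toy_grid():
    return VolumeGrid((8, 8, 8), np.eye(4))


def _fm(grid, vals, polarity="positive"):
    return FrequencyMap(grid, vals, polarity, "motor", 10)


class TestSeegSpecificity:
    def test_constructed_medians_and_direction(self, toy_grid):
        gm = MaskVolume(toy_grid, np.ones(toy_grid.dims))
        pos = _fm(toy_grid, np.zeros(toy_grid.dims))
        neg_v = np.full(toy_grid.dims, 80.0)
        neg = _fm(toy_grid, neg_v, "negative")
        pts = SeedSet([SeedPoint((float(i % 8), 1.0, 2.0), "motor") for i in range(20)])
        res = seeg_specificity(pts, pos, neg, gm)
        assert res.median_pos == 0.0
        assert res.median_neg == 0.8
        assert res.p_value < 0.01

    def test_identical_maps_yield_p_one(self, toy_grid):
        gm = MaskVolume(toy_grid, np.ones(toy_grid.dims))
        vals = np.full(toy_grid.dims, 50.0)
        pts = SeedSet([SeedPoint((float(i), 1.0, 2.0), "motor") for i in range(8)])
        res = seeg_specificity(pts, _fm(toy_grid, vals), _fm(toy_grid, vals, "negative"), gm)
        assert res.p_value == 1.0
        assert res.n_zero_differences == 8

    def test_duplicates_and_outside_gm_filtered(self, toy_grid):
        gm_vals = np.ones(toy_grid.dims)
        gm_vals[0, :, :] = 0
        gm = MaskVolume(toy_grid, gm_vals)
        pts = SeedSet(
            [
                SeedPoint((2.0, 2.0, 2.0), "motor"),
                SeedPoint((2.0, 2.0, 2.0), "motor"),  # exact duplicate
                SeedPoint((0.0, 1.0, 1.0), "motor"),  # outside GM
                SeedPoint((3.0, 3.0, 3.0), "motor"),
            ]
        )
        rng = np.random.default_rng(0)
        pos = _fm(toy_grid, rng.integers(0, 11, toy_grid.dims) * 10.0)
        neg = _fm(toy_grid, rng.integers(0, 11, toy_grid.dims) * 10.0, "negative")
        res = seeg_specificity(pts, pos, neg, gm)
        assert res.n_duplicates_removed == 1
        assert res.n_outside_gm == 1
        assert len(res.table) == 2
        assert res.n_input == 4

    def test_wilcoxon_matches_exhaustive_enumeration(self, toy_grid):
        # 8 untied pairs: exact signed-rank null is all 2^8 sign assignments
        gm = MaskVolume(toy_grid, np.ones(toy_grid.dims))
        pos_v = np.zeros(toy_grid.dims)
        neg_v = np.zeros(toy_grid.dims)
        diffs = np.array([0.11, -0.23, 0.35, 0.47, -0.52, 0.66, 0.71, 0.84])
        for i, d in enumerate(diffs):
            if d > 0:
                pos_v[i, 0, 0] = 100 * d
            else:
                neg_v[i, 0, 0] = -100 * d
        pts = SeedSet([SeedPoint((float(i), 0.0, 0.0), "motor") for i in range(8)])
        res = seeg_specificity(pts, _fm(toy_grid, pos_v), _fm(toy_grid, neg_v, "negative"), gm)
        # independent oracle: enumerate all sign patterns of the rank sum
        ranks = stats.rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        w_min_obs = min(w_obs, ranks.sum() - w_obs)
        count = 0
        for signs in itertools.product([1, -1], repeat=8):
            w = ranks[np.array(signs) > 0].sum()
            if min(w, ranks.sum() - w) <= w_min_obs:
                count += 1
        p_exact = count / 2**8
        assert res.statistic == pytest.approx(w_min_obs)
        assert res.p_value == pytest.approx(p_exact)


class TestResectionImportance:
    def _setup(self, grid, rng):
        pos_v = rng.integers(0, 11, grid.dims) * 10.0
        neg_v = rng.integers(0, 11, grid.dims) * 10.0
        label = np.zeros(grid.dims, dtype=np.int8)
        label[:4] = 1
        label[5:] = -1
        return (
            _fm(grid, pos_v),
            _fm(grid, neg_v, "negative"),
            BipartiteNetwork(grid, label, "motor"),
        )

    def test_cavity_inside_positive_territory(self, toy_grid):
        pos_v = np.zeros(toy_grid.dims)
        pos_v[0, 0, :5] = [10, 20, 30, 40, 50]
        pos_v[0, 1, :5] = [60, 70, 80, 90, 100]
        label = np.zeros(toy_grid.dims, dtype=np.int8)
        label[0] = 1
        cavity_vals = np.zeros(toy_grid.dims)
        cavity_vals[0, :2, :5] = 1
        entry = resection_importance(
            MaskVolume(toy_grid, cavity_vals),
            BipartiteNetwork(toy_grid, label, "motor"),
            _fm(toy_grid, pos_v),
            _fm(toy_grid, np.zeros(toy_grid.dims), "negative"),
        )
        assert entry.importance_pos == pytest.approx(np.percentile(np.arange(10, 101, 10), 90))
        assert entry.importance_neg == 0.0
        assert entry.perfect_bipartite

    def test_cavity_in_unassigned_territory(self, toy_grid, rng):
        pos, neg, bip = self._setup(toy_grid, rng)
        cavity = np.zeros(toy_grid.dims)
        cavity[4, :, :] = 1  # the label-0 slab
        entry = resection_importance(MaskVolume(toy_grid, cavity), bip, pos, neg)
        assert entry.importance_pos == 0.0 and entry.importance_neg == 0.0
        assert not entry.perfect_bipartite

    def test_split_and_recombine_idempotent(self, toy_grid, rng):
        pos, neg, bip = self._setup(toy_grid, rng)
        cavity = sphere_mask((4.0, 4.0, 4.0), 3.0, toy_grid)
        whole = resection_importance(cavity, bip, pos, neg)
        pos_part = MaskVolume(toy_grid, cavity.values & (bip.label == 1))
        neg_part = MaskVolume(toy_grid, cavity.values & (bip.label == -1))
        a = resection_importance(pos_part, bip, pos, neg)
        b = resection_importance(neg_part, bip, pos, neg)
        assert whole.importance_pos == a.importance_pos
        assert whole.importance_neg == b.importance_neg

    def test_empty_cavity_rejected(self, toy_grid, rng):
        pos, neg, bip = self._setup(toy_grid, rng)
        with pytest.raises(ValueError, match="empty"):
            resection_importance(
                MaskVolume(toy_grid, np.zeros(toy_grid.dims)), bip, pos, neg
            )


class TestCorrelateImportance:
    def _table(self, imp_pos, imp_neg, scores, perfect=None):
        import pandas as pd

        return pd.DataFrame(
            {
                "importance_pos": imp_pos,
                "importance_neg": imp_neg,
                "perfect_bipartite": perfect if perfect is not None else [False] * len(scores),
                "score": scores,
            }
        )

    def test_strictly_monotone_gives_minus_one(self):
        imp = np.arange(8.0)
        table = self._table(imp, np.zeros(8) + np.arange(8) % 2, 100 - imp)
        res = correlate_importance(table)
        assert res.rho_pos == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        imp_pos = rng.uniform(0, 100, 6)
        imp_neg = rng.uniform(0, 100, 6)
        scores = rng.uniform(0, 30, 6)
        res = correlate_importance(self._table(imp_pos, imp_neg, scores))
        oracle = np.corrcoef(stats.rankdata(imp_pos), stats.rankdata(scores))[0, 1]
        assert res.rho_pos == pytest.approx(oracle)

    def test_exclude_perfect_patients(self, rng):
        imp = rng.uniform(0, 100, 10)
        perfect = [True] * 3 + [False] * 7
        res = correlate_importance(
            self._table(imp, imp, rng.uniform(0, 10, 10), perfect),
            exclude_perfect=True,
        )
        assert res.n_used == 7
        assert res.n_excluded_perfect == 3

    def test_constant_column_flagged(self):
        res = correlate_importance(
            self._table(np.zeros(6), np.arange(6.0), np.arange(6.0))
        )
        assert not res.pos_defined
        assert np.isnan(res.rho_pos)
        assert res.neg_defined


@pytest.fixture(scope="module")
def setup():
    grid = VolumeGrid((10, 10, 10), np.diag([4.0, 4.0, 4.0, 1.0]))
    gm = make_brain_mask(grid, scale=1.0)
    return grid, gm


class TestCorrectedSimilarity:
    def test_self_similarity_attains_p_floor(self, setup):
        grid, gm = setup
        m = make_smooth_map(grid, rng_seed=4)
        res = corrected_similarity(m, m, gm, n_surrogates=49, rng_seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_corrected == pytest.approx(1 / 50)

    def test_p_value_bounds(self, setup, rng):
        grid, gm = setup
        a = make_smooth_map(grid, rng_seed=5)
        b = ScalarVolume(grid, rng.standard_normal(grid.dims))
        res = corrected_similarity(a, b, gm, n_surrogates=49, rng_seed=1)
        assert 1 / 50 <= res.p_corrected <= 1.0

    def test_reproducible_given_seed(self, setup):
        grid, gm = setup
        a = make_smooth_map(grid, rng_seed=6)
        b = make_smooth_map(grid, rng_seed=7)
        r1 = corrected_similarity(a, b, gm, n_surrogates=29, rng_seed=9)
        r2 = corrected_similarity(a, b, gm, n_surrogates=29, rng_seed=9)
        assert r1.p_corrected == r2.p_corrected

    def test_constant_map_rejected(self, setup):
        grid, gm = setup
        a = ScalarVolume(grid, np.zeros(grid.dims))
        b = make_smooth_map(grid, rng_seed=8)
        with pytest.raises(ValueError, match="degenerate|constant"):
            corrected_similarity(a, b, gm, n_surrogates=10, rng_seed=0)
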