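"""Permutation inference: t-statistic hand values, TFCE closed forms and
monotonicity, exhaustive enumeration against a brute-force oracle, and
cluster extraction connectivity."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from rsnpipe.images import BrainMask
from rsnpipe.perminf import (
    PermConfig,
    glm_group_stat,
    tfce,
    permutation_maxstat,
    extract_clusters,
)
from conftest import full_mask


class TestGroupStat:
    def test_identical_means_give_zero(self, rng):
        base = rng.standard_normal(20)
        maps = np.tile(base, (6, 1))
        labels = ["control"] * 3 + ["patient"] * 3
        np.testing.assert_allclose(glm_group_stat(maps, labels), 0.0)

    def test_hand_worked_t_value(self):
        # {1,2,3} vs {4,5,6}: pooled var 1, t = -3 / sqrt(2/3) = -3.674
        maps = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        labels = ["control"] * 3 + ["patient"] * 3
        t = glm_group_stat(maps, labels)
        assert t[0] == pytest.approx(-3.674, abs=5e-4)

    def test_scale_invariance(self, rng):
        maps = rng.standard_normal((8, 12))
        labels = ["control"] * 4 + ["patient"] * 4
        t1 = glm_group_stat(maps, labels)
        t2 = glm_group_stat(maps * 7.3, labels)
        np.testing.assert_allclose(t1, t2, atol=1e-10)

    def test_zero_variance_voxel_statistic_zero(self):
        maps = np.ones((6, 3))
        labels = ["control"] * 3 + ["patient"] * 3
        np.testing.assert_array_equal(glm_group_stat(maps, labels), 0.0)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            glm_group_stat(rng.standard_normal((3, 4)),
                           ["control", "patient", "patient"])


class TestTfce:
    def test_single_voxel_hand_summation(self):
        s = np.zeros((3, 3, 3))
        s[1, 1, 1] = 1.0
        out = tfce(s, E=0.5, H=2.0, dh=0.1)
        # 0.1 * sum_{i=1..10} (0.1 i)^2 = 0.1 * 0.01 * 385 = 0.385
        assert out[1, 1, 1] == pytest.approx(0.385, abs=1e-12)

    def test_zero_exponents_reproduce_heights(self, rng):
        s = np.abs(rng.standard_normal((4, 4, 4)))
        dh = s.max() / 100.0
        out = tfce(s, E=0.0, H=0.0, dh=dh)
        assert np.abs(out - s).max() <= dh + 1e-12

    def test_monotone_in_voxel_height(self, rng):
        s = np.abs(rng.standard_normal((5, 5, 3)))
        base = tfce(s, dh=0.05)
        s2 = s.copy()
        s2[2, 2, 1] += 0.7
        raised = tfce(s2, dh=0.05)
        assert (raised - base >= -1e-12).all()

    def test_zero_below_first_threshold(self):
        s = np.zeros((3, 3, 1))
        s[0, 0, 0] = 0.05
        s[2, 2, 0] = 1.0
        out = tfce(s, dh=0.1)
        assert out[0, 0, 0] == 0.0

    def test_negative_values_enhanced_separately(self):
        s = np.zeros((3, 3, 3))
        s[0, 0, 0] = 1.0
        s[2, 2, 2] = -1.0
        out = tfce(s, E=0.5, H=2.0, dh=0.1)
        assert out[0, 0, 0] == pytest.approx(0.385, abs=1e-12)
        assert out[2, 2, 2] == pytest.approx(-0.385, abs=1e-12)


class TestPermutation:
    def _data(self, rng, n_per=4, v=18):
        maps = rng.standard_normal((2 * n_per, v))
        labels = np.array(["control"] * n_per + ["patient"] * n_per)
        return maps, labels

    def test_exhaustive_matches_bruteforce_oracle(self, rng):
        maps, labels = self._data(rng)
        mask = full_mask((18, 1, 1))
        cfg = PermConfig(n_perm=100, seed=0)  # 70 relabelings -> exhaustive
        res = permutation_maxstat(maps, labels, mask, cfg)
        assert res.exhaustive and res.n_perm_used == 70
        # independent oracle: enumerate all C(8,4) label splits with scipy
        null = []
        for idx in combinations(range(8), 4):
            sel = np.zeros(8, bool)
            sel[list(idx)] = True
            t, _ = stats.ttest_ind(maps[sel], maps[~sel], axis=0)
            null.append(np.abs(t).max())
        null = np.array(null)
        t_obs, _ = stats.ttest_ind(maps[:4], maps[4:], axis=0)
        expected = (null[None, :] >= np.abs(t_obs)[:, None] - 1e-12).mean(axis=1)
        np.testing.assert_allclose(res.p_corrected, expected, atol=1e-12)

    def test_massive_effect_reaches_minimum_p(self, rng):
        maps = rng.standard_normal((10, 12)) * 0.05
        maps[5:, 3] += 20.0  # enormous group effect at one voxel
        labels = np.array(["control"] * 5 + ["patient"] * 5)
        cfg = PermConfig(n_perm=99, seed=1, mode="montecarlo")
        res = permutation_maxstat(maps, labels, full_mask((12, 1, 1)), cfg)
        assert res.p_corrected.min() == pytest.approx(1.0 / 100.0)

    def test_montecarlo_close_to_exhaustive(self, rng):
        maps, labels = self._data(rng)
        mask = full_mask((18, 1, 1))
        exact = permutation_maxstat(maps, labels, mask,
                                    PermConfig(n_perm=100, seed=0))
        mc = permutation_maxstat(maps, labels, mask,
                                 PermConfig(n_perm=5000, seed=0,
                                            mode="montecarlo"))
        assert np.abs(exact.p_corrected - mc.p_corrected).max() < 0.02

    def test_deterministic_given_seed(self, rng):
        maps, labels = self._data(rng, n_per=5)
        mask = full_mask((18, 1, 1))
        cfg = PermConfig(n_perm=150, seed=9, mode="montecarlo")
        a = permutation_maxstat(maps, labels, mask, cfg)
        b = permutation_maxstat(maps, labels, mask, cfg)
        np.testing.assert_array_equal(a.p_corrected, b.p_corrected)

    def test_tfce_path_runs(self, rng):
        maps, labels = self._data(rng)
        cfg = PermConfig(n_perm=30, seed=2, use_tfce=True)
        res = permutation_maxstat(maps, labels, full_mask((3, 3, 2)), cfg)
        assert res.p_corrected.shape == (18,)
        assert (res.p_corrected > 0).all() and (res.p_corrected <= 1).all()


class TestClusters:
    def test_two_disjoint_blobs(self):
        mask = full_mask((7, 3, 1))
        p = np.ones(21)
        stat = np.zeros(21)
        blob = [0, 1, 15, 16]  # voxels (0,0,0),(0,1,0),(5,0,0),(5,1,0)
        for v in blob:
            p[v] = 0.01
            stat[v] = 3.0
        rep = extract_clusters(p, stat, mask, alpha=0.05)
        assert len(rep) == 2
        assert set(rep["voxel_count"]) == {2}

    def test_connectivity_distinguishes_diagonal(self):
        mask = full_mask((3, 3, 1))
        p = np.ones(9)
        stat = np.zeros(9)
        for v in (0, 4):  # (0,0,0) and (1,1,0): touch only diagonally
            p[v] = 0.01
            stat[v] = 2.0
        assert len(extract_clusters(p, stat, mask, connectivity=26)) == 1
        assert len(extract_clusters(p, stat, mask, connectivity=6)) == 2

    def test_l_shape_connected_at_any_connectivity(self):
        mask = full_mask((3, 3, 1))
        p = np.ones(9)
        stat = np.zeros(9)
        for v in (0, 3, 4):  # L: (0,0),(1,0),(1,1) — face-connected
            p[v] = 0.01
            stat[v] = 2.0
        assert len(extract_clusters(p, stat, mask, connectivity=6)) == 1
        assert len(extract_clusters(p, stat, mask, connectivity=26)) == 1

    def test_peak_statistics_reported(self):
        mask = full_mask((4, 1, 1))
        p = np.array([0.01, 0.01, 1.0, 1.0])
        stat = np.array([2.0, 5.0, 0.0, 0.0])
        rep = extract_clusters(p, stat, mask)
        assert rep.loc[0, "max_stat"] == 5.0
        assert (rep.loc[0, ["peak_x", "peak_y", "peak_z"]] == [1, 0, 0]).all()
        assert rep.loc[0, "mean"] == pytest.approx(3.5)

    def test_nothing_significant_empty_report(self):
        rep = extract_clusters(np.ones(8), np.zeros(8), full_mask((2, 2, 2)))
        assert len(rep) == 0
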