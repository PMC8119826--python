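"""Network matrices: closed-form partial correlations, a residual-regression
oracle, Fisher-z group averaging, and hierarchical cluster comparison."""

import numpy as np
import pytest

from rsnpipe.netmodel import (
    full_corr,
    partial_corr,
    subject_netmat,
    group_netmat,
    hclust_netmat,
    height_for_k,
    compare_group_clusters,
    NetMat,
)
from rsnpipe.simdata import modular_covariance, sample_mvn_timecourses


def timecourses_with_exact_corr(corr, t=60, seed=0):
    """Sample whose empirical correlation equals ``corr`` exactly: orthonormal
    columns recolored by the Cholesky factor."""
    rng = np.random.default_rng(seed)
    k = corr.shape[0]
    x = rng.standard_normal((t, k))
    x -= x.mean(axis=0)
    q, _ = np.linalg.qr(x)
    q -= q.mean(axis=0)
    q, _ = np.linalg.qr(q)  # re-orthonormalize after demeaning
    return q @ np.linalg.cholesky(corr).T


def residual_partial_oracle(tc):
    """Independent route: correlate the residuals of node i and j after
    regressing both on all remaining nodes."""
    t, k = tc.shape
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            others = [m for m in range(k) if m not in (i, j)]
            design = np.column_stack([np.ones(t), tc[:, others]])
            proj = design @ np.linalg.pinv(design)
            ri = tc[:, i] - proj @ tc[:, i]
            rj = tc[:, j] - proj @ tc[:, j]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


class TestFullCorr:
    def test_diagonal_zeroed_by_convention(self, rng):
        r, z = full_corr(rng.standard_normal((30, 3)))
        assert (np.diag(r) == 0).all() and (np.diag(z) == 0).all()

    def test_fisher_z_closed_form(self):
        corr = np.eye(2)
        corr[0, 1] = corr[1, 0] = 0.5
        tc = timecourses_with_exact_corr(corr)
        r, z = full_corr(tc)
        assert r[0, 1] == pytest.approx(0.5, abs=1e-10)
        assert z[0, 1] == pytest.approx(0.5493, abs=5e-5)  # atanh(0.5)

    def test_orthogonal_columns_uncorrelated(self):
        tc = timecourses_with_exact_corr(np.eye(3))
        r, _ = full_corr(tc)
        np.testing.assert_allclose(r, 0.0, atol=1e-10)

    def test_constant_column_rejected(self, rng):
        tc = rng.standard_normal((20, 2))
        tc[:, 1] = 4.0
        with pytest.raises(ValueError, match="constant"):
            full_corr(tc)


class TestPartialCorr:
    def test_three_node_closed_form(self):
        # r12 = r23 = 0.5, r13 = 0.25 -> partial r13 | 2 = 0
        corr = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 1.0]])
        tc = timecourses_with_exact_corr(corr)
        pr, _ = partial_corr(tc)
        assert pr[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_nodes_partial_equals_full(self, rng):
        tc = rng.standard_normal((40, 2))
        fr, _ = full_corr(tc)
        pr, _ = partial_corr(tc)
        assert pr[0, 1] == pytest.approx(fr[0, 1], abs=1e-10)

    def test_chain_conditional_independence(self):
        # x3 <- x2 <- x1: full r13 clearly positive, partial r13 ~ 0
        rng = np.random.default_rng(4)
        t = 20_000
        x1 = rng.standard_normal(t)
        x2 = 0.8 * x1 + 0.6 * rng.standard_normal(t)
        x3 = 0.8 * x2 + 0.6 * rng.standard_normal(t)
        tc = np.column_stack([x1, x2, x3])
        fr, _ = full_corr(tc)
        pr, _ = partial_corr(tc)
        assert fr[0, 2] > 0.3
        assert abs(pr[0, 2]) < 0.05

    def test_matches_residual_regression_oracle(self, rng):
        for _ in range(20):
            tc = rng.standard_normal((40, 5))
            pr, _ = partial_corr(tc)
            np.testing.assert_allclose(pr, residual_partial_oracle(tc),
                                       atol=1e-8)

    def test_singular_covariance_guidance(self, rng):
        tc = rng.standard_normal((30, 2))
        tc = np.column_stack([tc, tc[:, 0]])  # exact collinearity
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            partial_corr(tc, ridge=0.0)
        pr, _ = partial_corr(tc, ridge=0.1)  # regularized path works
        assert np.isfinite(pr).all()


class TestGroupNetmat:
    def test_identical_subjects_average_to_subject(self, rng):
        tc = rng.standard_normal((50, 4))
        nm = subject_netmat(tc)
        g = group_netmat([nm, nm], ["control", "control"])["control"]
        np.testing.assert_allclose(g.full_z, nm.full_z, atol=1e-12)

    def test_opposite_z_average_to_zero(self, rng):
        tc = rng.standard_normal((50, 3))
        nm = subject_netmat(tc)
        flipped = NetMat(full_r=-nm.full_r, partial_r=-nm.partial_r,
                         full_z=-nm.full_z, partial_z=-nm.partial_z)
        g = group_netmat([nm, flipped], ["c", "c"])["c"]
        np.testing.assert_allclose(g.full_z, 0.0, atol=1e-12)

    def test_z_averaging_differs_from_r_averaging(self, rng):
        # the Jensen gap: averaging on the z scale is the contract
        tc1 = rng.standard_normal((60, 2))
        tc2 = rng.standard_normal((60, 2))
        nms = [subject_netmat(t) for t in (tc1, tc2)]
        g = group_netmat(nms, ["c", "c"])["c"]
        r_avg = 0.5 * (nms[0].full_r[0, 1] + nms[1].full_r[0, 1])
        assert g.full_r[0, 1] != pytest.approx(r_avg, abs=1e-12)


class TestClustering:
    def _block_netmat(self, rng, sizes=(3, 3), within=0.8, between=0.05):
        cov, labels = modular_covariance(sizes, within, between)
        tc = sample_mvn_timecourses(cov, 2000, rng)
        return subject_netmat(tc), labels

    def test_recovers_two_clean_blocks(self, rng):
        from sklearn.metrics import adjusted_rand_score

        nm, labels = self._block_netmat(rng)
        tree = hclust_netmat(nm, cut={"k": 2})
        assert adjusted_rand_score(labels, tree.assignments) == 1.0

    def test_permutation_equivariance(self, rng):
        nm, _ = self._block_netmat(rng)
        perm = rng.permutation(nm.k)
        permuted = NetMat(
            full_r=nm.full_r[np.ix_(perm, perm)],
            partial_r=nm.partial_r[np.ix_(perm, perm)],
            full_z=nm.full_z[np.ix_(perm, perm)],
            partial_z=nm.partial_z[np.ix_(perm, perm)],
        )
        from sklearn.metrics import adjusted_rand_score

        t1 = hclust_netmat(nm, cut={"k": 2})
        t2 = hclust_netmat(permuted, cut={"k": 2})
        assert adjusted_rand_score(t1.assignments[perm], t2.assignments) == 1.0

    def test_three_node_average_linkage_hand_computed(self):
        # hand-picked netmat; profile distances computed by explicit loops
        m = np.array([[0.0, 0.8, 0.1],
                      [0.8, 0.0, 0.2],
                      [0.1, 0.2, 0.0]])
        nm = NetMat(full_r=m, partial_r=m, full_z=m, partial_z=m)
        d = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i != j:
                    d[i, j] = 1.0 - np.corrcoef(m[i], m[j])[0, 1]
        pairs = [(0, 1), (0, 2), (1, 2)]
        i0, j0 = min(pairs, key=lambda p: d[p])
        rest = ({0, 1, 2} - {i0, j0}).pop()
        h1 = d[i0, j0]
        h2 = 0.5 * (d[rest, i0] + d[rest, j0])  # average linkage
        tree = hclust_netmat(nm, cut={"k": 1})
        np.testing.assert_allclose(tree.linkage[:, 2], [h1, h2], atol=1e-12)

    def test_height_for_k_yields_k_clusters(self, rng):
        cov, _ = modular_covariance((3, 3, 3), 0.7, 0.05)
        nm = subject_netmat(sample_mvn_timecourses(cov, 1500, rng))
        tree = hclust_netmat(nm, cut={"k": 3})
        h = height_for_k(tree, 3)
        recut = hclust_netmat(nm, cut={"height": h})
        assert recut.n_clusters == 3

    def test_invalid_cut_rejected(self, rng):
        nm, _ = self._block_netmat(rng)
        with pytest.raises(ValueError, match="out of range"):
            hclust_netmat(nm, cut={"k": 99})


class TestCompare:
    def test_identical_trees_no_changes(self, rng):
        cov, _ = modular_covariance((3, 3), 0.7, 0.05)
        nm = subject_netmat(sample_mvn_timecourses(cov, 1500, rng))
        t1 = hclust_netmat(nm, cut={"k": 2})
        t2 = hclust_netmat(nm, cut={"k": 2})
        diff = compare_group_clusters(t1, t2)
        assert diff["changed_nodes"] == []
        assert diff["dissolved_ref_clusters"] == []
        assert diff["n_clusters_ref"] == diff["n_clusters_other"] == 2

    def test_equal_k_cut_counts_equal(self, rng):
        cov, _ = modular_covariance((3, 3, 3), 0.7, 0.05)
        a = subject_netmat(sample_mvn_timecourses(cov, 1500, rng))
        b = subject_netmat(sample_mvn_timecourses(cov, 1500, rng))
        ta = hclust_netmat(a, cut={"k": 3})
        tb = hclust_netmat(b, cut={"k": 3})
        diff = compare_group_clusters(ta, tb)
        assert diff["n_clusters_ref"] == diff["n_clusters_other"] == 3

    def test_node_set_mismatch_rejected(self, rng):
        cov2, _ = modular_covariance((2, 2), 0.7, 0.05)
        cov3, _ = modular_covariance((3, 3), 0.7, 0.05)
        ta = hclust_netmat(subject_netmat(
            sample_mvn_timecourses(cov2, 500, rng)), cut={"k": 2})
        tb = hclust_netmat(subject_netmat(
            sample_mvn_timecourses(cov3, 500, rng)), cut={"k": 2})
        with pytest.raises(ValueError, match="node set"):
            compare_group_clusters(ta, tb)
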