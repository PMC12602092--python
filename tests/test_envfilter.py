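"""PCA, PERMANOVA, DAPC and iterative environment-site removal."""

import itertools

import numpy as np
import pandas as pd
import pytest

from finclock import envfilter


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.05, (40, 10))
        x[20:, :10] += 1.0  # shift second cluster on all 10 sites
        scores, _, evr = envfilter.pca_scores(x)
        assert evr[0] > 0.8
        assert (scores[:20, 0] < 0).all() != (scores[20:, 0] < 0).all()

    def test_identical_rows_give_zero_scores(self):
        x = np.tile(np.arange(5.0), (8, 1))
        scores, _, _ = envfilter.pca_scores(x, scale_unit=False)
        assert np.allclose(scores, 0)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 6))
        scores, _, _ = envfilter.pca_scores(x)
        c = scores.T @ scores
        off = c - np.diag(np.diag(c))
        assert np.allclose(off, 0, atol=1e-8)

    def test_zero_variance_site_dropped_under_scaling(self):
        x = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        scores, loadings, _ = envfilter.pca_scores(x, scale_unit=True)
        assert loadings.shape[0] == 2
        assert np.allclose(loadings[1], 0)  # constant site carries no loading


class TestPermanova:
    def test_worked_example_exact(self):
        x = np.array([[0.0], [0.1], [1.0], [1.1]])
        res = envfilter.permanova(x, ["a", "a", "b", "b"])
        assert res.method == "exhaustive"
        assert res.pseudo_f == pytest.approx(200.0)
        assert res.p_value == pytest.approx(2 / 6)

    def test_accepts_precomputed_distance_matrix(self):
        x = np.array([[0.0], [0.1], [1.0], [1.1]])
        d = np.abs(x - x.T)
        res = envfilter.permanova(d, ["a", "a", "b", "b"])
        assert res.pseudo_f == pytest.approx(200.0)

    def test_identical_groups_give_f_near_zero_p_one(self):
        x = np.array([[0.0], [1.0], [0.0], [1.0]])
        res = envfilter.permanova(x, ["a", "a", "b", "b"])
        assert res.pseudo_f == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == 1.0

    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 2))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = envfilter.permanova(x, labels)
        assert res.method == "exhaustive"
        # independent oracle: enumerate every distinct permutation of labels
        fs = []
        for perm in set(itertools.permutations(labels)):
            r = envfilter.permanova(x, list(perm), permutations="exhaustive")
            fs.append(r.pseudo_f)
        expected_p = np.mean([f >= res.pseudo_f - 1e-12 for f in fs])
        assert res.p_value == pytest.approx(expected_p)

    def test_monte_carlo_p_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(4)
        x = rng.normal(size=(20, 4))
        x[10:] += 0.8
        labels = ["a"] * 10 + ["b"] * 10
        diff = x[:, None, :] - x[None, :, :]
        d = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        mine = envfilter.permanova(x, labels, n_perm=999, seed=1, permutations="monte_carlo")
        theirs = sk_permanova(
            skbio.DistanceMatrix(d, ids=[str(i) for i in range(20)]),
            grouping=labels, permutations=999,
        )
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)
        assert mine.p_value == pytest.approx(theirs["p-value"], abs=0.05)

    def test_pseudo_f_invariant_to_rotation_and_translation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 3))
        labels = ["a"] * 6 + ["b"] * 6
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        f1 = envfilter.permanova(x, labels, n_perm=99, seed=0).pseudo_f
        f2 = envfilter.permanova(x @ q + 5.0, labels, n_perm=99, seed=0).pseudo_f
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="2 members"):
            envfilter.permanova(np.zeros((3, 1)), ["a", "b", "b"])


class TestKmeans:
    def test_recovers_separated_blobs(self):
        rng = np.random.default_rng(6)
        x = np.vstack([rng.normal(0, 0.2, (15, 2)), rng.normal(5, 0.2, (15, 2))])
        labels = envfilter.kmeans_clusters(x, k=2, seed=0)
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert labels[0] != labels[-1]

    def test_k_one_single_label(self):
        assert set(envfilter.kmeans_clusters(np.random.default_rng(0).normal(size=(5, 2)), k=1)) == {1}

    def test_duplicated_points_co_assigned(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0], [9.0, 9.0]])
        labels = envfilter.kmeans_clusters(x, k=2, seed=1)
        assert labels[0] == labels[1] and labels[2] == labels[3]


def _planted_frame(n_fish=40, n_sites=30, n_signal=5, shift=1.0, seed=7):
    rng = np.random.default_rng(seed)
    x = rng.normal(0.5, 0.05, (n_fish, n_sites))
    labels = np.array(["a"] * (n_fish // 2) + ["b"] * (n_fish // 2))
    x[labels == "b", :n_signal] += shift
    cols = [f"s{j:03d}" for j in range(n_sites)]
    return pd.DataFrame(x, columns=cols), labels, cols[:n_signal]


class TestDapc:
    def test_planted_sites_hold_top_contributions(self):
        frame, labels, signal = _planted_frame()
        fit = envfilter.dapc_fit(frame, labels, n_pcs=10)
        top5 = fit.site_contributions.nlargest(5).index
        assert set(top5) == set(signal)
        assert fit.site_contributions.sum() == pytest.approx(1.0)
        assert fit.assignment_accuracy == 1.0

    def test_null_contributions_roughly_uniform(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(size=(40, 30)),
                         columns=[f"s{j}" for j in range(30)])
        labels = np.array(["a", "b"] * 20)
        fit = envfilter.dapc_fit(x, labels, n_pcs=5)
        c = fit.site_contributions
        # no site dominates: largest contribution within an order of magnitude
        # of the uniform share (the median of squared weights sits well below
        # the mean, so the mean is the stable reference)
        assert c.max() / c.mean() < 10

    def test_one_pc_matches_pc1_direction(self):
        frame, labels, _ = _planted_frame()
        fit = envfilter.dapc_fit(frame, labels, n_pcs=1)
        _, loadings, _ = envfilter.pca_scores(frame.to_numpy(), scale_unit=False)
        v = fit.site_contributions.to_numpy()
        pc1 = loadings[:, 0] ** 2 / (loadings[:, 0] ** 2).sum()
        assert np.allclose(v, pc1, atol=1e-8)

    def test_crossvalidation_easy_case_accurate_and_deterministic(self):
        frame, labels, _ = _planted_frame(shift=2.0)
        best1, table1 = envfilter.dapc_crossvalidate(frame, labels, max_pcs=10,
                                                     reps=5, seed=3)
        best2, table2 = envfilter.dapc_crossvalidate(frame, labels, max_pcs=10,
                                                     reps=5, seed=3)
        assert best1 == best2
        pd.testing.assert_frame_equal(table1, table2)
        assert table1["mean_accuracy"].max() > 0.95

    def test_random_labels_near_baseline_accuracy(self):
        rng = np.random.default_rng(9)
        x = pd.DataFrame(rng.normal(size=(40, 20)), columns=[f"s{j}" for j in range(20)])
        labels = rng.permutation(["a"] * 20 + ["b"] * 20)
        _, table = envfilter.dapc_crossvalidate(x, labels, max_pcs=5, reps=20, seed=4)
        assert table["mean_accuracy"].max() < 0.85  # chance is 0.5


class TestIterativeRemoval:
    def test_no_signal_means_zero_iterations(self):
        rng = np.random.default_rng(12)
        x = pd.DataFrame(rng.normal(0.5, 0.05, (30, 20)),
                         columns=[f"s{j}" for j in range(20)])
        groups = ["a"] * 15 + ["b"] * 15
        retained, removed, audit = envfilter.iterative_env_site_removal(
            x, groups, n_perm=199, seed=0
        )
        assert removed == []
        assert len(retained) == 20
        assert len(audit) == 1 and audit.loc[0, "p_value"] > 0.05

    def test_planted_signal_removed_and_audit_reconciles(self):
        frame, labels, signal = _planted_frame(n_fish=40, n_sites=40, n_signal=8,
                                               shift=0.6, seed=11)
        retained, removed, audit = envfilter.iterative_env_site_removal(
            frame, labels, n_perm=499, cv_reps=10, seed=1
        )
        assert set(retained) | set(removed) == set(frame.columns)
        assert set(retained) & set(removed) == set()
        assert audit.iloc[-1]["p_value"] > 0.05
        assert len(set(removed) & set(signal)) >= int(0.7 * len(signal))

    def test_removal_fraction_one_exhausts_sites_with_warning(self):
        frame, labels, _ = _planted_frame(shift=2.0)
        retained, removed, audit = envfilter.iterative_env_site_removal(
            frame, labels, removal_fraction=1.0, n_perm=199, seed=2
        )
        assert retained == []
        assert set(removed) == set(frame.columns)
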