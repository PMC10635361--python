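"""Fuzzy c-means properties: memberships, objective, recovery, limits."""

import collections

import numpy as np
import pandas as pd
import pytest

from splicedyn.clustering import (
    TEMPLATE_SHAPES,
    assign_and_prevalence,
    center_scale,
    fuzzy_cmeans,
    match_clusters_across_cohorts,
    select_cluster_input,
    template_trajectories,
)
from splicedyn.exon_usage import ExonUsageResult


def _result(cohort, comparison, sig_exons, all_exons):
    df = pd.DataFrame(index=pd.Index(all_exons, name="exon_id"))
    df["gene_id"] = "G1"
    df["tested"] = True
    df["qvalue"] = 0.5
    df.loc[list(sig_exons), "qvalue"] = 0.01
    df["significant"] = df["qvalue"] < 0.05
    return ExonUsageResult(cohort=cohort, comparison=comparison, table=df)


class TestSelectClusterInput:
    def test_union_over_comparisons(self):
        exons = [f"e{i}" for i in range(30)]
        r1 = _result("lean", ("confluence", "day3"), exons[:10], exons)
        r2 = _result("lean", ("day3", "day15"), exons[10:25], exons)
        other = _result("obese", ("day3", "day15"), exons[25:], exons)
        chosen = select_cluster_input([r1, r2, other], "lean")
        assert chosen == set(exons[:25])


class TestCenterScale:
    def test_hand_example(self):
        out = center_scale(pd.DataFrame([[2.0, 4.0, 6.0]]))
        assert np.allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_rows_dropped(self):
        out = center_scale(pd.DataFrame([[5.0, 5.0, 5.0], [0.0, 1.0, 2.0]]))
        assert len(out) == 1

    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        out = center_scale(pd.DataFrame(rng.normal(0, 1, (50, 3))))
        assert np.abs(out.mean(axis=1)).max() < 1e-10
        assert np.allclose(out.std(axis=1, ddof=1), 1.0)


class TestFuzzyCMeans:
    def test_k1_centroid_is_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (40, 3))
        model = fuzzy_cmeans(pd.DataFrame(X), k=1, seed=0)
        assert np.allclose(model.centroids[0], X.mean(axis=0), atol=1e-6)
        assert np.allclose(model.membership.to_numpy(), 1.0)

    def test_two_separated_clouds_recovered_exactly(self):
        rng = np.random.default_rng(2)
        X = np.vstack([
            rng.normal(0, 0.1, (50, 3)),
            rng.normal(10, 0.1, (50, 3)),
        ])
        model = fuzzy_cmeans(pd.DataFrame(X), k=2, seed=5)
        hard = assign_and_prevalence(model).assignments.to_numpy()
        assert len(set(hard[:50])) == 1 and len(set(hard[50:])) == 1
        assert hard[0] != hard[-1]

    def test_memberships_sum_to_one_and_trace_non_increasing(self):
        X, _ = template_trajectories(n_per_template=50, seed=3)
        model = fuzzy_cmeans(center_scale(X), k=6, seed=3)
        U = model.membership.to_numpy()
        assert np.abs(U.sum(axis=1) - 1).max() < 1e-8
        tr = model.objective_trace
        assert all(a >= b - 1e-9 for a, b in zip(tr, tr[1:]))

    def test_deterministic_for_fixed_seed(self):
        X, _ = template_trajectories(n_per_template=30, seed=4)
        Z = center_scale(X)
        m1 = fuzzy_cmeans(Z, k=6, seed=9)
        m2 = fuzzy_cmeans(Z, k=6, seed=9)
        assert np.array_equal(m1.centroids, m2.centroids)
        assert m1.membership.equals(m2.membership)

    def test_affine_rescaling_invariant_after_standardization(self):
        X, _ = template_trajectories(n_per_template=30, seed=5)
        Z1 = center_scale(X)
        Z2 = center_scale(X * 3.7 + 11.0)
        assert np.allclose(Z1.to_numpy(), Z2.to_numpy(), atol=1e-12)
        m1 = fuzzy_cmeans(Z1, k=4, seed=2)
        m2 = fuzzy_cmeans(Z2, k=4, seed=2)
        assert np.allclose(m1.centroids, m2.centroids, atol=1e-8)
        assert np.allclose(m1.membership.to_numpy(), m2.membership.to_numpy(),
                           atol=1e-8)

    def test_coincident_point_gets_full_membership(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [4.0, 4.0], [5.0, 5.0]])
        model = fuzzy_cmeans(pd.DataFrame(X), k=2, seed=0, max_iter=1)
        # after one update no point needs to coincide; force via centroids
        from splicedyn.clustering import _memberships

        d2 = np.array([[0.0, 4.0], [1.0, 1.0]])
        U = _memberships(d2, m=2.0)
        assert U[0, 0] == 1.0 and U[0, 1] == 0.0
        assert np.allclose(U[1], [0.5, 0.5])

    def test_k_larger_than_points_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_cmeans(pd.DataFrame(np.eye(3)), k=5, seed=0)

    def test_m_at_one_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_cmeans(pd.DataFrame(np.eye(3)), k=2, m=1.0, seed=0)


class TestAssignment:
    def test_argmax_and_tie_to_lowest_index(self):
        from splicedyn.clustering import ClusterModel

        U = pd.DataFrame([[0.7, 0.1, 0.2], [0.5, 0.5, 0.0]],
                         index=["e1", "e2"])
        model = ClusterModel(centroids=np.zeros((3, 3)), membership=U,
                             fuzzifier=2.0)
        a = assign_and_prevalence(model)
        assert a.assignments["e1"] == 0
        assert a.assignments["e2"] == 0  # exact tie -> lowest index
        assert a.prevalence.sum() == pytest.approx(100.0, abs=1e-6)


class TestClusterMatching:
    def test_identity_for_identical_sets(self):
        from splicedyn.clustering import ClusterModel

        C = TEMPLATE_SHAPES.copy()
        U = pd.DataFrame(np.ones((1, len(C))) / len(C))
        models = {
            "lean": ClusterModel(centroids=C, membership=U, fuzzifier=2.0),
            "obese": ClusterModel(centroids=C, membership=U, fuzzifier=2.0),
        }
        match = match_clusters_across_cohorts(models)
        obese = match[match["cohort"] == "obese"]
        assert (obese["cluster"] == obese["reference_cluster"]).all()

    def test_permutation_recovered_matches_brute_force(self):
        import itertools

        from splicedyn.clustering import ClusterModel

        rng = np.random.default_rng(6)
        C = rng.normal(0, 1, (6, 3))
        perm = rng.permutation(6)
        U = pd.DataFrame(np.ones((1, 6)) / 6)
        models = {
            "ref": ClusterModel(centroids=C, membership=U, fuzzifier=2.0),
            "other": ClusterModel(centroids=C[perm], membership=U, fuzzifier=2.0),
        }
        match = match_clusters_across_cohorts(models, max_distance=np.inf)
        got = dict(zip(match[match["cohort"] == "other"]["cluster"],
                       match[match["cohort"] == "other"]["reference_cluster"]))
        # brute force over all 6! assignments minimizing total distance
        best = min(
            itertools.permutations(range(6)),
            key=lambda p: sum(
                np.linalg.norm(C[perm][i] - C[p[i]]) for i in range(6)
            ),
        )
        assert got == {i: best[i] for i in range(6)}
        assert got == {i: int(perm[i]) for i in range(6)}

    def test_far_centroid_reported_unmatched(self):
        from splicedyn.clustering import ClusterModel

        U = pd.DataFrame(np.ones((1, 2)) / 2)
        ref = ClusterModel(centroids=np.array([[0.0, 0], [5.0, 5]]),
                           membership=U, fuzzifier=2.0)
        other = ClusterModel(centroids=np.array([[0.1, 0], [100.0, 100]]),
                             membership=U, fuzzifier=2.0)
        match = match_clusters_across_cohorts({"a": ref, "b": other},
                                              max_distance=1.0)
        b = match[match["cohort"] == "b"].set_index("cluster")
        assert b.loc[0, "reference_cluster"] == 0
        assert b.loc[1, "reference_cluster"] == -1


class TestRecovery:
    def test_template_recovery_accuracy(self):
        X, labels = template_trajectories(n_per_template=100, sigma=0.3, seed=0)
        traj = center_scale(X)
        model = fuzzy_cmeans(traj, k=6, seed=0)
        a = assign_and_prevalence(model)
        lab = labels[traj.index.to_numpy()]
        mapping = {}
        for j in range(6):
            members = lab[(a.assignments == j).to_numpy()]
            if len(members):
                mapping[j] = collections.Counter(members).most_common(1)[0][0]
        acc = np.mean([mapping.get(c) == l
                       for c, l in zip(a.assignments.to_numpy(), lab)])
        assert acc >= 0.90

    def test_m_near_one_matches_kmeans(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(c, 0.4, (17, 3))
                       for c in ([0, 0, 0], [4, 0, 0], [0, 4, 0])])[:50]
        model = fuzzy_cmeans(pd.DataFrame(X), k=3, m=1.05, seed=3)
        hard = assign_and_prevalence(model).assignments.to_numpy()
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        import itertools

        agree = max(
            (km.labels_ == np.vectorize(lambda h: p[h])(hard)).mean()
            for p in itertools.permutations(range(3))
        )
        assert agree == 1.0
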