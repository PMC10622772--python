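import numpy as np
import pandas as pd
import pytest

import metabophen as mp
from conftest import make_profile
from metabophen.cohort import QuantMatrix


def planted_block_profile(rng, n_blocks=3, biomarkers_per_block=8,
                          participants_per_block=30, p_in=0.9, p_out=0.02):
    """Binary profile with biomarker blocks that co-identify disjoint
    participant groups: within-block Jaccard low, between-block high."""
    n = n_blocks * participants_per_block
    b = n_blocks * biomarkers_per_block
    M = np.zeros((n, b), dtype=np.int8)
    for g in range(n_blocks):
        rows = slice(g * participants_per_block, (g + 1) * participants_per_block)
        cols = slice(g * biomarkers_per_block, (g + 1) * biomarkers_per_block)
        M[rows, cols] = (rng.random((participants_per_block, biomarkers_per_block)) < p_in)
        other = np.ones(b, dtype=bool)
        other[cols] = False
        M[rows][:, other] = 0
    M |= (rng.random(M.shape) < p_out).astype(np.int8)
    truth = np.repeat(np.arange(n_blocks), biomarkers_per_block)
    return make_profile(M), truth


def exact_partition_match(assignments, truth):
    lab = pd.Series(assignments).to_numpy()
    mapping = {}
    for a, t in zip(lab, truth):
        if a in mapping and mapping[a] != t:
            return False
        mapping[a] = t
    return len(set(mapping.values())) == len(set(truth))


class TestJaccard:
    def test_hand_example(self):
        # A positives {0,1}, B positives {1,2}: d = 1 - 1/3
        M = np.array([[1, 0], [1, 1], [0, 1]])
        D = mp.jaccard_distance_matrix(make_profile(M))
        assert D.iloc[0, 1] == pytest.approx(2 / 3)

    def test_identical_and_disjoint_columns(self):
        M = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        D = mp.jaccard_distance_matrix(make_profile(M))
        assert D.iloc[0, 1] == 0.0
        assert D.iloc[0, 2] == 1.0

    def test_zero_positive_biomarker_distance_one(self, caplog):
        M = np.array([[1, 0], [1, 0]])
        with caplog.at_level("WARNING", logger="metabophen.cluster"):
            D = mp.jaccard_distance_matrix(make_profile(M), restrict_to_identified=False)
        assert D.iloc[0, 1] == 1.0
        assert D.iloc[1, 1] == 0.0

    def test_metric_properties_on_random_profiles(self):
        rng = np.random.default_rng(0)
        M = (rng.random((40, 12)) < 0.3).astype(int)
        M[:, 0] = 1  # ensure at least one identified participant everywhere
        D = mp.jaccard_distance_matrix(make_profile(M)).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        n = D.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_restricts_to_identified_participants(self):
        M = np.array([[1, 0], [0, 1], [0, 0]])
        D_all = mp.jaccard_distance_matrix(make_profile(M), restrict_to_identified=False)
        D_id = mp.jaccard_distance_matrix(make_profile(M))
        # distances are set-based so restriction leaves them unchanged here
        pd.testing.assert_frame_equal(D_all, D_id)


class TestClusterBiomarkers:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(1)
        profile, truth = planted_block_profile(rng)
        D = mp.jaccard_distance_matrix(profile)
        model = mp.cluster_biomarkers(D, k_range=(2, 10))
        assert model.k == 3
        assert exact_partition_match(model.assignments, truth)

    def test_degenerate_identical_biomarkers(self, caplog):
        M = np.tile(np.array([[1], [1], [0]]), (1, 5))
        D = mp.jaccard_distance_matrix(make_profile(M))
        with caplog.at_level("WARNING", logger="metabophen.cluster"):
            model = mp.cluster_biomarkers(D, k_range=(2, 4))
        # identical objects cannot be split: the smallest-k cut collapses
        # to a single cluster and a warning is emitted
        assert model.k == 1
        assert model.assignments.nunique() == 1
        assert any("degenerate" in r.getMessage() for r in caplog.records)

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(2)
        profile, truth = planted_block_profile(rng)
        D = mp.jaccard_distance_matrix(profile)
        perm = rng.permutation(D.shape[0])
        Dp = D.iloc[perm, perm]
        a = mp.cluster_biomarkers(D, k_range=(2, 8))
        b = mp.cluster_biomarkers(Dp, k_range=(2, 8))
        assert a.k == b.k
        # same partition up to label permutation
        left = a.assignments.loc[Dp.index]
        assert exact_partition_match(b.assignments, left.to_numpy())

    def test_k_range_truncated_for_few_biomarkers(self, caplog):
        M = (np.random.default_rng(3).random((30, 4)) < 0.4).astype(int)
        D = mp.jaccard_distance_matrix(make_profile(M))
        with caplog.at_level("WARNING", logger="metabophen.cluster"):
            model = mp.cluster_biomarkers(D, k_range=(5, 50))
        assert 2 <= model.k <= 3

    def test_hierarchical_cuts_nest(self):
        rng = np.random.default_rng(4)
        profile, _ = planted_block_profile(rng)
        D = mp.jaccard_distance_matrix(profile)
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform
        Z = linkage(squareform(D.to_numpy(), checks=False), method="complete")
        for k in range(2, 8):
            a = fcluster(Z, t=k, criterion="maxclust")
            b = fcluster(Z, t=k + 1, criterion="maxclust")
            if np.unique(b).size != np.unique(a).size + 1:
                continue  # tie in merge heights; cut skipped a level
            # every cluster at k+1 is contained in exactly one cluster at k
            for cb in np.unique(b):
                parents = np.unique(a[b == cb])
                assert parents.size == 1


class TestSummariesAndFoldChanges:
    def test_single_biomarker_cluster_reduces_to_biomarker_metrics(self):
        M = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [0, 0], [0, 0]])
        labels = np.array(["ASD", "ASD", "ASD", "TYP", "ASD", "TYP"])
        profile = make_profile(M)
        model = mp.ClusterModel(assignments=pd.Series([1, 2], index=["B0", "B1"]),
                                k=2, linkage_tree=None, silhouette_by_k={})
        summ = mp.cluster_summaries(model, profile, labels)
        # cluster 1 = {B0}: identifies 2 of 4 ASD, all positives are ASD
        assert summ.loc[1, "pct_asd"] == pytest.approx(2 / 4)
        assert summ.loc[1, "pmp_asd"] == pytest.approx(1.0)
        # cluster 2 = {B1}: 1 ASD + 1 TYP positive
        assert summ.loc[2, "pmp_asd"] == pytest.approx(0.5)

    def test_nested_positives_union_is_largest_member(self):
        # B1 positives ⊂ B0 positives: cluster %ASD driven by B0
        M = np.array([[1, 1], [1, 0], [1, 0], [0, 0]])
        labels = np.array(["ASD", "ASD", "ASD", "TYP"])
        profile = make_profile(M)
        assignments = pd.Series([1, 1], index=["B0", "B1"])
        model = mp.ClusterModel(assignments=assignments, k=1, linkage_tree=None,
                                silhouette_by_k={})
        summ = mp.cluster_summaries(model, profile, labels)
        assert summ.loc[1, "pct_asd"] == pytest.approx(1.0)

    def test_fold_change_null_near_one_and_planted_near_two(self):
        rng = np.random.default_rng(5)
        n = 400
        carriers = rng.random(n) < 0.12
        conc = pd.DataFrame({
            "m_shift": np.exp2(rng.normal(3, 0.3, n) + carriers * 1.0),
            "m_null": np.exp2(rng.normal(1, 0.3, n)),
        }, index=[f"P{i}" for i in range(n)])
        labels = np.array(["ASD"] * n)
        profile = make_profile(carriers[:, None].astype(int), participants=conc.index)
        model = mp.ClusterModel(assignments=pd.Series([1], index=["B0"]), k=1,
                                linkage_tree=None, silhouette_by_k={})
        fct = mp.fold_changes(model, QuantMatrix(conc), labels, profile)
        assert fct.loc[1, "m_shift"] == pytest.approx(2.0, rel=0.2)
        assert fct.loc[1, "m_null"] == pytest.approx(1.0, rel=0.15)

    def test_fold_change_missing_positive_group(self):
        conc = pd.DataFrame({"m": [np.nan, 2.0, 3.0]}, index=["A", "B", "C"])
        labels = np.array(["ASD"] * 3)
        profile = make_profile(np.array([[1], [0], [0]]), participants=conc.index)
        model = mp.ClusterModel(assignments=pd.Series([1], index=["B0"]), k=1,
                                linkage_tree=None, silhouette_by_k={})
        fct = mp.fold_changes(model, QuantMatrix(conc), labels, profile)
        assert np.isnan(fct.loc[1, "m"])


class TestGroupClusters:
    def test_identical_vectors_share_group(self):
        fct = pd.DataFrame({"a": [2.0, 2.0, 0.5], "b": [1.5, 1.5, 0.7],
                            "c": [0.8, 0.8, 1.4]}, index=[1, 2, 3]).T
        fct = pd.DataFrame({
            1: {"m1": 2.0, "m2": 1.5, "m3": 0.8},
            2: {"m1": 2.0, "m2": 1.5, "m3": 0.8},
            3: {"m1": 0.5, "m2": 0.7, "m3": 1.4},
        }).T
        groups = mp.group_clusters(fct, n_groups=2)
        assert groups[1] == groups[2]
        assert groups[1] != groups[3]

    def test_negated_vectors_split_first(self):
        fct = pd.DataFrame({
            1: {"m1": 2.0, "m2": 4.0, "m3": 0.5},
            2: {"m1": 0.5, "m2": 0.25, "m3": 2.0},  # log2 FC exactly negated
        }).T
        groups = mp.group_clusters(fct, n_groups=2)
        assert groups[1] != groups[2]

    def test_planted_archetypes_recovered(self):
        rng = np.random.default_rng(6)
        archetypes = rng.normal(0, 1, (3, 20))
        rows = {}
        truth = []
        for i in range(12):
            g = i % 3
            rows[i + 1] = np.exp2(archetypes[g] + rng.normal(0, 0.1, 20))
            truth.append(g)
        fct = pd.DataFrame(rows, index=[f"m{j}" for j in range(20)]).T
        groups = mp.group_clusters(fct, n_groups=3)
        assert exact_partition_match(groups, truth)

    def test_too_many_groups_rejected(self):
        fct = pd.DataFrame({1: {"m": 2.0}, 2: {"m": 0.5}}).T
        with pytest.raises(ValueError, match="n_groups"):
            mp.group_clusters(fct, n_groups=3)


class TestPrimaryAssignment:
    def _model(self, n_biomarkers, assignment):
        return mp.ClusterModel(
            assignments=pd.Series(assignment, index=[f"B{j}" for j in range(n_biomarkers)]),
            k=len(set(assignment)), linkage_tree=None, silhouette_by_k={})

    def test_all_in_one_cluster(self):
        M = np.array([[1, 1, 0, 0]])
        labels = np.array(["ASD"])
        profile = make_profile(M)
        model = self._model(4, [1, 1, 2, 2])
        out = mp.assign_primary_cluster(profile, model, labels)
        assert out.loc["P0", "primary_cluster"] == 1
        assert out.loc["P0", "cluster_count"] == 1

    def test_majority_cluster_wins(self):
        M = np.array([[1, 1, 1, 1, 0]])
        labels = np.array(["ASD"])
        profile = make_profile(M)
        model = self._model(5, [1, 1, 1, 2, 2])
        out = mp.assign_primary_cluster(profile, model, labels)
        assert out.loc["P0", "primary_cluster"] == 1
        assert out.loc["P0", "cluster_count"] == 2

    def test_tie_broken_by_cluster_pct_asd(self):
        # participant P0 has 1 positive in each cluster; cluster 2 identifies
        # more ASD participants overall and must win the tie
        M = np.array([
            [1, 1],   # P0 (the tie)
            [0, 1],   # extra ASD participants identified by cluster 2 only
            [0, 1],
        ])
        labels = np.array(["ASD", "ASD", "ASD"])
        profile = make_profile(M)
        model = self._model(2, [1, 2])
        out = mp.assign_primary_cluster(profile, model, labels)
        assert out.loc["P0", "primary_cluster"] == 2

    def test_all_negative_excluded(self):
        M = np.array([[1, 0], [0, 0]])
        labels = np.array(["ASD", "TYP"])
        out = mp.assign_primary_cluster(make_profile(M), self._model(2, [1, 2]), labels)
        assert "P1" not in out.index

    def test_partition_conservation(self, default_screened):
        """Summing per-cluster positive-biomarker counts over clusters must
        reproduce each participant's total positive count."""
        profile = default_screened["profile"]
        labels = default_screened["labels"]
        D = mp.jaccard_distance_matrix(profile)
        model = mp.cluster_biomarkers(D, k_range=(2, 12))
        counts = pd.DataFrame(index=profile.matrix.index)
        for cid, members in model.clusters.items():
            counts[cid] = profile.matrix[members].sum(axis=1)
        np.testing.assert_array_equal(counts.sum(axis=1).to_numpy(),
                                      profile.positive_counts.to_numpy())

    def test_cluster_count_tracks_true_phenotype_burden(self, default_screened):
        """The engine behind the severity analyses: discovered cluster count
        correlates with the number of planted phenotypes carried."""
        from scipy.stats import spearmanr

        profile = default_screened["profile"]
        labels = default_screened["labels"]
        cohort = default_screened["cohort"]
        D = mp.jaccard_distance_matrix(profile)
        model = mp.cluster_biomarkers(D)
        primary = mp.assign_primary_cluster(profile, model, labels)
        cc = primary["cluster_count"].reindex(profile.matrix.index).fillna(0)
        truth_count = cohort.truth.carried_count.reindex(profile.matrix.index)
        rho = spearmanr(cc, truth_count).statistic
        assert rho > 0.3
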