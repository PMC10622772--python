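import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import metabophen as mp


def brute_force_threshold(values, labels, min_sens=0.045):
    """Independent oracle: exhaustive enumeration of every cut position on
    the sorted values, keeping the best (PMP, sensitivity) pair subject to
    the sensitivity floor."""
    v = np.asarray(values, float)
    y = np.asarray(labels) == "ASD" if np.asarray(labels).dtype != bool else np.asarray(labels)
    n_case = y.sum()
    order = np.argsort(-v, kind="stable")
    vs, ys = v[order], y[order]
    best = None
    for j in range(1, len(v) + 1):  # positives = top j values
        if j < len(v) and vs[j - 1] == vs[j]:
            continue  # not a boundary between distinct values
        n_pos_case = int(ys[:j].sum())
        sens = n_pos_case / n_case
        pmp = n_pos_case / j
        if sens < min_sens:
            continue
        if best is None or (pmp, sens) > best:
            best = (pmp, sens)
    return best


class TestSelectThreshold:
    def test_perfect_separation(self):
        values = [5, 6, 7, 1, 2, 3]
        labels = ["ASD"] * 3 + ["TYP"] * 3
        res = mp.select_threshold(values, labels)
        assert res.threshold == pytest.approx(4.0)
        assert res.sensitivity == 1.0
        assert res.pmp == 1.0
        assert res.n_positive == 3

    def test_wrong_orientation_recovered_by_flip(self):
        values = np.array([1, 2, 3, 5, 6, 7], dtype=float)
        labels = np.array(["ASD"] * 3 + ["TYP"] * 3)
        res = mp.select_threshold(values, labels)
        assert res.pmp <= 0.5
        flipped = mp.select_threshold(-values, labels)
        assert flipped.pmp == 1.0 and flipped.sensitivity == 1.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(20, 60))
            v = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = np.where(rng.random(n) < 0.6, "ASD", "TYP")
            if (labels == "ASD").sum() in (0, n):
                continue
            res = mp.select_threshold(v, labels)
            assert (res.pmp, res.sensitivity) == brute_force_threshold(v, labels)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="missing"):
            mp.select_threshold([np.nan, np.nan], ["ASD", "TYP"])

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="case"):
            mp.select_threshold([1.0, 2.0], ["ASD", "ASD"])

    def test_missing_dropped_pairwise(self):
        values = [5, 6, 7, np.nan, 1, 2, 3]
        labels = ["ASD"] * 4 + ["TYP"] * 3
        res = mp.select_threshold(values, labels)
        assert res.pmp == 1.0  # computed over the 6 non-missing values


class TestCrossValidation:
    def _separated(self, n_per=40):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(5, 0.3, n_per), rng.normal(0, 0.3, n_per)])
        labels = np.array(["ASD"] * n_per + ["TYP"] * n_per)
        strata = labels.copy()
        return v, labels, strata

    def test_perfectly_separated_feature(self):
        v, labels, strata = self._separated()
        sens, pmp = mp.crossvalidate_feature(v, labels, strata, repeats=5, seed=0)
        assert sens == 1.0
        assert pmp == 1.0

    def test_null_feature_pmp_near_prevalence(self):
        rng = np.random.default_rng(1)
        n = 400
        labels = np.array(["ASD"] * 280 + ["TYP"] * 120)
        v = rng.normal(size=n)
        sens, pmp = mp.crossvalidate_feature(v, labels, labels, repeats=10, seed=1)
        assert pmp == pytest.approx(0.70, abs=0.1)
        assert pmp < 0.90

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=120)
        labels = np.where(rng.random(120) < 0.6, "ASD", "TYP")
        a = mp.crossvalidate_feature(v, labels, labels, repeats=5, seed=7)
        b = mp.crossvalidate_feature(v, labels, labels, repeats=5, seed=7)
        assert a == b

    def test_small_strata_merged_not_fatal(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=50)
        labels = np.where(rng.random(50) < 0.5, "ASD", "TYP")
        strata = np.array([f"{l}|s|a{i % 25}" for i, l in enumerate(labels)])  # tiny strata
        sens, pmp = mp.crossvalidate_feature(v, labels, strata, repeats=2, seed=0)
        assert 0.0 <= sens <= 1.0 and 0.0 <= pmp <= 1.0

    def test_make_strata_terciles(self):
        cohort = mp.generate_cohort(mp.CohortConfig(seed=8, n_asd=120, n_typ=60))
        strata = mp.make_strata(cohort.records)
        parts = strata.str.split("|", expand=True)
        assert set(parts[0]) == {"ASD", "TYP"}
        # age terciles are diagnosis-specific: three bins per diagnosis
        assert parts.groupby(0)[2].nunique().max() <= 3


class TestPermutation:
    def test_perfect_separation_small_p(self):
        # at non-degenerate n the 4.5% floor keeps the null statistic from
        # saturating at 1, so a perfectly separated feature is significant
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.normal(5, 0.3, 300), rng.normal(0, 0.3, 200)])
        labels = np.array(["ASD"] * 300 + ["TYP"] * 200)
        p = mp.permutation_test(v, labels, n_perm=199, seed=0)
        assert p <= 0.05

    def test_constant_feature_p_one(self):
        v = np.ones(40)
        labels = np.array(["ASD"] * 25 + ["TYP"] * 15)
        assert mp.permutation_test(v, labels, n_perm=199, seed=0) == 1.0

    def test_min_permutations_enforced(self):
        with pytest.raises(ValueError, match="99"):
            mp.permutation_test([1.0, 2.0], ["ASD", "TYP"], n_perm=10)

    def test_null_p_values_approximately_uniform(self):
        """Under label-independent features the permutation p-value should be
        ~Uniform(0,1); checked with a KS statistic over simulated nulls."""
        rng = np.random.default_rng(5)
        n = 420
        labels = np.array(["ASD"] * 280 + ["TYP"] * 140)
        ps = []
        for i in range(300):
            v = rng.normal(size=n)
            ps.append(mp.permutation_test(v, labels, n_perm=199, seed=1000 + i))
        ks = sps.kstest(ps, "uniform").statistic
        assert ks < 0.1


class TestAdjustFdr:
    def test_constant_ratio_example(self):
        np.testing.assert_allclose(mp.adjust_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        np.testing.assert_allclose(mp.adjust_fdr([0.07]), [0.07])

    def test_two_p_hand_computation(self):
        np.testing.assert_allclose(mp.adjust_fdr([0.001, 0.5]), [0.002, 0.5])

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            mp.adjust_fdr([0.5, 1.2])

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(6)
        p = rng.random(50)
        adj = mp.adjust_fdr(np.sort(p))
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj <= 1.0).all()


class TestScreenAll:
    def test_reproducible_and_orientation_search(self, default_screened):
        fm = default_screened["fm"]
        labels = default_screened["labels"]
        strata = default_screened["strata"]
        small = mp.FeatureMatrix(
            fm.values.iloc[:, :40], fm.mu.iloc[:40], fm.sigma.iloc[:40],
            fm.definitions[:40])
        params = mp.ScreenParams(repeats=3, n_perm=99, seed=3)
        a = mp.screen_all(small, labels, strata, params).to_frame()
        b = mp.screen_all(small, labels, strata, params).to_frame()
        pd.testing.assert_frame_equal(a, b)
        assert set(a["orientation"]) <= {"up", "down"}

    def test_flagged_singles_excluded_by_default(self, default_screened):
        result = default_screened["result"]
        screened = {d.feature_id for d in result.definitions}
        for mid in mp.defaults.LOW_QUANT_METABOLITES:
            assert mid not in screened
        assert result.metadata["n_features_screened"] == 51 + 1275

    def test_accepted_satisfy_acceptance_rule(self, default_screened):
        result = default_screened["result"]
        p = result.params
        assert len(result.accepted) > 0
        for d in result.accepted:
            assert d.cv_sensitivity >= p.min_sens
            assert d.cv_pmp >= p.min_pmp
            assert d.adj_p < p.alpha_fdr

    def test_planted_phenotypes_recovered(self, default_screened):
        accepted_names = " ".join(d.feature_id for d in default_screened["result"].accepted)
        assert "lactate" in accepted_names
        assert "carnitine" in accepted_names


class TestProfiles:
    def test_empty_profile_valid(self, default_screened):
        fm = default_screened["fm"]
        profile = mp.build_profiles([], fm)
        assert profile.matrix.shape == (len(fm.values), 0)
        assert (profile.positive_counts == 0).all()

    def test_row_sums_equal_counts(self, default_screened):
        profile = default_screened["profile"]
        np.testing.assert_array_equal(
            profile.positive_counts.to_numpy(),
            profile.matrix.to_numpy().sum(axis=1))

    def test_thresholds_reproduce_matrix(self, default_screened):
        """Recomputing positivity from stored thresholds must reproduce the
        profile exactly (strict exceedance, missing = negative)."""
        fm = default_screened["fm"]
        profile = default_screened["profile"]
        d = profile.definitions[0]
        v = fm.values[d.feature_id].to_numpy()
        if d.feature.orientation == "down":
            v = -v
        expected = np.where(np.isnan(v), 0, (v > d.threshold).astype(int))
        np.testing.assert_array_equal(profile.matrix[d.feature_id].to_numpy(), expected)

    def test_identified_fraction_counts_cases_only(self):
        matrix = np.zeros((10, 2), dtype=int)
        matrix[:4, 0] = 1  # 4 of 6 cases identified; controls all negative
        labels = np.array(["ASD"] * 6 + ["TYP"] * 4)
        profile = mp.BiomarkerProfile(matrix=pd.DataFrame(
            matrix.astype(np.int8), index=[f"P{i}" for i in range(10)],
            columns=["B0", "B1"]))
        assert mp.identified_fraction(profile, labels) == pytest.approx(4 / 6)
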