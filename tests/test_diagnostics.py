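"""Posterior certainty, profiles, features, subgroup sizes, cross-tabs."""

import numpy as np
import pandas as pd
import pytest

import lcasub as L
from lcasub.diagnostics import ProfileMatrix, _ari_from_counts


class TestPosteriorSummary:
    def test_one_hot_posteriors(self):
        post = np.eye(3)[np.array([0, 1, 2, 0])]
        s = L.posterior_summary(post)
        assert s.median_max_posterior == 1.0
        assert s.n_below_070 == 0 and s.n_multi_033 == 0

    def test_hand_example(self):
        post = np.array([[0.5, 0.5], [0.8, 0.2], [0.65, 0.35]])
        s = L.posterior_summary(post)
        assert s.median_max_posterior == pytest.approx(0.65)
        assert s.n_below_070 == 2
        assert s.n_multi_033 == 2

    def test_strict_boundaries_on_uniform_three_class(self):
        # the multi-membership threshold is one third: an exactly uniform
        # three-class posterior is not counted as shared membership
        post = np.full((10, 3), 1 / 3)
        s = L.posterior_summary(post)
        assert s.n_below_070 == 10
        assert s.n_multi_033 == 0


class TestNormalizedProfile:
    def _fit_for(self, cb, model_kwargs):
        model = L.LCAModel(codebook=cb, **model_kwargs)
        post = np.ones((4, model.K)) / model.K
        return L.FitResult(model=model, loglik=0.0, n_params=1, n_obs=4,
                           bic=0.0, posteriors=post,
                           assignments=L.modal_assign(post), converged=True,
                           n_iter=1, seed=0)

    def test_continuous_range_scaling_and_reversal(self):
        cb = L.Codebook((L.VariableSpec(name="x", kind="continuous",
                                        range=(0, 10)),))
        fit = self._fit_for(cb, dict(
            K=2, pi=np.array([0.5, 0.5]), cat_probs={},
            cont_means={"x": np.array([7.0, 2.0])},
            cont_vars={"x": np.array([1.0, 1.0])}))
        prof = L.normalized_profile(fit, cb)
        assert prof.scores.loc["x"].tolist() == pytest.approx([0.7, 0.2])
        cb_rev = L.Codebook((L.VariableSpec(name="x", kind="continuous",
                                            range=(0, 10),
                                            severity_direction="lower_worse"),))
        fit_rev = self._fit_for(cb_rev, dict(
            K=2, pi=np.array([0.5, 0.5]), cat_probs={},
            cont_means={"x": np.array([7.0, 2.0])},
            cont_vars={"x": np.array([1.0, 1.0])}))
        prof_rev = L.normalized_profile(fit_rev, cb_rev)
        assert prof_rev.scores.loc["x"].tolist() == pytest.approx([0.3, 0.8])

    def test_binary_severe_level_probability(self):
        cb = L.Codebook((L.VariableSpec(name="y", kind="nominal",
                                        levels=(0, 1), severe_level=1),))
        fit = self._fit_for(cb, dict(
            K=2, pi=np.array([0.5, 0.5]),
            cat_probs={"y": np.array([[0.1, 0.9], [0.8, 0.2]])},
            cont_means={}, cont_vars={}))
        prof = L.normalized_profile(fit, cb)
        assert prof.scores.loc["y"].tolist() == pytest.approx([0.9, 0.2])

    def test_nominal_without_severity_info_excluded(self):
        cb = L.Codebook((L.VariableSpec(name="y", kind="nominal",
                                        levels=("a", "b")),))
        fit = self._fit_for(cb, dict(
            K=2, pi=np.array([0.5, 0.5]),
            cat_probs={"y": np.array([[0.1, 0.9], [0.8, 0.2]])},
            cont_means={}, cont_vars={}))
        with pytest.warns(UserWarning):
            prof = L.normalized_profile(fit, cb)
        assert prof.excluded == ["y"] and prof.scores.empty

    def test_reversal_is_involution(self):
        rng = np.random.default_rng(0)
        scores = rng.random((5, 3))
        assert np.allclose(1.0 - (1.0 - scores), scores)


def _profile(rows: dict, K: int) -> ProfileMatrix:
    frame = pd.DataFrame(rows, index=range(1, K + 1)).T
    return ProfileMatrix(scores=frame, methods={k: "test" for k in rows})


class TestDetectFeatures:
    def test_concordant_pair_groups_discordant_apart(self):
        prof = _profile({"v1": [0.9, 0.2], "v2": [0.8, 0.3], "v3": [0.2, 0.9]}, 2)
        groups = L.detect_features(prof)
        members = sorted(tuple(sorted(g.members)) for g in groups)
        assert members == [("v1", "v2"), ("v3",)]
        big = next(g for g in groups if len(g.members) == 2)
        assert big.spread == pytest.approx(0.5)  # min of 0.7 and 0.5
        assert big.classification == "quantitative"

    def test_all_below_spread_threshold_gives_no_features(self):
        prof = _profile({"v1": [0.5, 0.6], "v2": [0.1, 0.2]}, 2)
        assert L.detect_features(prof) == []

    def test_single_class_profile_has_no_features(self):
        prof = _profile({"v1": [0.9]}, 1)
        assert L.detect_features(prof) == []

    def test_invariant_to_class_relabelling(self):
        rows = {"v1": [0.9, 0.1, 0.5], "v2": [0.8, 0.2, 0.5], "v3": [0.1, 0.9, 0.4]}
        perm = {"v1": [0.5, 0.9, 0.1], "v2": [0.5, 0.8, 0.2], "v3": [0.4, 0.1, 0.9]}
        g1 = L.detect_features(_profile(rows, 3))
        g2 = L.detect_features(_profile(perm, 3))
        assert sorted(tuple(sorted(g.members)) for g in g1) == \
            sorted(tuple(sorted(g.members)) for g in g2)
        assert sorted(round(g.spread, 12) for g in g1) == \
            sorted(round(g.spread, 12) for g in g2)


class TestClassifyDifference:
    @pytest.mark.parametrize("a,b,expected", [
        ([0.8, 0.8], [0.3, 0.3], "quantitative"),
        ([0.8, 0.2], [0.2, 0.8], "qualitative"),
        ([0.5, 0.5], [0.5, 0.5], "quantitative"),
    ])
    def test_examples(self, a, b, expected):
        assert L.classify_difference(a, b) == expected


class TestSubgroupSize:
    def _fit_with_shares(self, shares, profile_rows=None, codebook=None):
        n = 1000
        counts = (np.array(shares) * n).astype(int)
        counts[0] += n - counts.sum()
        assignments = np.repeat(np.arange(1, len(shares) + 1), counts)
        K = len(shares)
        post = np.eye(K)[assignments - 1]
        if codebook is None:
            codebook = L.Codebook((L.VariableSpec(name="x", kind="continuous",
                                                  range=(0, 1)),))
            model = L.LCAModel(codebook=codebook, K=K,
                               pi=counts / n,
                               cat_probs={},
                               cont_means={"x": np.array(profile_rows or [0.5] * K)},
                               cont_vars={"x": np.ones(K)})
        return L.FitResult(model=model, loglik=0, n_params=1, n_obs=n, bic=0,
                           posteriors=post, assignments=assignments,
                           converged=True, n_iter=1, seed=0), codebook

    def test_small_class_with_relaxed_variable_conditionally_accepted(self):
        fit, cb = self._fit_with_shares([0.50, 0.46, 0.04],
                                        profile_rows=[0.2, 0.25, 0.9])
        report = L.subgroup_size_check(fit, cb, relaxed_variables=["x"])
        assert report.status == ["ok", "ok", "conditionally_acceptable"]

    def test_class_below_three_percent_always_flagged(self):
        fit, cb = self._fit_with_shares([0.50, 0.48, 0.02],
                                        profile_rows=[0.2, 0.25, 0.9])
        report = L.subgroup_size_check(fit, cb, relaxed_variables=["x"])
        assert report.status[2] == "flagged"

    def test_no_flags_when_all_above_threshold(self):
        fit, cb = self._fit_with_shares([0.6, 0.4], profile_rows=[0.2, 0.8])
        report = L.subgroup_size_check(fit, cb)
        assert report.status == ["ok", "ok"]


class TestCrossTab:
    def test_two_by_two_flags(self):
        ct = L.CrossTab.from_counts(np.array([[8, 2], [1, 9]]))
        assert ct.flags.iloc[0, 0] == "a" and ct.flags.iloc[1, 1] == "a"
        assert ct.flags.iloc[0, 1] == "c"  # 2 is 20% of its row
        assert ct.flags.iloc[1, 0] == "d"  # 1 is >10% of its column only
        assert ct.grand_total == 20

    def test_identical_assignments_diagonal(self):
        a = np.array([1, 1, 2, 3, 3, 3])
        ct = L.crosstab(a, a)
        m = ct.counts.to_numpy()
        assert np.all(m == np.diag(np.diag(m)))
        for i in range(3):
            assert ct.flags.iloc[i, i] == "a"
        assert not (ct.flags.to_numpy() == "c").any()
        assert not (ct.flags.to_numpy() == "d").any()

    def test_margins_reconcile_with_vectors(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 5, 200)
        b = rng.integers(1, 4, 200)
        ct = L.crosstab(a, b)
        assert ct.grand_total == 200
        assert ct.row_margins.sum() == 200 and ct.col_margins.sum() == 200
        assert np.array_equal(ct.counts.sum(axis=1).to_numpy(),
                              ct.row_margins.to_numpy())

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            L.crosstab(np.array([1, 2]), np.array([1]))


class TestAgreement:
    def test_identical_assignments(self):
        a = np.array([1, 2, 3] * 10)
        agr = L.crosstab_agreement(L.crosstab(a, a))
        assert agr.ari == pytest.approx(1.0)
        assert (agr.row_nonzero == 1).all()
        assert agr.percent_agreement == pytest.approx(100.0)

    def test_independent_assignments_have_near_zero_ari(self):
        rng = np.random.default_rng(12)
        a = rng.integers(1, 6, 5000)
        b = rng.integers(1, 6, 5000)
        agr = L.crosstab_agreement(L.crosstab(a, b))
        assert abs(agr.ari) < 0.02

    def test_ari_matches_sklearn(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(7)
        a = rng.integers(1, 4, 300)
        b = (a + (rng.random(300) < 0.3).astype(int) - 1) % 3 + 1
        ct = L.crosstab(a, b)
        assert _ari_from_counts(ct.counts.to_numpy()) == pytest.approx(
            adjusted_rand_score(a, b), abs=1e-12)


class TestRounding:
    @pytest.mark.parametrize("count,total,expected", [
        (219, 928, 24), (154, 928, 17), (75, 928, 8), (45, 928, 5),
    ])
    def test_half_away_from_zero_percent(self, count, total, expected):
        assert L.round_half_up_percent(count, total) == expected
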