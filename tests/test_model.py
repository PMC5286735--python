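"""EM core: likelihood, E/M steps, fitting, parameter counts, BIC."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lcasub as L
from lcasub.model import _posteriors_and_loglik

from conftest import binary_model, make_dataset, oracle_posteriors


def _random_model_and_data(seed):
    """Small random mixed model + dataset (n<=20, <=3 vars, <=3 cats, K<=2)."""
    rng = np.random.default_rng(seed)
    K = rng.integers(1, 3)
    specs = []
    n_vars = rng.integers(1, 4)
    for j in range(n_vars):
        if rng.random() < 0.7:
            C = int(rng.integers(2, 4))
            specs.append(L.VariableSpec(name=f"v{j}", kind="nominal",
                                        levels=tuple(range(C))))
        else:
            specs.append(L.VariableSpec(name=f"v{j}", kind="continuous"))
    cb = L.Codebook(tuple(specs))
    pi = rng.dirichlet(np.ones(K))
    cat_probs, cont_means, cont_vars = {}, {}, {}
    for v in cb:
        if v.is_categorical:
            cat_probs[v.name] = rng.dirichlet(np.ones(v.n_levels), size=K)
        else:
            cont_means[v.name] = rng.normal(0, 2, size=K)
            cont_vars[v.name] = rng.uniform(0.5, 2.0, size=K)
    model = L.LCAModel(codebook=cb, K=int(K), pi=pi, cat_probs=cat_probs,
                       cont_means=cont_means, cont_vars=cont_vars)
    n = int(rng.integers(2, 21))
    cols = {}
    for v in cb:
        if v.is_categorical:
            vals = rng.integers(0, v.n_levels, size=n).astype(object)
        else:
            vals = rng.normal(0, 2, size=n)
        # sprinkle missingness but keep at least one observed cell per row
        mask = rng.random(n) < 0.2
        vals = np.asarray(vals, dtype=object)
        vals[mask] = None
        cols[v.name] = vals
    df = {k: list(v) for k, v in cols.items()}
    import pandas as pd

    frame = pd.DataFrame(df)
    all_missing = frame.isna().all(axis=1)
    frame.loc[all_missing, cb.names[0]] = (
        0 if cb.variables[0].is_categorical else 0.0)
    return model, L.Dataset(frame, cb)


class TestLoglikelihood:
    def test_one_class_binary_equals_binomial_closed_form(self, binary_codebook):
        data = make_dataset(binary_codebook, {"y": [1] * 7 + [0] * 3})
        fit = L.fit_em(data, binary_codebook, K=1, seed=0)
        expected = 7 * math.log(0.7) + 3 * math.log(0.3)
        assert fit.loglik == pytest.approx(expected, abs=1e-8)
        assert fit.model.cat_probs["y"][0, 1] == pytest.approx(0.7, abs=1e-6)

    def test_two_class_mixture_density_hand_value(self, binary_codebook):
        model = binary_model(binary_codebook, pi=[0.6, 0.4], p1=[0.9, 0.2])
        data = make_dataset(binary_codebook, {"y": [1]})
        assert L.loglikelihood(model, data) == pytest.approx(math.log(0.62), abs=1e-12)

    def test_missing_entry_is_skipped(self):
        cb = L.Codebook((
            L.VariableSpec(name="a", kind="nominal", levels=(0, 1)),
            L.VariableSpec(name="b", kind="continuous"),
        ))
        model = L.LCAModel(
            codebook=cb, K=2, pi=np.array([0.6, 0.4]),
            cat_probs={"a": np.array([[0.1, 0.9], [0.8, 0.2]])},
            cont_means={"b": np.array([-1.0, 2.0])},
            cont_vars={"b": np.array([1.5, 1.5])})
        d_both = make_dataset(cb, {"a": [1, 1], "b": [0.5, None]})
        d_full = make_dataset(cb, {"a": [1], "b": [0.5]})
        d_partial = make_dataset(cb, {"a": [1], "b": [None]})
        assert L.loglikelihood(model, d_both) == pytest.approx(
            L.loglikelihood(model, d_full) + L.loglikelihood(model, d_partial),
            abs=1e-10)

    def test_column_deletion_contract_at_K1(self, mixed_codebook):
        rng = np.random.default_rng(11)
        data = make_dataset(mixed_codebook, {
            "y": rng.integers(0, 2, 30).astype(object),
            "grade": rng.integers(0, 3, 30).astype(object),
            "score": rng.uniform(0, 10, 30),
        })
        total = L.fit_em(data, mixed_codebook, 1, seed=0).loglik
        parts = 0.0
        for name in mixed_codebook.names:
            sub = data.select([name])
            parts += L.fit_em(sub, sub.codebook, 1, seed=0).loglik
        assert total == pytest.approx(parts, abs=1e-8)

    def test_dimension_mismatch_raises(self, binary_codebook, mixed_codebook):
        model = binary_model(binary_codebook, [1.0], [0.5])
        data = make_dataset(mixed_codebook, {"y": [0], "grade": [1], "score": [2.0]})
        with pytest.raises(L.DimensionMismatchError):
            L.loglikelihood(model, data)


class TestEStep:
    def test_single_class_posteriors_are_one(self, binary_codebook):
        model = binary_model(binary_codebook, [1.0], [0.3])
        data = make_dataset(binary_codebook, {"y": [0, 1, 1]})
        assert np.allclose(L.e_step(model, data), 1.0)

    def test_hand_bayes_rule_value(self, binary_codebook):
        model = binary_model(binary_codebook, [0.6, 0.4], [0.9, 0.2])
        data = make_dataset(binary_codebook, {"y": [1]})
        post = L.e_step(model, data)
        assert post[0, 0] == pytest.approx(0.54 / 0.62, abs=1e-12)

    def test_row_missing_all_but_one_variable_matches_single_variable(self):
        cb = L.Codebook((
            L.VariableSpec(name="a", kind="nominal", levels=(0, 1)),
            L.VariableSpec(name="b", kind="nominal", levels=(0, 1)),
        ))
        model = L.LCAModel(
            codebook=cb, K=2, pi=np.array([0.5, 0.5]),
            cat_probs={"a": np.array([[0.2, 0.8], [0.7, 0.3]]),
                       "b": np.array([[0.6, 0.4], [0.1, 0.9]])},
            cont_means={}, cont_vars={})
        data = make_dataset(cb, {"a": [1], "b": [None]})
        post = L.e_step(model, data)
        # only variable a informs the posterior
        expect = 0.5 * 0.8 / (0.5 * 0.8 + 0.5 * 0.3)
        assert post[0, 0] == pytest.approx(expect, abs=1e-12)

    @given(st.integers(0, 60))
    def test_oracle_equivalence_on_small_problems(self, seed):
        """E-step matches direct Bayes enumeration to 1e-10."""
        model, data = _random_model_and_data(seed)
        post = L.e_step(model, data)
        assert np.allclose(post, oracle_posteriors(model, data), atol=1e-10)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)


class TestMStep:
    def test_hard_posteriors_give_per_class_frequencies(self, binary_codebook):
        data = make_dataset(binary_codebook, {"y": [1, 1, 0, 0]})
        post = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        model = L.m_step(post, data, binary_codebook)
        assert model.pi == pytest.approx([0.5, 0.5])
        assert model.cat_probs["y"][0, 1] == pytest.approx(1.0, abs=2e-6)
        assert model.cat_probs["y"][1, 1] == pytest.approx(0.0, abs=2e-6)

    def test_uniform_posteriors_give_marginal_fit(self, binary_codebook):
        data = make_dataset(binary_codebook, {"y": [1, 1, 1, 0]})
        post = np.full((4, 2), 0.5)
        model = L.m_step(post, data, binary_codebook)
        assert np.allclose(model.cat_probs["y"][0], model.cat_probs["y"][1])
        assert model.cat_probs["y"][0, 1] == pytest.approx(0.75, abs=1e-6)

    def test_weighted_frequency_hand_value(self, binary_codebook):
        data = make_dataset(binary_codebook, {"y": [1, 0]})
        post = np.array([[0.8, 0.2], [0.4, 0.6]])
        model = L.m_step(post, data, binary_codebook)
        assert model.pi == pytest.approx([0.6, 0.4], abs=1e-12)
        assert model.cat_probs["y"][0, 1] == pytest.approx(0.8 / 1.2, abs=1e-6)

    def test_collapsed_class_raises(self, binary_codebook):
        data = make_dataset(binary_codebook, {"y": [1, 0]})
        post = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(L.ClassCollapseError):
            L.m_step(post, data, binary_codebook)


class TestFitEM:
    def test_one_class_converges_fast_to_marginal(self, binary_codebook):
        data = make_dataset(binary_codebook, {"y": [1] * 6 + [0] * 4})
        fit = L.fit_em(data, binary_codebook, 1, seed=3)
        assert fit.n_iter <= 2 and fit.converged

    def test_same_seed_is_bitwise_identical(self, mixed_codebook):
        rng = np.random.default_rng(0)
        data = make_dataset(mixed_codebook, {
            "y": rng.integers(0, 2, 40).astype(object),
            "grade": rng.integers(0, 3, 40).astype(object),
            "score": rng.uniform(0, 10, 40),
        })
        f1 = L.fit_em(data, mixed_codebook, 2, seed=9)
        f2 = L.fit_em(data, mixed_codebook, 2, seed=9)
        assert f1.loglik == f2.loglik and f1.bic == f2.bic
        assert np.array_equal(f1.posteriors, f2.posteriors)
        assert np.array_equal(f1.model.pi, f2.model.pi)

    def test_two_class_recovery_within_sampling_error(self):
        # several parallel binary indicators with P(1)=0.9 vs 0.1 per class
        # (a single binary indicator would leave the mixture unidentified)
        rng = np.random.default_rng(42)
        n, J = 500, 5
        cb = L.Codebook(tuple(
            L.VariableSpec(name=f"y{j}", kind="nominal", levels=(0, 1))
            for j in range(J)))
        z = rng.random(n) < 0.5
        cols = {}
        for j in range(J):
            p = np.where(z, 0.9, 0.1)
            cols[f"y{j}"] = (rng.random(n) < p).astype(int).astype(object)
        data = make_dataset(cb, cols)
        fit = L.fit_em(data, cb, 2, seed=1)
        assert fit.model.pi[0] == pytest.approx(0.5, abs=0.05)
        for j in range(J):
            p1 = np.sort(fit.model.cat_probs[f"y{j}"][:, 1])
            assert p1[1] == pytest.approx(0.9, abs=0.05)
            assert p1[0] == pytest.approx(0.1, abs=0.05)

    def test_loglik_monotone_and_invariants(self, mixed_codebook):
        rng = np.random.default_rng(2)
        data = make_dataset(mixed_codebook, {
            "y": rng.integers(0, 2, 60).astype(object),
            "grade": rng.integers(0, 3, 60).astype(object),
            "score": rng.uniform(0, 10, 60),
        })
        fit = L.fit_em(data, mixed_codebook, 3, seed=4)
        hist = np.array(fit.loglik_history)
        assert np.all(np.diff(hist) >= -1e-8)
        assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert fit.bic == -2 * fit.loglik + fit.n_params * math.log(fit.n_obs)
        assert np.array_equal(fit.assignments, fit.posteriors.argmax(axis=1) + 1)
        assert np.all(np.diff(fit.model.pi) <= 1e-12)  # descending weights

    def test_K_larger_than_n_raises(self, binary_codebook):
        data = make_dataset(binary_codebook, {"y": [0, 1]})
        with pytest.raises(ValueError):
            L.fit_em(data, binary_codebook, 3, seed=0)


class TestLabelPermutation:
    def test_permuting_classes_preserves_loglik_and_bic(self):
        model, data = _random_model_and_data(17)
        if model.K == 1:
            model, data = _random_model_and_data(18)
        perm = np.arange(model.K)[::-1]
        ll = L.loglikelihood(model, data)
        ll_p = L.loglikelihood(model.permuted(perm), data)
        assert ll == pytest.approx(ll_p, abs=1e-10)
        p = L.n_parameters(model.codebook, model.K)
        assert L.bic(ll, p, data.n) == pytest.approx(L.bic(ll_p, p, data.n), abs=1e-10)


class TestCounts:
    def test_single_class_binary_has_one_parameter(self):
        cb = L.Codebook((L.VariableSpec(name="y", kind="nominal", levels=(0, 1)),))
        assert L.n_parameters(cb, 1) == 1

    def test_mixed_codebook_term_by_term(self):
        cb = L.Codebook((
            L.VariableSpec(name="a", kind="nominal", levels=(0, 1, 2, 3)),
            L.VariableSpec(name="b", kind="nominal", levels=(0, 1)),
            L.VariableSpec(name="c", kind="continuous"),
        ))
        assert L.n_parameters(cb, 3, "pooled") == 2 + 3 * 3 + 3 * 1 + (3 + 1)
        assert L.n_parameters(cb, 3, "class_specific") == 2 + 9 + 3 + 6

    def test_empty_codebook_is_invalid(self):
        with pytest.raises(L.DimensionMismatchError):
            L.n_parameters(L.Codebook(()), 2)


class TestBIC:
    @pytest.mark.parametrize("loglik,p,n,expected", [
        (0.0, 0, 50, 0.0),
        (-500.0, 10, 100, 1000 + 10 * math.log(100)),
    ])
    def test_formula(self, loglik, p, n, expected):
        assert L.bic(loglik, p, n) == pytest.approx(expected, abs=1e-10)

    def test_one_extra_parameter_adds_log_n(self):
        assert L.bic(-10, 6, 200) - L.bic(-10, 5, 200) == pytest.approx(
            math.log(200), abs=1e-12)

    def test_invalid_n_raises(self):
        with pytest.raises(ValueError):
            L.bic(-10, 5, 0)


class TestModalAssign:
    @pytest.mark.parametrize("post,expected", [
        ([[0.7, 0.3]], [1]),
        ([[0.5, 0.5]], [1]),  # tie breaks toward the lowest class
        ([[0.2, 0.3, 0.5], [0.6, 0.3, 0.1]], [3, 1]),
    ])
    def test_examples(self, post, expected):
        assert L.modal_assign(np.array(post)).tolist() == expected
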