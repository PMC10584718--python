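"""Gaussian LDA classification and Wilks'-lambda stepwise selection."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from vowelmap import (
    ValidationError,
    VowelToken,
    classify_proportions,
    loo_cv_accuracy,
    train_lda,
    wilks_lambda,
    wilks_stepwise,
)
from vowelmap.core_io import design_matrix


def _toks_1d(values_by_class, feature_pad=0.0):
    """1-D problems encoded in f1; f2/f3 constant offsets (normalized
    tokens skip the ordering check)."""
    toks = []
    for label, values in values_by_class.items():
        for i, v in enumerate(values):
            toks.append(VowelToken(
                speaker=f"s{i}", language="CG", vowel=label,
                f1=float(v), f2=feature_pad, f3=feature_pad,
                duration=100.0, normalized=True))
    return toks


def _toks_from_xy(X, y):
    X = np.atleast_2d(X)
    pad = np.zeros((X.shape[0], 4 - X.shape[1]))
    full = np.hstack([X, pad])
    return [VowelToken(speaker=f"s{i}", language="CG", vowel=str(label),
                       f1=float(r[0]), f2=float(r[1]), f3=float(r[2]),
                       duration=100.0, normalized=True)
            for i, (r, label) in enumerate(zip(full, y))]


class TestTrainAndPosteriors:
    def test_symmetric_classes_put_the_boundary_at_zero(self):
        rng = np.random.default_rng(0)
        vals_a = rng.normal(-10, 0.1, 20)
        vals_b = rng.normal(+10, 0.1, 20)
        model = train_lda(_toks_1d({"a": vals_a, "b": vals_b}),
                          features=("f1",))
        post = model.posteriors(np.array([[-1.0], [1.0]]))
        assert post[0, 0] > 0.5 > post[1, 0]
        # scores cross close to the midpoint of the class means
        mid = (vals_a.mean() + vals_b.mean()) / 2
        s = model.decision_scores(np.array([[mid]]))
        assert s[0, 0] == pytest.approx(s[0, 1], abs=1e-6)

    def test_posterior_dominates_at_a_class_mean(self):
        rng = np.random.default_rng(1)
        model = train_lda(_toks_1d({
            "a": rng.normal(-10, 0.5, 30), "b": rng.normal(10, 0.5, 30)}),
            features=("f1",))
        post = model.posteriors(np.array([[model.means[0, 0]]]))
        assert post[0, 0] > 0.99

    def test_posteriors_sum_to_one(self, cg_tokens):
        model = train_lda(cg_tokens)
        X, _ = design_matrix(cg_tokens, model.features)
        post = model.posteriors(X)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_two_class_posterior_equals_gaussian_density_ratio(self):
        # closed form: posterior = logistic of the score difference, which
        # must equal the explicit equal-covariance density ratio
        rng = np.random.default_rng(2)
        vals = {"a": rng.normal(-1, 1.0, 25), "b": rng.normal(1, 1.0, 25)}
        model = train_lda(_toks_1d(vals), features=("f1",))
        x = np.array([[0.37]])
        var = model.cov[0, 0]
        dens = [np.exp(-0.5 * (x[0, 0] - m) ** 2 / var)
                for m in model.means[:, 0]]
        expected = dens[0] / (dens[0] + dens[1])
        assert model.posteriors(x)[0, 0] == pytest.approx(expected,
                                                          abs=1e-12)

    def test_singular_covariance_suggests_feature_reduction(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        X = np.column_stack([x, 2 * x])  # perfectly collinear
        y = ["a"] * 10 + ["b"] * 10
        with pytest.raises(ValidationError, match="feature"):
            train_lda(_toks_from_xy(X, y), features=("f1", "f2"))


class TestBruteForceBayesAgreement:
    @pytest.mark.parametrize("seed", range(5))
    def test_small_instances_match_explicit_gaussian_bayes(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 4))
        n_per = int(rng.integers(5, 11))
        centers = rng.normal(0, 3, size=(k, 2))
        X = np.vstack([rng.normal(c, 1.0, size=(n_per, 2))
                       for c in centers])
        y = np.repeat([f"c{i}" for i in range(k)], n_per)
        toks = _toks_from_xy(X, y)
        model = train_lda(toks, features=("f1", "f2"))
        # oracle: explicit pooled-covariance Gaussian densities
        means = {c: X[y == c].mean(axis=0) for c in model.classes}
        W = sum((X[y == c] - means[c]).T @ (X[y == c] - means[c])
                for c in model.classes)
        cov = W / (len(y) - k)
        grid = rng.normal(0, 3, size=(40, 2))
        expect = []
        for x in grid:
            dens = {c: multivariate_normal.pdf(x, mean=means[c], cov=cov)
                    for c in model.classes}
            expect.append(max(dens, key=dens.get))
        got = model.predict(grid)
        assert list(got) == expect

    def test_agreement_with_scikit_learn_reference(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(c, 1.0, size=(30, 2))
                       for c in ([-2, 0], [2, 0], [0, 3])])
        y = np.repeat(["a", "b", "c"], 30)
        model = train_lda(_toks_from_xy(X, y), features=("f1", "f2"))
        ref = sklearn.LinearDiscriminantAnalysis(
            priors=[1 / 3] * 3).fit(X, y)
        grid = rng.normal(0, 2, size=(100, 2))
        assert list(model.predict(grid)) == list(ref.predict(grid))


class TestLeaveOneOut:
    def test_perfect_separation_scores_one(self):
        rng = np.random.default_rng(4)
        toks = _toks_1d({"a": rng.normal(-100, 1, 20),
                         "b": rng.normal(100, 1, 20)})
        assert loo_cv_accuracy(toks, features=("f1",)) == 1.0

    def test_indistinguishable_classes_approach_chance(self):
        rng = np.random.default_rng(5)
        toks = _toks_1d({"a": rng.normal(0, 1, 150),
                         "b": rng.normal(0, 1, 150)})
        acc = loo_cv_accuracy(toks, features=("f1",))
        assert 0.35 < acc < 0.65


class TestClassifyProportions:
    def test_tokens_at_a_class_mean_map_entirely_to_it(self, cg_tokens):
        model = train_lda(cg_tokens)
        i_mean = model.means[list(model.classes).index("i")]
        probes = [VowelToken(
            speaker="x", language="NL", vowel="i",
            f1=i_mean[0], f2=i_mean[1], f3=i_mean[2],
            duration=i_mean[3], normalized=True) for _ in range(5)]
        matrix = classify_proportions(model, probes)
        assert matrix.row("i")["i"] == 1.0

    def test_rows_sum_to_one(self, cg_tokens, nl_tokens):
        model = train_lda(cg_tokens)
        matrix = classify_proportions(model, nl_tokens)
        sums = matrix.data.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert matrix.source == "acoustic"

    def test_equidistant_token_ties_are_flagged(self):
        toks = _toks_1d({"a": [-2.0, -1.0], "b": [1.0, 2.0]})
        model = train_lda(toks, features=("f1",))
        probe = [VowelToken(speaker="x", language="NL", vowel="p",
                            f1=0.0, f2=0.0, f3=0.0, duration=100.0,
                            normalized=True)]
        post = model.posteriors(np.array([[0.0]]))
        assert post[0] == pytest.approx([0.5, 0.5], abs=1e-12)
        matrix = classify_proportions(model, probe)
        assert "p" in matrix.tie_rows
        assert matrix.row("p")["a"] == 1.0  # canonical-order tie break

    def test_missing_expected_vowel_is_an_error(self, cg_tokens):
        model = train_lda(cg_tokens)
        with pytest.raises(ValidationError, match="œ"):
            classify_proportions(model, cg_tokens[:10],
                                 expected_vowels=["œ"])


class TestWilksStepwise:
    def test_noise_feature_is_not_entered(self):
        rng = np.random.default_rng(6)
        X = np.column_stack([
            np.concatenate([rng.normal(-5, 1, 40), rng.normal(5, 1, 40)]),
            rng.normal(0, 1, 80)])
        y = np.repeat(["a", "b"], 40)
        trace = wilks_stepwise(_toks_from_xy(X, y),
                               candidates=("f1", "f2"))
        assert trace.features == ("f1",)

    def test_entry_order_matches_exhaustive_lambda_enumeration(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([
            np.concatenate([rng.normal(-1, 1, 40), rng.normal(1, 1, 40)]),
            np.concatenate([rng.normal(-3, 1, 40), rng.normal(3, 1, 40)])])
        y = np.repeat(["a", "b"], 40)
        lam = {f: wilks_lambda(X[:, [j]], np.array(y, dtype=object),
                               ("a", "b"))
               for j, f in enumerate(("f1", "f2"))}
        trace = wilks_stepwise(_toks_from_xy(X, y),
                               candidates=("f1", "f2"))
        assert trace.features[0] == min(lam, key=lam.get)

    def test_lambda_strictly_decreases(self, cg_tokens):
        trace = wilks_stepwise(cg_tokens)
        lams = [s.wilks_lambda for s in trace.steps]
        assert all(a > b for a, b in zip(lams, lams[1:]))
        assert all(s.p_value < trace.alpha for s in trace.steps)

    def test_duplicated_collinear_feature_rejected(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(-5, 1, 30), rng.normal(5, 1, 30)])
        X = np.column_stack([x, x])  # duplicated
        y = np.repeat(["a", "b"], 30)
        trace = wilks_stepwise(_toks_from_xy(X, y),
                               candidates=("f1", "f2"))
        assert trace.features == ("f1",)

    def test_no_qualifying_candidate_gives_empty_trace(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 1, size=(40, 2))  # pure noise
        y = np.repeat(["a", "b"], 20)
        trace = wilks_stepwise(_toks_from_xy(X, y),
                               candidates=("f1", "f2"), alpha=1e-6)
        assert trace.steps == []
        assert trace.diagnostics
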