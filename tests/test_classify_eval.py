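"""Naive Bayes training/prediction against brute-force and scikit-learn
oracles; metric identities; cross-validation; ROC."""

import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import MultinomialNB

from fusemine.classify_eval import (
    ClassifyError,
    NBModel,
    cross_validate,
    evaluate,
    predict_many,
    predict_nb,
    roc_curve,
    split_40_60,
    split_halves,
    token_agreement_score,
    train_nb,
)


def brute_force_posterior(X_train, y_train, x, alpha):
    """Independent Bayes computation with explicit loops."""
    classes = sorted(set(y_train))
    n_features = len(x)
    log_joint = {}
    for cls in classes:
        rows = [X_train[i] for i in range(len(y_train)) if y_train[i] == cls]
        prior = len(rows) / len(y_train)
        total = sum(sum(r) for r in rows)
        lj = math.log(prior)
        for j in range(n_features):
            count = sum(r[j] for r in rows)
            theta = (count + alpha) / (total + alpha * n_features)
            lj += x[j] * math.log(theta)
        log_joint[cls] = lj
    m = max(log_joint.values())
    unnorm = {c: math.exp(v - m) for c, v in log_joint.items()}
    z = sum(unnorm.values())
    return {c: v / z for c, v in unnorm.items()}


class TestTrainNB:
    def test_hand_computed_likelihoods(self):
        # 2 docs, 2 words, alpha=1: theta = (count+1)/(total+V)
        X = [[3, 0], [0, 2]]
        model = train_nb(X, ["pos", "neg"], alpha=1.0)
        i_pos = model.classes.index("pos")
        i_neg = model.classes.index("neg")
        assert np.exp(model.log_likelihood[i_pos]) == pytest.approx(
            [(3 + 1) / (3 + 2), (0 + 1) / (3 + 2)]
        )
        assert np.exp(model.log_likelihood[i_neg]) == pytest.approx(
            [(0 + 1) / (2 + 2), (2 + 1) / (2 + 2)]
        )

    def test_balanced_labels_equal_priors(self):
        model = train_nb([[1, 0], [0, 1]], ["a", "b"], alpha=1.0)
        assert np.exp(model.log_prior) == pytest.approx([0.5, 0.5])

    def test_likelihoods_normalize_per_class(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 5, size=(8, 6))
        model = train_nb(X, ["a", "b"] * 4, alpha=0.7)
        for row in model.log_likelihood:
            assert np.exp(row).sum() == pytest.approx(1.0)
        assert np.exp(model.log_prior).sum() == pytest.approx(1.0)

    def test_alpha_zero_is_error(self):
        with pytest.raises(ClassifyError):
            train_nb([[1], [1]], ["a", "b"], alpha=0.0)

    def test_single_class_is_error(self):
        with pytest.raises(ClassifyError):
            train_nb([[1], [2]], ["a", "a"])


class TestPredictNB:
    def test_symmetric_model_ties_to_negative(self):
        X = [[2, 0], [0, 2]]
        model = train_nb(X, ["neg", "pos"], alpha=1.0, negative_label="neg")
        label, post = predict_nb(model, [1, 1])
        assert post["neg"] == pytest.approx(0.5)
        assert post["pos"] == pytest.approx(0.5)
        assert label == "neg"

    def test_zero_vector_predicts_prior_argmax(self):
        X = [[1, 0], [1, 0], [0, 1]]
        model = train_nb(X, ["maj", "maj", "min"], alpha=1.0)
        label, post = predict_nb(model, [0, 0])
        assert label == "maj"
        assert post["maj"] == pytest.approx(2 / 3)

    def test_vocabulary_mismatch_rejected(self):
        model = train_nb([[1, 0], [0, 1]], ["a", "b"],
                         vocabulary_ref=("u", "v"))
        with pytest.raises(ClassifyError, match="vocabulary"):
            predict_nb(model, [1, 0], vocabulary_ref=("u", "w"))
        with pytest.raises(ClassifyError):
            predict_nb(model, [1, 0, 0])

    def test_brute_force_oracle_equivalence(self):
        """Posteriors equal exhaustive Bayes on all small instances."""
        rng = random.Random(7)
        for _ in range(60):
            n_docs = rng.randint(2, 5)
            n_feats = rng.randint(1, 4)
            X = [[rng.randint(0, 3) for _ in range(n_feats)]
                 for _ in range(n_docs)]
            y = ["pos" if i % 2 else "neg" for i in range(n_docs)]
            alpha = rng.choice([0.5, 1.0, 2.0])
            model = train_nb(X, y, alpha=alpha)
            x = [rng.randint(0, 3) for _ in range(n_feats)]
            _, post = predict_nb(model, x)
            expected = brute_force_posterior(X, y, x, alpha)
            for cls in expected:
                assert post[cls] == pytest.approx(expected[cls], abs=1e-10)

    def test_matches_sklearn_multinomial_nb(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 6, size=(20, 8)).astype(float)
        y = ["pos" if v else "neg" for v in rng.integers(0, 2, size=20)]
        model = train_nb(X, y, alpha=1.0)
        sk = MultinomialNB(alpha=1.0).fit(X, y)
        _, post = predict_many(model, X)
        ours = post[:, model.classes.index("pos")]
        theirs = sk.predict_proba(X)[:, list(sk.classes_).index("pos")]
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_json_round_trip(self, tmp_path):
        model = train_nb([[1, 2], [3, 0]], ["a", "b"],
                         vocabulary_ref=(("x",), ("y", "z")))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = NBModel.from_json(path)
        assert back.classes == model.classes
        assert np.allclose(back.log_likelihood, model.log_likelihood)
        assert back.vocabulary_ref == model.vocabulary_ref


class TestEvaluate:
    def test_printed_substitution(self):
        report = evaluate(
            ["p", "p", "p", "n", "p"], ["p", "p", "p", "p", "n"], "p"
        )
        assert (report.tp, report.fp, report.fn) == (3, 1, 1)
        assert report.precision == pytest.approx(0.75)
        assert report.recall == pytest.approx(0.75)
        assert report.f_score == pytest.approx(0.75)

    def test_perfect_prediction(self):
        report = evaluate(["p", "n"], ["p", "n"], "p")
        assert (report.precision, report.recall,
                report.f_score, report.accuracy) == (1.0, 1.0, 1.0, 1.0)

    def test_no_predicted_positives_precision_undefined(self):
        report = evaluate(["p", "n"], ["n", "n"], "p")
        assert report.precision is None
        assert report.recall == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ClassifyError):
            evaluate(["p"], ["p", "n"], "p")

    def test_random_count_triples_match_formulas(self):
        """Eqs for P/R/F recovered from 1000 random confusion counts."""
        rng = random.Random(99)
        for _ in range(1000):
            tp, fp, fn = (rng.randint(0, 20) for _ in range(3))
            truth = ["p"] * (tp + fn) + ["n"] * fp
            pred = ["p"] * tp + ["n"] * fn + ["p"] * fp
            report = evaluate(truth, pred, "p")
            if tp + fp:
                assert report.precision == pytest.approx(tp / (tp + fp))
            else:
                assert report.precision is None
            if tp + fn:
                assert report.recall == pytest.approx(tp / (tp + fn))
            else:
                assert report.recall is None
            p, r = report.precision, report.recall
            if p is not None and r is not None and p + r > 0:
                assert report.f_score == pytest.approx(2 * p * r / (p + r))

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=300, deadline=None)
    def test_f_between_min_and_max_of_p_and_r(self, tp, fp, fn):
        truth = ["p"] * (tp + fn) + ["n"] * fp
        pred = ["p"] * tp + ["n"] * fn + ["p"] * fp
        report = evaluate(truth, pred, "p")
        p, r = report.precision, report.recall
        if p is not None and r is not None and p + r > 0:
            assert min(p, r) - 1e-12 <= report.f_score <= max(p, r) + 1e-12

    def test_metrics_invariant_to_example_order(self):
        truth = ["p", "n", "p", "n", "p"]
        pred = ["p", "p", "n", "n", "p"]
        base = evaluate(truth, pred, "p")
        rng = random.Random(0)
        order = list(range(5))
        rng.shuffle(order)
        shuffled = evaluate([truth[i] for i in order],
                            [pred[i] for i in order], "p")
        assert (base.tp, base.fp, base.fn, base.tn) == (
            shuffled.tp, shuffled.fp, shuffled.fn, shuffled.tn)


class TestTokenAgreementScore:
    def test_printed_worked_example(self):
        assert token_agreement_score(
            ["n", "y", "n", "a"], ["n", "n", "n", "a"]
        ) == pytest.approx(0.75)

    def test_identical_sequences(self):
        assert token_agreement_score(["y", "n", "a"], ["y", "n", "a"]) == 1.0

    def test_fully_disagreeing(self):
        assert token_agreement_score(["y", "y"], ["n", "a"]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ClassifyError):
            token_agreement_score(["y"], ["y", "n"])

    def test_labels_outside_alphabet_rejected(self):
        with pytest.raises(ClassifyError):
            token_agreement_score(["x"], ["y"])


class TestCrossValidate:
    def _data(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        X = np.zeros((n, 4))
        y = []
        for i in range(n):
            if i % 2:
                X[i] = [5, 4, 0, 0] + rng.integers(0, 2, 4)
                y.append("pos")
            else:
                X[i] = [0, 0, 5, 4] + rng.integers(0, 2, 4)
                y.append("neg")
        return X, y

    def test_each_example_tested_exactly_once(self):
        X, y = self._data(20)
        report = cross_validate(X, y, "pos", k=10, seed=3)
        assert report.tp + report.fp + report.fn + report.tn == 20

    def test_n_equals_k_single_test_example_per_fold(self):
        X, y = self._data(10)
        report = cross_validate(X, y, "pos", k=10, seed=3)
        assert len(report.per_fold) == 10
        for fold in report.per_fold:
            assert fold["TP"] + fold["FP"] + fold["FN"] + fold["TN"] == 1

    def test_same_seed_same_result(self):
        X, y = self._data(20)
        a = cross_validate(X, y, "pos", k=5, seed=42)
        b = cross_validate(X, y, "pos", k=5, seed=42)
        assert a.to_dict() == b.to_dict()

    def test_separable_data_recovers_labels(self):
        X, y = self._data(40)
        report = cross_validate(X, y, "pos", k=10, seed=1)
        assert report.f_score == pytest.approx(1.0)
        assert report.auc == pytest.approx(1.0)

    def test_k_too_large_rejected(self):
        X, y = self._data(4)
        with pytest.raises(ClassifyError):
            cross_validate(X, y, "pos", k=10)

    def test_alternative_split_protocols_partition(self):
        _, y = self._data(20)
        train, test = split_40_60(y, seed=0)
        assert len(train) + len(test) == 20
        assert set(train) & set(test) == set()
        assert len(train) == 8
        train, test = split_halves(y, seed=0)
        assert len(train) + len(test) == 20
        assert set(train) & set(test) == set()


class TestRocCurve:
    def test_perfect_separation(self):
        points, auc = roc_curve(["n", "n", "p", "p"],
                                [0.1, 0.2, 0.8, 0.9], "p")
        assert (0.0, 1.0) in points
        assert auc == pytest.approx(1.0)

    def test_constant_posteriors_auc_half(self):
        points, auc = roc_curve(["p", "n", "p", "n"], [0.5] * 4, "p")
        assert auc == pytest.approx(0.5)

    def test_endpoints_and_monotone(self):
        rng = random.Random(5)
        truth = [rng.choice("pn") for _ in range(30)]
        truth[0], truth[1] = "p", "n"
        scores = [rng.random() for _ in range(30)]
        points, _ = roc_curve(truth, scores, "p")
        assert points[0] == (0.0, 0.0)
        assert points[-1] == (1.0, 1.0)
        for (f1, t1), (f2, t2) in zip(points, points[1:]):
            assert f2 >= f1 and t2 >= t1

    def test_single_class_truth_is_error(self):
        with pytest.raises(ClassifyError):
            roc_curve(["p", "p"], [0.5, 0.6], "p")

    def test_auc_equals_pairwise_concordance(self):
        """Oracle: AUC = (concordant + ties/2) / (n_pos * n_neg)."""
        rng = random.Random(17)
        for _ in range(50):
            n = rng.randint(4, 25)
            truth = [rng.choice("pn") for _ in range(n)]
            if "p" not in truth:
                truth[0] = "p"
            if "n" not in truth:
                truth[-1] = "n"
            scores = [rng.choice([0.1, 0.3, 0.5, 0.7, 0.9]) for _ in range(n)]
            _, auc = roc_curve(truth, scores, "p")
            pos = [s for s, t in zip(scores, truth) if t == "p"]
            neg = [s for s, t in zip(scores, truth) if t == "n"]
            conc = sum(
                1.0 if sp > sn else 0.5 if sp == sn else 0.0
                for sp, sn in itertools.product(pos, neg)
            )
            assert auc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_matches_sklearn_auc(self):
        rng = np.random.default_rng(23)
        truth = ["p" if v else "n" for v in rng.integers(0, 2, 40)]
        truth[0], truth[1] = "p", "n"
        scores = rng.random(40).tolist()
        _, auc = roc_curve(truth, scores, "p")
        expected = roc_auc_score([t == "p" for t in truth], scores)
        assert auc == pytest.approx(expected, abs=1e-12)
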