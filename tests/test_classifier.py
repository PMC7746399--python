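"""N-gram featurization, the L1 linear classifier, CV and the AUC statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paitraj.classifier import (
    build_vocabulary,
    compare_predictions,
    cross_validate,
    featurize,
    featurize_corpus,
    lexicon_baseline,
    predict_corpus,
    roc_auc,
    train,
)
from paitraj.corpus import tokenize


def brute_force_auc(scores, labels):
    """Probability a random positive outranks a random negative, ties = 1/2."""
    s = np.asarray(scores, dtype=float)
    pos = s[np.asarray(labels) == 1]
    neg = s[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestVocabulary:
    def test_document_frequency_threshold_boundary(self):
        # 100 docs at 2%: an n-gram in 2 docs is kept, in 1 doc dropped
        docs = [["common"] for _ in range(98)] + [["common", "pair"], ["common", "pair"]]
        docs[0] = ["common", "solo"]
        vocab = build_vocabulary(docs, nmax=1, min_doc_frac=0.02)
        grams = set(vocab.ngrams)
        assert ("pair",) in grams and ("common",) in grams
        assert ("solo",) not in grams

    def test_zero_threshold_keeps_everything(self):
        docs = [["a", "b"], ["c"]]
        vocab = build_vocabulary(docs, nmax=2, min_doc_frac=0.0)
        assert set(vocab.ngrams) == {("a",), ("b",), ("c",), ("a", "b")}

    def test_exhaustive_enumeration_small_corpus(self):
        docs = [tokenize("i like swimming")] * 3
        vocab = build_vocabulary(docs, nmax=3, min_doc_frac=0.02)
        assert set(vocab.ngrams) == {
            ("i",),
            ("like",),
            ("swimming",),
            ("i", "like"),
            ("like", "swimming"),
            ("i", "like", "swimming"),
        }

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])

    def test_deterministic_lexicographic_order(self):
        docs = [["b", "a"], ["a", "b"]]
        vocab = build_vocabulary(docs, nmax=1, min_doc_frac=0.0)
        assert list(vocab.ngrams) == sorted(vocab.ngrams)


class TestFeaturize:
    def test_binary_not_counts(self):
        vocab = build_vocabulary([["swim"], ["swim"]], nmax=1, min_doc_frac=0.0)
        x = featurize(["swim", "swim", "swim"], vocab)
        assert x.tolist() == [1]

    def test_empty_document_all_zero(self):
        vocab = build_vocabulary([["a"], ["b"]], nmax=1, min_doc_frac=0.0)
        assert featurize([], vocab).sum() == 0

    def test_full_coverage_all_one(self):
        vocab = build_vocabulary([["a", "b"]], nmax=2, min_doc_frac=0.0)
        assert featurize(["a", "b"], vocab).min() == 1

    @given(st.lists(st.sampled_from("abcde"), max_size=15), st.lists(st.sampled_from("abcde"), max_size=5))
    @settings(derandomize=True, max_examples=60)
    def test_monotone_in_document_content(self, doc, extra):
        vocab = build_vocabulary([list("abcde"), list("edcba")], nmax=2, min_doc_frac=0.0)
        x0 = featurize(doc, vocab)
        x1 = featurize(doc + extra, vocab)
        assert (x1 >= x0).all()


class TestTrain:
    def _separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        docs, y = [], []
        for _ in range(n):
            label = int(rng.random() < 0.4)
            toks = ["filler", "words", "here"]
            if label:
                toks.append("marker")
            docs.append(toks)
            y.append(label)
        vocab = build_vocabulary(docs, nmax=1, min_doc_frac=0.0)
        return featurize_corpus(docs, vocab), np.array(y), vocab

    def test_separable_corpus_perfect_training_fit(self):
        X, y, vocab = self._separable()
        clf = train(X, y, lam=0.001, vocab=vocab)
        j = vocab.index[("marker",)]
        assert clf.weights[j] > 0
        assert (clf.predict(X) == y).all()

    def test_large_penalty_shrinks_to_majority_class(self):
        X, y, _ = self._separable()
        clf = train(X, y, lam=1e4)
        assert clf.n_nonzero == 0
        assert (clf.predict(X) == int(y.mean() > 0.5)).all()

    def test_row_duplication_leaves_boundary_unchanged(self):
        X, y, _ = self._separable()
        from scipy import sparse

        clf1 = train(X, y, lam=0.01)
        clf2 = train(sparse.vstack([X, X]), np.r_[y, y], lam=0.01)
        np.testing.assert_allclose(clf1.weights, clf2.weights, atol=1e-3)
        assert clf1.intercept == pytest.approx(clf2.intercept, abs=1e-3)

    def test_single_class_labels_rejected(self):
        X, y, _ = self._separable()
        with pytest.raises(ValueError, match="single class"):
            train(X, np.ones_like(y))

    def test_sparsity_nonincreasing_in_lambda(self):
        X, y, _ = self._separable(n=300, seed=1)
        nnz = [train(X, y, lam=lam).n_nonzero for lam in (1e-3, 1e-2, 1e-1, 1.0, 10.0)]
        for a, b in zip(nnz, nnz[1:]):
            assert b <= a + 1  # optimizer tolerance slack of one feature


class TestRocAuc:
    def test_hand_example_four_pairs(self):
        auc, _ = roc_auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(3 / 4)

    def test_all_ties_half(self):
        auc, _ = roc_auc([1.0] * 10, [1] * 4 + [0] * 6)
        assert auc == pytest.approx(0.5)

    def test_perfect_separation_one(self):
        auc, points = roc_auc([3, 2, 1, 0], [1, 1, 0, 0])
        assert auc == 1.0
        assert points[0].tolist() == [0.0, 0.0] and points[-1].tolist() == [1.0, 1.0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_matches_brute_force_mann_whitney(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 50))
            scores = rng.choice([0.1, 0.2, 0.5, 0.9], size=n)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=max(1, n // 3), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


class TestCrossValidate:
    def test_folds_partition_and_stratify(self):
        rng = np.random.default_rng(2)
        docs = [["w"] if rng.random() < 0.3 else ["v"] for _ in range(200)]
        y = np.array([1 if d == ["w"] else 0 for d in docs])
        vocab = build_vocabulary(docs, nmax=1, min_doc_frac=0.0)
        X = featurize_corpus(docs, vocab)
        rep = cross_validate(X, y, k=10, seed=0)
        counts = np.bincount(rep.fold_assignment, minlength=10)
        assert counts.sum() == 200 and counts.min() >= 1
        for fold in range(10):
            pos = y[rep.fold_assignment == fold].sum()
            assert abs(pos - y.sum() / 10) <= 1  # integer-balanced stratification

    def test_shuffled_labels_give_chance_auc(self, clean_cohort):
        from paitraj.classifier import DEFAULT_LAMBDA_GRID

        docs = [tokenize(r.text) for r in clean_cohort.essays]
        vocab = build_vocabulary(docs)
        X = featurize_corpus(docs, vocab)
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(3):
            y = rng.permutation(clean_cohort.gold_labels["active01"].to_numpy())
            rep = cross_validate(X, y, k=10, seed=0, lam_grid=(0.01, 0.1), inner_k=3)
            aucs.append(rep.auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)

    def test_leave_one_out_covers_every_document(self):
        docs = [["w"]] * 6 + [["v"]] * 6
        y = np.array([1] * 6 + [0] * 6)
        vocab = build_vocabulary(docs, nmax=1, min_doc_frac=0.0)
        X = featurize_corpus(docs, vocab)
        rep = cross_validate(X, y, k=6, seed=0, inner_k=2, lam_grid=(0.01,))
        assert len(np.unique(rep.fold_assignment)) == 6

    def test_small_class_reduces_k_with_warning(self):
        docs = [["w"]] * 4 + [["v"]] * 40
        y = np.array([1] * 4 + [0] * 40)
        vocab = build_vocabulary(docs, nmax=1, min_doc_frac=0.0)
        X = featurize_corpus(docs, vocab)
        with pytest.warns(UserWarning, match="reducing k"):
            rep = cross_validate(X, y, k=10, seed=0, inner_k=2, lam_grid=(0.01,))
        assert rep.k == 4
        with pytest.raises(ValueError):
            cross_validate(X, y, k=10, seed=0, strict=True)


class TestPredictCorpus:
    def test_vocabulary_mismatch_rejected(self, clean_cohort):
        docs = [tokenize(r.text) for r in clean_cohort.essays[:50]]
        vocab1 = build_vocabulary(docs, min_doc_frac=0.02)
        vocab2 = build_vocabulary(docs, min_doc_frac=0.5)
        X = featurize_corpus(docs, vocab1)
        y = clean_cohort.gold_labels["active01"].to_numpy()[:50]
        clf = train(X, y, lam=0.01, vocab=vocab1)
        with pytest.raises(ValueError, match="vocabulary mismatch"):
            predict_corpus(clf, docs, vocab2)

    def test_token_order_invariance(self):
        docs = [["a", "b", "c"], ["x", "y", "z"]] * 20
        y = np.array([1, 0] * 20)
        vocab = build_vocabulary(docs, nmax=1, min_doc_frac=0.0)
        X = featurize_corpus(docs, vocab)
        clf = train(X, y, lam=0.01, vocab=vocab)
        p1 = predict_corpus(clf, [["a", "b", "c"]], vocab)
        p2 = predict_corpus(clf, [["c", "a", "b"]], vocab)
        assert p1.iloc[0] == p2.iloc[0]

    def test_all_zero_vector_decided_by_intercept(self):
        docs = [["a"]] * 30 + [["b"]] * 70
        y = np.array([1] * 30 + [0] * 70)
        vocab = build_vocabulary(docs, nmax=1, min_doc_frac=0.0)
        X = featurize_corpus(docs, vocab)
        clf = train(X, y, lam=0.01, vocab=vocab)
        pred = predict_corpus(clf, [["unseen", "tokens"]], vocab).iloc[0]
        assert pred == int(clf.intercept > 0)

    def test_heldout_predictions_equal_gold_on_clean_corpus(self, clean_cohort):
        docs = [tokenize(r.text) for r in clean_cohort.essays]
        vocab = build_vocabulary(docs)
        X = featurize_corpus(docs, vocab)
        y = clean_cohort.gold_labels["active01"].to_numpy()
        clf = train(X[:400], y[:400], lam=0.001, vocab=vocab)
        preds = clf.predict(X[400:])
        assert (preds == y[400:]).mean() >= 0.98


class TestLexiconBaseline:
    def test_generator_aligned_lexicon_is_perfect(self, clean_cohort):
        from paitraj.simulate import ACTIVE_LEXICON

        preds = lexicon_baseline(clean_cohort.essays, ACTIVE_LEXICON)
        gold = clean_cohort.gold_labels["active01"]
        table = compare_predictions(preds, preds, gold)
        assert table.loc["lexicon", "sensitivity"] == 1.0
        assert table.loc["lexicon", "specificity"] == 1.0

    def test_absent_lexicon_predicts_all_zero(self, clean_cohort):
        preds = lexicon_baseline(clean_cohort.essays, ["zzzunseen"])
        assert preds.sum() == 0

    def test_ambiguous_word_hurts_lexicon_but_not_classifier(self):
        # "play" appears in active ("play tennis") and non-active
        # ("watch them play on television") contexts
        rng = np.random.default_rng(4)
        docs, gold = [], []
        for _ in range(1000):
            if rng.random() < 0.4:
                docs.append(["i", "will", "play", "tennis", "every", "week"])
                gold.append(1)
            elif rng.random() < 0.5:
                docs.append(["i", "watch", "them", "play", "on", "television"])
                gold.append(0)
            else:
                docs.append(["my", "home", "will", "be", "warm"])
                gold.append(0)
        gold = np.array(gold)
        vocab = build_vocabulary(docs, nmax=3, min_doc_frac=0.02)
        X = featurize_corpus(docs, vocab)
        clf = train(X, gold, lam=0.01, vocab=vocab)
        model_preds = clf.predict(X)
        lex_preds = lexicon_baseline(docs, ["play"])
        table = compare_predictions(model_preds, lex_preds, gold)
        assert table.loc["lexicon", "specificity"] < table.loc["classifier", "specificity"]
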