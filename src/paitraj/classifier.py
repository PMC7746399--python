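"""Binary n-gram features and the L1-penalized linear classifier for PAI.

Each essay is represented as a bag of 1-3-grams, encoded as binary
presence/absence (relative frequencies are unstable for short documents).
The vocabulary keeps only n-grams occurring in at least a fixed fraction of
essays (default 2%).  Separate classifiers are trained for the "active" and
"spectator" codes: linear large-margin classifiers with an L1 ("lasso")
penalty, so the fitted weight vector is sparse and the surviving n-grams act
as a learned lexicon.

The solver is liblinear via scikit-learn; with an L1 penalty liblinear uses
the squared hinge loss.  The penalty is parameterized as lambda with the
per-observation scaling

    minimize  lambda * ||w||_1  +  (1/n) * sum_i  max(0, 1 - y_i s_i)^2

so duplicating every training row leaves the solution unchanged.  lambda is
selected by inner cross-validation on the training folds only; ties break
toward the larger lambda (sparser model).

Evaluation: stratified k-fold cross-validation with pooled held-out accuracy
and the ROC/AUC; AUC is the normalized Mann-Whitney U (probability a random
positive outranks a random negative, ties counted 1/2).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .corpus import EssayRecord, tokenize

__all__ = [
    "NGramVocabulary",
    "LinearClassifier",
    "CVReport",
    "build_vocabulary",
    "featurize",
    "featurize_corpus",
    "train",
    "cross_validate",
    "roc_auc",
    "predict_corpus",
    "lexicon_baseline",
    "compare_predictions",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(10.0 ** np.arange(-3.0, 2.5, 0.5))


def _doc_ngrams(tokens: Sequence[str], nmax: int) -> set[tuple[str, ...]]:
    toks = tuple(tokens)
    return {toks[i : i + n] for n in range(1, nmax + 1) for i in range(len(toks) - n + 1)}


@dataclass(frozen=True)
class NGramVocabulary:
    """Deterministically (lexicographically) ordered n-gram vocabulary."""

    ngrams: tuple[tuple[str, ...], ...]
    nmax: int
    min_doc_frac: float
    n_docs: int

    def __len__(self) -> int:
        return len(self.ngrams)

    @property
    def index(self) -> dict[tuple[str, ...], int]:
        return {g: j for j, g in enumerate(self.ngrams)}

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for g in self.ngrams:
            h.update(" ".join(g).encode() + b"\n")
        return h.hexdigest()[:16]


def build_vocabulary(
    token_docs: Sequence[Sequence[str]], nmax: int = 3, min_doc_frac: float = 0.02
) -> NGramVocabulary:
    """All 1..nmax-grams occurring in >= ceil(min_doc_frac * n_docs) documents."""
    if len(token_docs) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    threshold = max(1, math.ceil(min_doc_frac * len(token_docs)))
    df: dict[tuple[str, ...], int] = {}
    for toks in token_docs:
        for g in _doc_ngrams(toks, nmax):
            df[g] = df.get(g, 0) + 1
    kept = sorted(g for g, c in df.items() if c >= threshold)
    return NGramVocabulary(tuple(kept), nmax, min_doc_frac, len(token_docs))


def featurize(tokens: Sequence[str], vocab: NGramVocabulary) -> np.ndarray:
    """Binary presence vector of the vocabulary's n-grams in one document."""
    present = _doc_ngrams(tokens, vocab.nmax)
    return np.fromiter((g in present for g in vocab.ngrams), dtype=np.int8, count=len(vocab))


def featurize_corpus(token_docs: Sequence[Sequence[str]], vocab: NGramVocabulary) -> sparse.csr_matrix:
    """Sparse documents x vocabulary binary feature matrix."""
    index = vocab.index
    indptr, indices = [0], []
    for toks in token_docs:
        cols = sorted(index[g] for g in _doc_ngrams(toks, vocab.nmax) if g in index)
        indices.extend(cols)
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.float64)
    return sparse.csr_matrix(
        (data, indices, indptr), shape=(len(token_docs), len(vocab))
    )


@dataclass
class LinearClassifier:
    """Sparse linear decision rule over an n-gram vocabulary.

    score = intercept + w . x ; prediction = 1 iff score > 0.
    """

    weights: np.ndarray
    intercept: float
    lam: float
    target: str
    vocab_hash: str

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    def decision_scores(self, X: sparse.spmatrix | np.ndarray) -> np.ndarray:
        return np.asarray(X @ self.weights).ravel() + self.intercept

    def predict(self, X: sparse.spmatrix | np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) > 0).astype(int)

    def save(self, vocab: NGramVocabulary, csv_path: str | Path, header_path: str | Path) -> None:
        pd.DataFrame(
            {"ngram": [" ".join(g) for g in vocab.ngrams], "weight": self.weights}
        ).to_csv(csv_path, index=False)
        Path(header_path).write_text(
            json.dumps(
                {
                    "intercept": self.intercept,
                    "lambda": self.lam,
                    "target": self.target,
                    "vocab_hash": self.vocab_hash,
                },
                indent=2,
                sort_keys=True,
            )
        )


def train(
    X: sparse.spmatrix | np.ndarray,
    y: Sequence[int],
    lam: float = 0.01,
    target: str = "active",
    vocab: NGramVocabulary | None = None,
    tol: float = 1e-6,
) -> LinearClassifier:
    """Fit the L1-penalized linear classifier at penalty ``lam``."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"training labels contain a single class ({classes.tolist()}); "
            "a classifier needs both positive and negative examples"
        )
    n = X.shape[0]
    C = 1.0 / (lam * n)  # per-observation penalty scaling
    svc = LinearSVC(
        penalty="l1", loss="squared_hinge", dual=False, C=C, tol=tol, max_iter=50000,
        random_state=0,  # liblinear shuffles coordinates; pin for determinism
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        svc.fit(X, y)
    return LinearClassifier(
        weights=svc.coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        lam=lam,
        target=target,
        vocab_hash=vocab.content_hash() if vocab is not None else "",
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, np.ndarray]:
    """AUC (Mann-Whitney identity, ties = 1/2) and the ROC polyline.

    Returns (auc, points) with points an (m, 2) array of (FPR, TPR) pairs
    swept over all decision thresholds.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(labels)
    n1 = int(t.sum())
    n0 = len(t) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both positive and negative labels")
    ranks = rankdata(s)  # average ranks for ties
    auc = (ranks[t == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    order = np.argsort(-s, kind="stable")
    sorted_t = t[order]
    sorted_s = s[order]
    distinct = np.r_[np.diff(sorted_s) != 0, True]
    tps = np.cumsum(sorted_t)[distinct]
    fps = np.cumsum(1 - sorted_t)[distinct]
    points = np.column_stack([np.r_[0, fps / n0], np.r_[0, tps / n1]])
    return float(auc), points


@dataclass
class CVReport:
    """Stratified k-fold cross-validation report for one target label."""

    target: str
    k: int
    fold_assignment: np.ndarray
    fold_accuracies: list[float]
    pooled_accuracy: float
    mean_fold_accuracy: float
    auc: float
    roc_points: np.ndarray = field(repr=False)
    selected_lambdas: list[float] = field(default_factory=list)
    pooled_scores: np.ndarray = field(default=None, repr=False)
    pooled_predictions: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "k": self.k,
            "fold_accuracies": [round(a, 10) for a in self.fold_accuracies],
            "pooled_accuracy": round(self.pooled_accuracy, 10),
            "mean_fold_accuracy": round(self.mean_fold_accuracy, 10),
            "auc": round(self.auc, 10),
            "selected_lambdas": self.selected_lambdas,
        }


def _select_lambda(X, y, lam_grid, inner_k, seed) -> float:
    """Inner-CV accuracy over the grid; ties broken toward larger lambda."""
    inner_k = min(inner_k, int(np.bincount(y).min()))
    if inner_k < 2:
        return max(lam_grid)
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    best_lam, best_acc = None, -1.0
    for lam in sorted(lam_grid):
        correct = 0
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2:
                continue
            clf = train(X[tr], y[tr], lam=lam)
            correct += int((clf.predict(X[te]) == y[te]).sum())
        acc = correct / len(y)
        if acc >= best_acc:  # >= : later (larger) lambda wins ties
            best_acc, best_lam = acc, lam
    return best_lam


def cross_validate(
    X: sparse.spmatrix | np.ndarray,
    y: Sequence[int],
    k: int = 10,
    lam_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
    target: str = "active",
    inner_k: int = 5,
    strict: bool = False,
) -> CVReport:
    """Stratified k-fold CV with per-fold inner lambda selection.

    The penalty is chosen on the training portion of each fold only; the
    held-out fold contributes pooled predictions and decision scores.  If the
    rarer class has fewer than k members, k is reduced with a warning (or an
    error when ``strict``).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("cross_validate requires both classes present in y")
    min_class = int(np.bincount(y).min())
    if min_class < k:
        msg = f"smallest class has {min_class} members < k={k}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + "; reducing k", stacklevel=2)
        k = min_class
    if X.shape[0] < k:
        raise ValueError("need at least k documents")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    preds = np.empty(len(y), dtype=int)
    fold_accs, lambdas = [], []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_assignment[te] = fold
        lam = _select_lambda(X[tr], y[tr], lam_grid, inner_k, seed + fold + 1)
        clf = train(X[tr], y[tr], lam=lam, target=target)
        lambdas.append(lam)
        scores[te] = clf.decision_scores(X[te])
        preds[te] = (scores[te] > 0).astype(int)
        fold_accs.append(float((preds[te] == y[te]).mean()))
    auc, points = roc_auc(scores, y)
    return CVReport(
        target=target,
        k=k,
        fold_assignment=fold_assignment,
        fold_accuracies=fold_accs,
        pooled_accuracy=float((preds == y).mean()),
        mean_fold_accuracy=float(np.mean(fold_accs)),
        auc=auc,
        roc_points=points,
        selected_lambdas=lambdas,
        pooled_scores=scores,
        pooled_predictions=preds,
    )


def predict_corpus(
    model: LinearClassifier,
    corpus: Sequence[EssayRecord] | Sequence[Sequence[str]],
    vocab: NGramVocabulary,
) -> pd.Series:
    """Binary predictions for every essay (all-zero vectors decided by the intercept)."""
    if model.vocab_hash and model.vocab_hash != vocab.content_hash():
        raise ValueError("vocabulary mismatch: model was trained against a different vocabulary")
    if corpus and isinstance(corpus[0], EssayRecord):
        ids = [r.person_id for r in corpus]
        token_docs = [tokenize(r.text) for r in corpus]
    else:
        ids = list(range(len(corpus)))
        token_docs = list(corpus)
    X = featurize_corpus(token_docs, vocab)
    return pd.Series(model.predict(X), index=ids, name=f"{model.target}01")


def lexicon_baseline(
    corpus: Sequence[EssayRecord] | Sequence[Sequence[str]], lexicon: Sequence[str]
) -> pd.Series:
    """Manual-lexicon rule: predict 1 iff any lexicon phrase occurs in the essay."""
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    phrases = [tuple(tokenize(p)) for p in lexicon]
    nmax = max(len(p) for p in phrases)
    if corpus and isinstance(corpus[0], EssayRecord):
        ids = [r.person_id for r in corpus]
        token_docs = [tokenize(r.text) for r in corpus]
    else:
        ids = list(range(len(corpus)))
        token_docs = list(corpus)
    out = []
    for toks in token_docs:
        grams = _doc_ngrams(toks, nmax)
        out.append(int(any(p in grams for p in phrases)))
    return pd.Series(out, index=ids, name="lexicon01")


def compare_predictions(
    model_preds: Sequence[int], lexicon_preds: Sequence[int], gold: Sequence[int]
) -> pd.DataFrame:
    """Sensitivity/specificity of the classifier and the lexicon rule vs gold."""
    gold = np.asarray(gold)

    def _sens_spec(pred):
        pred = np.asarray(pred)
        pos, neg = gold == 1, gold == 0
        sens = float((pred[pos] == 1).mean()) if pos.any() else float("nan")
        spec = float((pred[neg] == 0).mean()) if neg.any() else float("nan")
        acc = float((pred == gold).mean())
        return sens, spec, acc

    rows = {"classifier": _sens_spec(model_preds), "lexicon": _sens_spec(lexicon_preds)}
    return pd.DataFrame(rows, index=["sensitivity", "specificity", "accuracy"]).T
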