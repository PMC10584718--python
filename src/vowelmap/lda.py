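"""Gaussian linear discriminant classification of vowel tokens.

The classifier models each L1 vowel category as a multivariate Gaussian
with its own mean and a covariance matrix pooled across categories (the
within-class scatter divided by n − k).  With uniform priors the posterior
is the softmax of the linear discriminant scores

    delta_k(x) = x' S^-1 m_k − 1/2 m_k' S^-1 m_k + log pi_k,

and a token is assigned to the argmax category.  Feeding target-language
tokens to a model trained on L1 tokens yields a machine confusion matrix:
the acoustic-similarity counterpart of a listener classification test.

Feature relevance is assessed by forward stepwise selection on Wilks'
lambda (the ratio of within-group to total scatter, smaller = better group
separation): at each step the candidate that minimizes the partial lambda
enters if its F-to-enter is significant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .core_io import FEATURES, ValidationError, VowelToken, design_matrix
from .upm import ConfusionMatrix

log = logging.getLogger(__name__)

_TIE_TOL = 1e-9


@dataclass
class LDAModel:
    """A trained pooled-covariance Gaussian classifier.

    ``classes`` fixes the canonical category order used for argmax
    tie-breaking; ``means`` is (k, p); ``cov`` the pooled (p, p) covariance
    with denominator n − k; ``priors`` sums to 1.
    """

    classes: tuple[str, ...]
    features: tuple[str, ...]
    means: np.ndarray
    cov: np.ndarray
    priors: np.ndarray
    n_train: int

    def __post_init__(self) -> None:
        if abs(float(self.priors.sum()) - 1.0) > 1e-9:
            raise ValidationError("priors must sum to 1")
        try:
            np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "pooled covariance is not positive-definite; reduce or "
                "decorrelate the feature set") from exc

    # -- scoring ----------------------------------------------------------

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant scores delta_k(x), shape (n, k)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        icov = np.linalg.inv(self.cov)
        A = self.means @ icov                       # (k, p)
        b = (-0.5 * np.einsum("kp,kp->k", A, self.means)
             + np.log(self.priors))
        return X @ A.T + b

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        """Posterior category probabilities; rows sum to 1."""
        s = self.decision_scores(X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray,
                return_ties: bool = False):
        """Argmax-posterior labels; ties broken by canonical class order."""
        s = self.decision_scores(X)
        idx = s.argmax(axis=1)
        labels = np.array(self.classes, dtype=object)[idx]
        if not return_ties:
            return labels
        top = s[np.arange(len(s)), idx]
        tie = (np.abs(s - top[:, None]) < _TIE_TOL).sum(axis=1) > 1
        return labels, tie

    def predict_tokens(self, tokens: Sequence[VowelToken],
                       return_ties: bool = False):
        X, _ = design_matrix(tokens, self.features)
        return self.predict(X, return_ties=return_ties)

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "classes": list(self.classes),
            "features": list(self.features),
            "means": self.means.tolist(),
            "cov": self.cov.tolist(),
            "priors": self.priors.tolist(),
            "n_train": self.n_train,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=2)

    @classmethod
    def from_json(cls, path) -> "LDAModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            classes=tuple(d["classes"]), features=tuple(d["features"]),
            means=np.array(d["means"], float), cov=np.array(d["cov"], float),
            priors=np.array(d["priors"], float), n_train=int(d["n_train"]))


def _class_order(y: np.ndarray) -> tuple[str, ...]:
    """Categories in order of first appearance (the canonical order of the
    training table)."""
    seen: list[str] = []
    for label in y:
        if label not in seen:
            seen.append(label)
    return tuple(seen)


def _fit(X: np.ndarray, y: np.ndarray,
         classes: tuple[str, ...], priors: str | np.ndarray,
         features: tuple[str, ...], check: bool = True) -> LDAModel:
    n, p = X.shape
    k = len(classes)
    means = np.empty((k, p))
    W = np.zeros((p, p))
    for i, c in enumerate(classes):
        Xi = X[y == c]
        if check and len(Xi) < 2:
            raise ValidationError(
                f"category {c!r} has fewer than 2 tokens")
        means[i] = Xi.mean(axis=0)
        D = Xi - means[i]
        W += D.T @ D
    if check and n <= p + k - 1:
        raise ValidationError(
            f"need more tokens ({n}) than features plus classes to pool a "
            "covariance")
    cov = W / (n - k)
    if priors == "uniform":
        pr = np.full(k, 1.0 / k)
    elif priors == "empirical":
        pr = np.array([(y == c).mean() for c in classes])
    else:
        pr = np.asarray(priors, dtype=float)
    return LDAModel(classes=classes, features=features, means=means,
                    cov=cov, priors=pr, n_train=n)


def train_lda(
        tokens: Sequence[VowelToken],
        features: Sequence[str] = FEATURES,
        priors: str | np.ndarray = "uniform",
) -> LDAModel:
    """Train on token-level data; deterministic given input order."""
    features = tuple(features)
    X, y = design_matrix(tokens, features)
    classes = _class_order(y)
    if len(classes) < 2:
        raise ValidationError("need at least 2 categories to train")
    return _fit(X, y, classes, priors, features)


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

def _loo_accuracy_xy(X: np.ndarray, y: np.ndarray,
                     classes: tuple[str, ...],
                     features: tuple[str, ...]) -> float:
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = _fit(X[mask], y[mask], classes, "uniform", features,
                     check=False)
        correct += int(model.predict(X[i:i + 1])[0] == y[i])
    return correct / n


def loo_cv_accuracy(
        tokens: Sequence[VowelToken],
        features: Sequence[str] = FEATURES,
) -> float:
    """Leave-one-out accuracy: each token predicted by a model trained on
    all other tokens.  Deterministic given the data."""
    features = tuple(features)
    X, y = design_matrix(tokens, features)
    classes = _class_order(y)
    if len(classes) < 2:
        raise ValidationError("need at least 2 categories")
    return _loo_accuracy_xy(X, y, classes, features)


# ---------------------------------------------------------------------------
# Cross-language classification
# ---------------------------------------------------------------------------

def classify_proportions(
        model: LDAModel,
        l2_tokens: Sequence[VowelToken],
        expected_vowels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Per target-language vowel, the share of its tokens assigned to each
    L1 category by hard argmax; rows sum to 1."""
    if not l2_tokens:
        raise ValidationError("no target-language tokens to classify")
    by_vowel: dict[str, list[VowelToken]] = {}
    for t in l2_tokens:
        by_vowel.setdefault(t.vowel, []).append(t)
    if expected_vowels is not None:
        missing = [v for v in expected_vowels if v not in by_vowel]
        if missing:
            raise ValidationError(
                f"no tokens for target vowel(s) {missing}")
    rows: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    tie_rows = set()
    for vowel, group in by_vowel.items():
        labels, ties = model.predict_tokens(group, return_ties=True)
        if ties.any():
            tie_rows.add(vowel)
            log.warning("argmax ties for %d token(s) of %r; broken by "
                        "canonical category order", int(ties.sum()), vowel)
        rows[vowel] = {c: float((labels == c).mean())
                       for c in model.classes}
        counts[vowel] = len(group)
    matrix = ConfusionMatrix.from_rows(
        rows, categories=model.classes, source="acoustic",
        row_counts=counts)
    matrix.tie_rows = frozenset(tie_rows)
    return matrix


# ---------------------------------------------------------------------------
# Wilks'-lambda forward stepwise selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepwiseStep:
    index: int
    feature: str
    wilks_lambda: float
    f_to_enter: float
    df1: int
    df2: int
    p_value: float
    cv_accuracy: float


@dataclass
class StepwiseTrace:
    """Ordered record of the features entered by forward selection."""

    steps: list[StepwiseStep] = field(default_factory=list)
    alpha: float = 0.05
    diagnostics: list[str] = field(default_factory=list)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(s.feature for s in self.steps)

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "steps": [s.__dict__ for s in self.steps],
            "diagnostics": self.diagnostics,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=2)


def wilks_lambda(X: np.ndarray, y: np.ndarray,
                 classes: Sequence[str]) -> float:
    """Lambda = det(W) / det(T): within-group over total scatter."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for c in classes:
        Xi = X[y == c]
        D = Xi - Xi.mean(axis=0)
        W += D.T @ D
    sign_w, logdet_w = np.linalg.slogdet(np.atleast_2d(W))
    sign_t, logdet_t = np.linalg.slogdet(np.atleast_2d(T))
    if sign_w <= 0 or sign_t <= 0:
        raise ValidationError(
            "singular scatter matrix; features are collinear")
    return float(np.exp(logdet_w - logdet_t))


def wilks_stepwise(
        tokens: Sequence[VowelToken],
        candidates: Sequence[str] = FEATURES,
        alpha: float = 0.05,
) -> StepwiseTrace:
    """Forward selection minimizing the partial Wilks' lambda.

    At each step the candidate with the smallest partial lambda enters if
    its F-to-enter (df1 = k − 1, df2 = n − k − p, p = features already in)
    has p < alpha.  The trace records the model's leave-one-out accuracy at
    every step.  Removal steps are not performed (pure forward selection).
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    candidates = list(candidates)
    X_all, y = design_matrix(tokens, candidates)
    classes = _class_order(y)
    k, n = len(classes), len(y)
    if k < 2:
        raise ValidationError("need at least 2 categories")

    trace = StepwiseTrace(alpha=alpha)
    selected: list[int] = []
    current_lambda = 1.0
    while len(selected) < len(candidates):
        p = len(selected)
        df1, df2 = k - 1, n - k - p
        if df2 <= 0:
            trace.diagnostics.append(
                "denominator degrees of freedom exhausted")
            break
        best: tuple[float, int] | None = None
        for j in range(len(candidates)):
            if j in selected:
                continue
            try:
                lam = wilks_lambda(X_all[:, selected + [j]], y, classes)
            except ValidationError:
                continue  # collinear with the selected set
            if best is None or lam < best[0]:
                best = (lam, j)
        if best is None:
            trace.diagnostics.append(
                "all remaining candidates are collinear with the "
                "selected set")
            break
        lam, j = best
        partial = lam / current_lambda
        if partial >= 1.0:
            f_stat, p_value = 0.0, 1.0
        else:
            f_stat = (df2 / df1) * (1.0 - partial) / partial
            p_value = float(sps.f.sf(f_stat, df1, df2))
        if p_value >= alpha:
            if not trace.steps:
                trace.diagnostics.append(
                    f"no candidate qualifies at step 1 (best "
                    f"{candidates[j]!r}: F = {f_stat:.3f}, "
                    f"p = {p_value:.3f})")
            break
        selected.append(j)
        feats = tuple(candidates[i] for i in selected)
        cv = _loo_accuracy_xy(X_all[:, selected], y, classes, feats)
        trace.steps.append(StepwiseStep(
            index=len(selected), feature=candidates[j], wilks_lambda=lam,
            f_to_enter=f_stat, df1=df1, df2=df2, p_value=p_value,
            cv_accuracy=cv))
        current_lambda = lam
    return trace
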