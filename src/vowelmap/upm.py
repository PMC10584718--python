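"""The Universal Perceptual Model (UPM) prediction engine.

UPM predicts how well listeners discriminate a non-native vowel contrast
from how the two contrast members are classified in terms of L1 categories.
Only *above-chance* classifications matter: a response category counts if
its classification proportion meets the chance score (1 / number of
response categories, inclusive).  The two members' above-chance sets then
determine the *overlap degree*:

* **complete** — identical above-chance sets;
* **partial**  — the sets share at least one category but differ;
* **none**     — disjoint sets.

Non-overlapping contrasts are predicted to be the most discriminable
("good"), partially overlapping contrasts "moderate-to-good", and
completely overlapping contrasts "poor" — unless listeners perceive a
phonetic distance between the members, operationalized as a significant
difference in goodness-of-fit ratings for the shared category, in which
case discrimination is upgraded to "moderate-to-good".

The engine is agnostic about where the confusion matrix comes from: a
machine classifier over acoustic measurements (acoustic similarity) or a
human classification experiment (perceptual similarity) both work.  The
classification overlap *score* (sum over shared categories of the smaller
classification percentage) quantifies overlap on a 0–100 scale.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import ValidationError, format_contrast

log = logging.getLogger(__name__)

#: Discrimination tiers, worst to best.
TIERS: tuple[str, ...] = ("poor", "moderate-to-good", "good")
TIER_ORDER: Mapping[str, int] = {t: i for i, t in enumerate(TIERS)}

#: Overlap degrees.  "uncategorized" marks a member with an empty
#: above-chance set; the degree lattice is defined only over non-empty sets.
DEGREES: tuple[str, ...] = ("complete", "partial", "none", "uncategorized")

_ABOVE_CHANCE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Confusion matrix container
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Stimulus x response-category classification proportions.

    Rows are stimulus vowels, columns L1 response categories; each row sums
    to 1.  ``source`` tags the provenance ("acoustic" for machine
    classification, "perceptual" for listener data); ``row_counts`` keeps
    the number of trials behind each row; ``tie_rows`` flags stimuli whose
    machine classification involved an argmax tie.
    """

    data: pd.DataFrame
    source: str = "perceptual"
    row_counts: dict[str, int] | None = None
    tie_rows: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        arr = self.data.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValidationError("confusion proportions must be >= 0")
        sums = arr.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValidationError(
                f"confusion rows must sum to 1; offending stimuli: "
                f"{[self.data.index[i] for i in bad]}")

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def row(self, stimulus: str) -> dict[str, float]:
        if stimulus not in self.data.index:
            raise ValidationError(
                f"no confusion row for stimulus {stimulus!r}")
        return {c: float(v) for c, v in self.data.loc[stimulus].items()}

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "stimulus"
        out.to_csv(path, encoding="utf-8")

    @classmethod
    def from_csv(cls, path, source: str = "perceptual") -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0, encoding="utf-8")
        return cls(data=df.astype(float), source=source)

    @classmethod
    def from_rows(cls, rows: Mapping[str, Mapping[str, float]],
                  categories: Sequence[str] | None = None,
                  source: str = "perceptual",
                  row_counts: dict[str, int] | None = None,
                  ) -> "ConfusionMatrix":
        if categories is None:
            seen: list[str] = []
            for r in rows.values():
                for c in r:
                    if c not in seen:
                        seen.append(c)
            categories = seen
        df = pd.DataFrame(
            [[float(r.get(c, 0.0)) for c in categories] for r in rows.values()],
            index=list(rows), columns=list(categories))
        return cls(data=df, source=source, row_counts=row_counts)


# ---------------------------------------------------------------------------
# Atomic UPM operations
# ---------------------------------------------------------------------------

def chance_score(n_categories: int) -> float:
    """1 divided by the number of response categories."""
    if n_categories < 1:
        raise ValidationError(
            f"need at least one response category, got {n_categories}")
    return 1.0 / n_categories


def above_chance_set(
        row: Mapping[str, float], threshold: float) -> frozenset[str]:
    """Categories whose proportion meets the threshold (inclusive)."""
    return frozenset(
        c for c, p in row.items() if p >= threshold - _ABOVE_CHANCE_TOL)


def overlap_degree(set_a: frozenset[str] | set,
                   set_b: frozenset[str] | set) -> str:
    """Overlap degree of two above-chance sets.

    An empty set means the stimulus was not categorized; that is reported
    as its own outcome rather than silently collapsed onto "none".
    """
    set_a, set_b = frozenset(set_a), frozenset(set_b)
    if not set_a or not set_b:
        return "uncategorized"
    if set_a == set_b:
        return "complete"
    if set_a & set_b:
        return "partial"
    return "none"


def overlap_score(row_a: Mapping[str, float],
                  row_b: Mapping[str, float]) -> float:
    """Classification overlap score, percent.

    Sums, over every L1 category shared by the two classification rows, the
    smaller of the two classification percentages.  All shared categories
    contribute, including below-chance ones.  Symmetric; 100 iff the rows
    are identical, 0 iff their supports are disjoint.
    """
    cats = set(row_a) | set(row_b)
    return 100.0 * sum(
        min(row_a.get(c, 0.0), row_b.get(c, 0.0)) for c in cats)


@dataclass(frozen=True)
class PerceivedDistance:
    """Result of the goodness-rating (perceived phonetic distance) test."""

    t: float
    df: int
    p: float
    significant: bool
    mean_a: float
    mean_b: float


def perceived_distance_test(
        ratings_a: Sequence[float], ratings_b: Sequence[float],
        alpha: float = 0.05) -> PerceivedDistance:
    """Pooled-variance (Student) two-sample t-test on goodness ratings.

    A significant difference means listeners heard the two contrast members
    as unequally good exemplars of the shared L1 category, i.e. they
    perceive a phonetic distance.  df = n1 + n2 - 2.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError(
            "need at least 2 ratings per group for the t-test")
    df = a.size + b.size - 2
    pooled_var = (((a.size - 1) * a.var(ddof=1)
                   + (b.size - 1) * b.var(ddof=1)) / df)
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return PerceivedDistance(0.0, df, 1.0, False,
                                     float(a.mean()), float(b.mean()))
        warnings.warn(
            "zero pooled variance with unequal means; reporting an "
            "infinite-t sentinel", stacklevel=2)
        return PerceivedDistance(math.inf, df, 0.0, True,
                                 float(a.mean()), float(b.mean()))
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return PerceivedDistance(float(t), df, float(p), bool(p < alpha),
                             float(a.mean()), float(b.mean()))


# ---------------------------------------------------------------------------
# Contrast analysis and tier prediction
# ---------------------------------------------------------------------------

@dataclass
class OverlapAnalysis:
    """UPM analysis of one non-native contrast."""

    contrast: tuple[str, str]
    set_a: frozenset[str]
    set_b: frozenset[str]
    degree: str
    score: float
    perceived_distance: PerceivedDistance | None = None
    feature_overlap: dict[str, str] | None = None
    predicted_tier: str | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.degree != overlap_degree(self.set_a, self.set_b):
            raise ValidationError(
                f"degree {self.degree!r} inconsistent with above-chance "
                f"sets {set(self.set_a)} / {set(self.set_b)}")
        if not 0.0 <= self.score <= 100.0 + 1e-9:
            raise ValidationError(
                f"overlap score must lie in [0, 100], got {self.score}")

    @property
    def label(self) -> str:
        return format_contrast(self.contrast)


def predict_tier(analysis: OverlapAnalysis) -> str:
    """Discrimination tier from overlap degree and perceived distance.

    none -> good; partial -> moderate-to-good; complete -> poor, upgraded
    to moderate-to-good when the perceived-distance test is significant.
    """
    if analysis.degree == "none":
        return "good"
    if analysis.degree == "partial":
        return "moderate-to-good"
    if analysis.degree == "complete":
        if analysis.perceived_distance is None:
            raise ValidationError(
                f"contrast {analysis.label}: complete overlap requires "
                "goodness-rating data for the perceived-distance test")
        return ("moderate-to-good"
                if analysis.perceived_distance.significant else "poor")
    raise ValidationError(
        f"contrast {analysis.label}: cannot assign a tier to an "
        "uncategorized member")


def analyze_contrast(
        matrix: ConfusionMatrix,
        contrast: tuple[str, str],
        threshold: float | None = None,
        ratings: tuple[Sequence[float], Sequence[float]] | None = None,
        alpha: float = 0.05,
        assign_tier: bool = True,
) -> OverlapAnalysis:
    """Compose the atomic operations for one contrast.

    ``ratings`` (one goodness-rating vector per member, restricted to
    trials that chose the shared above-chance category) is consulted only
    when the degree is complete.
    """
    if threshold is None:
        threshold = chance_score(len(matrix.categories))
    a, b = contrast
    row_a, row_b = matrix.row(a), matrix.row(b)
    set_a = above_chance_set(row_a, threshold)
    set_b = above_chance_set(row_b, threshold)
    degree = overlap_degree(set_a, set_b)
    analysis = OverlapAnalysis(
        contrast=tuple(contrast), set_a=set_a, set_b=set_b, degree=degree,
        score=overlap_score(row_a, row_b))
    if degree == "complete" and ratings is not None:
        analysis.perceived_distance = perceived_distance_test(
            ratings[0], ratings[1], alpha=alpha)
    if assign_tier:
        analysis.predicted_tier = predict_tier(analysis)
    return analysis


def shared_category(set_a: frozenset[str], set_b: frozenset[str],
                    row_a: Mapping[str, float],
                    row_b: Mapping[str, float]) -> str:
    """The shared above-chance category carrying the most joint weight."""
    shared = set_a & set_b
    if not shared:
        raise ValidationError("the above-chance sets share no category")
    return max(shared, key=lambda c: min(row_a[c], row_b[c]))


def acoustic_prediction(
        lda_matrix: ConfusionMatrix,
        stepwise,
        contrasts: Sequence[tuple[str, str]],
        feature_matrices: Mapping[str, ConfusionMatrix] | None = None,
        threshold: float | None = None,
) -> list[OverlapAnalysis]:
    """UPM analyses from a machine-classification matrix.

    The full-model matrix fixes degree and score.  For contrasts that
    completely overlap under the full model, single-feature matrices (one
    per feature entered by the stepwise selection, when given) provide a
    phonetic escape hatch: if the members separate — even partially — on an
    individual acoustic measure, listeners attending to that measure may
    discriminate them, so the tier is upgraded from poor to
    moderate-to-good.
    """
    if threshold is None:
        threshold = chance_score(len(lda_matrix.categories))
    features: Sequence[str]
    if stepwise is not None and getattr(stepwise, "features", None):
        features = list(stepwise.features)
    elif feature_matrices:
        features = list(feature_matrices)
    else:
        features = []
    analyses = []
    for contrast in contrasts:
        analysis = analyze_contrast(
            lda_matrix, contrast, threshold=threshold, assign_tier=False)
        if feature_matrices:
            per_feature: dict[str, str] = {}
            for f in features:
                if f not in feature_matrices:
                    continue
                fm = feature_matrices[f]
                thr = chance_score(len(fm.categories))
                per_feature[f] = overlap_degree(
                    above_chance_set(fm.row(contrast[0]), thr),
                    above_chance_set(fm.row(contrast[1]), thr))
            analysis.feature_overlap = per_feature
        if analysis.degree in ("none", "partial"):
            analysis.predicted_tier = predict_tier(analysis)
        elif analysis.degree == "complete":
            escapes = [f for f, d in (analysis.feature_overlap or {}).items()
                       if d in ("partial", "none")]
            if escapes:
                analysis.predicted_tier = "moderate-to-good"
                analysis.notes.append(
                    "complete overlap in the full model, but the members "
                    f"separate on individual measure(s) {escapes}; "
                    "listeners attending to these cues may discriminate")
            else:
                analysis.predicted_tier = "poor"
        else:
            analysis.predicted_tier = None
            analysis.notes.append(
                "a member has no above-chance category (uncategorized)")
        analyses.append(analysis)
    return analyses
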