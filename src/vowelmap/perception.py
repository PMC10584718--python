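"""Listener trial logs -> confusion matrices, goodness summaries, and
per-contrast AXB discrimination accuracies with above-chance tests.

The AXB above-chance test follows the per-listener convention: each
listener contributes one accuracy, and a one-sample t-test compares the
listener accuracies against the 0.5 chance level (df = n_listeners − 1).
Observed accuracies are mapped onto discrimination tiers through
configurable bands, since "moderate" vs "good" cut points are a reporting
convention rather than a theoretical constant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core_io import (
    AXBTrial,
    ClassificationResponse,
    ValidationError,
    format_contrast,
)
from .upm import ConfusionMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Classification responses -> confusion matrix / goodness
# ---------------------------------------------------------------------------

def confusion_from_responses(
        responses: Sequence[ClassificationResponse],
        categories: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Row(stimulus)[category] = count / total for that stimulus."""
    if not responses:
        raise ValidationError("no classification responses")
    by_stim: dict[str, list[ClassificationResponse]] = {}
    for r in responses:
        by_stim.setdefault(r.stimulus, []).append(r)
    if categories is None:
        seen: list[str] = []
        for r in responses:
            if r.choice not in seen:
                seen.append(r.choice)
        categories = seen
    rows: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    for stim, group in by_stim.items():
        n = len(group)
        rows[stim] = {c: sum(r.choice == c for r in group) / n
                      for c in categories}
        counts[stim] = n
    return ConfusionMatrix.from_rows(
        rows, categories=categories, source="perceptual", row_counts=counts)


@dataclass(frozen=True)
class GoodnessSummary:
    stimulus: str
    category: str
    mean: float
    n: int


def goodness_ratings(
        responses: Sequence[ClassificationResponse],
        stimulus: str, category: str) -> list[int]:
    """Goodness ratings of trials where ``stimulus`` was labelled
    ``category``."""
    return [r.goodness for r in responses
            if r.stimulus == stimulus and r.choice == category]


def goodness_summary(
        responses: Sequence[ClassificationResponse],
        stimulus: str, category: str) -> GoodnessSummary | None:
    """Mean goodness for one (stimulus, chosen category) cell; None when
    the cell is empty (distinct from a zero rating)."""
    ratings = goodness_ratings(responses, stimulus, category)
    if not ratings:
        return None
    return GoodnessSummary(stimulus=stimulus, category=category,
                           mean=float(np.mean(ratings)), n=len(ratings))


# ---------------------------------------------------------------------------
# AXB accuracy
# ---------------------------------------------------------------------------

@dataclass
class AXBResult:
    """Per-contrast discrimination accuracy with the above-chance test."""

    contrast: tuple[str, str]
    group: str | None
    n_trials: int
    n_correct: int
    accuracy: float
    per_listener: dict[str, float]
    t: float | None = None
    df: int | None = None
    p: float | None = None
    significant: bool | None = None

    @property
    def label(self) -> str:
        return format_contrast(self.contrast)


def axb_accuracy(
        trials: Sequence[AXBTrial],
        group: str | None = None,
        chance: float = 0.5,
        alpha: float = 0.05,
) -> list[AXBResult]:
    """Pooled and per-listener accuracy per contrast, with a one-sample
    t-test of the per-listener accuracies against chance.

    With a single listener the accuracy is still reported but the test is
    skipped with a warning.
    """
    if not trials:
        raise ValidationError("no AXB trials")
    by_contrast: dict[tuple[str, str], list[AXBTrial]] = {}
    for t in trials:
        by_contrast.setdefault(t.contrast, []).append(t)
    results = []
    for contrast, group_trials in by_contrast.items():
        by_listener: dict[str, list[AXBTrial]] = {}
        for t in group_trials:
            by_listener.setdefault(t.listener, []).append(t)
        per_listener = {
            lid: sum(t.correct for t in ts) / len(ts)
            for lid, ts in by_listener.items()}
        n_correct = sum(t.correct for t in group_trials)
        res = AXBResult(
            contrast=contrast, group=group, n_trials=len(group_trials),
            n_correct=n_correct,
            accuracy=n_correct / len(group_trials),
            per_listener=per_listener)
        accs = np.array(list(per_listener.values()), dtype=float)
        if accs.size < 2:
            warnings.warn(
                f"contrast {res.label}: single listener; above-chance "
                "test skipped", stacklevel=2)
        else:
            if accs.std(ddof=1) == 0.0:
                tstat = 0.0 if accs.mean() == chance else np.inf
                p = 1.0 if accs.mean() == chance else 0.0
            else:
                tstat, p = sps.ttest_1samp(accs, chance)
            res.t, res.p = float(tstat), float(p)
            res.df = accs.size - 1
            res.significant = bool(res.p < alpha)
        results.append(res)
    return results


def axb_accuracy_by_group(
        trials: Sequence[AXBTrial],
        groups: Mapping[str, str],
        chance: float = 0.5,
        alpha: float = 0.05,
) -> dict[str, list[AXBResult]]:
    """Split trials by listener group, then score each group."""
    split: dict[str, list[AXBTrial]] = {}
    for t in trials:
        if t.listener not in groups:
            raise ValidationError(
                f"listener {t.listener!r} has no group assignment")
        split.setdefault(groups[t.listener], []).append(t)
    return {g: axb_accuracy(ts, group=g, chance=chance, alpha=alpha)
            for g, ts in split.items()}


# ---------------------------------------------------------------------------
# Tier bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TierBands:
    """Accuracy cut points: poor <= poor_max < moderate-to-good <=
    moderate_max < good."""

    poor_max: float = 0.60
    moderate_max: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.poor_max < self.moderate_max < 1.0:
            raise ValidationError(
                f"bands must satisfy 0 < poor_max < moderate_max < 1, "
                f"got ({self.poor_max}, {self.moderate_max})")


DEFAULT_BANDS = TierBands()


def tier_from_accuracy(
        result: AXBResult | float,
        bands: TierBands = DEFAULT_BANDS) -> str:
    """Map a pooled AXB accuracy onto a discrimination tier."""
    acc = result.accuracy if isinstance(result, AXBResult) else float(result)
    if not 0.0 <= acc <= 1.0:
        raise ValidationError(f"accuracy must lie in [0, 1], got {acc}")
    if acc <= bands.poor_max:
        return "poor"
    if acc <= bands.moderate_max:
        return "moderate-to-good"
    return "good"
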