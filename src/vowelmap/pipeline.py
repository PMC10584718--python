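"""End-to-end orchestration of the two prediction arms.

The *acoustic* arm goes from raw production tokens to UPM analyses:
Lobanov normalization -> pseudo-Hz rescaling -> L1 LDA training (with a
Wilks'-lambda stepwise trace) -> machine classification of the target
language tokens -> overlap analysis.  The *perceptual* arm goes from a
listener classification log to the same analyses via the empirical
confusion matrix, with goodness-rating perceived-distance tests where a
contrast completely overlaps.  Observed AXB accuracies then adjudicate
both arms: a prediction "agrees" when its tier equals the tier of the
observed accuracy.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_io import (
    ClassificationResponse,
    StudyConfig,
    ValidationError,
    VowelToken,
    format_contrast,
)
from .acoustics import lobanov_normalize, rescale_to_hz
from .lda import (
    LDAModel,
    StepwiseTrace,
    classify_proportions,
    train_lda,
    wilks_stepwise,
)
from .perception import (
    AXBResult,
    TierBands,
    DEFAULT_BANDS,
    axb_accuracy,
    confusion_from_responses,
    goodness_ratings,
    tier_from_accuracy,
)
from .upm import (
    ConfusionMatrix,
    OverlapAnalysis,
    above_chance_set,
    acoustic_prediction,
    analyze_contrast,
    chance_score,
    overlap_degree,
    shared_category,
)

log = logging.getLogger(__name__)


def _stage(name: str, n_in: int, n_out: int) -> None:
    log.info("stage %-22s in=%d out=%d", name, n_in, n_out)


# ---------------------------------------------------------------------------
# Acoustic arm
# ---------------------------------------------------------------------------

@dataclass
class AcousticArm:
    """Everything the acoustic arm produced, for auditability."""

    analyses: list[OverlapAnalysis]
    model: LDAModel
    stepwise: StepwiseTrace
    confusion: ConfusionMatrix
    feature_confusions: dict[str, ConfusionMatrix]


def run_acoustic_arm(
        cg_tokens: Sequence[VowelToken],
        nl_tokens: Sequence[VowelToken],
        contrasts: Sequence[tuple[str, str]],
        config: StudyConfig | None = None,
        normalize: bool = True,
) -> AcousticArm:
    """Normalize -> rescale -> train -> stepwise -> classify -> UPM.

    ``normalize=False`` accepts tokens already on a common normalized
    scale (e.g. published summary values) and skips the speaker
    normalization stages.
    """
    config = config or StudyConfig()
    if normalize:
        cg_z, cg_state = lobanov_normalize(cg_tokens)
        cg_train = rescale_to_hz(cg_z, cg_state)
        _stage("normalize/rescale CG", len(cg_tokens), len(cg_train))
        nl_z, nl_state = lobanov_normalize(nl_tokens)
        nl_test = rescale_to_hz(nl_z, nl_state)
        _stage("normalize/rescale NL", len(nl_tokens), len(nl_test))
    else:
        cg_train, nl_test = list(cg_tokens), list(nl_tokens)

    model = train_lda(cg_train, features=config.features)
    _stage("train LDA", len(cg_train), len(model.classes))
    trace = wilks_stepwise(cg_train, candidates=config.features)
    _stage("stepwise selection", len(cg_train), len(trace.steps))

    confusion = classify_proportions(model, nl_test)
    _stage("classify NL tokens", len(nl_test), len(confusion.stimuli))

    feature_confusions: dict[str, ConfusionMatrix] = {}
    for feat in (trace.features or config.features):
        single = train_lda(cg_train, features=(feat,))
        feature_confusions[feat] = classify_proportions(single, nl_test)

    analyses = acoustic_prediction(
        confusion, trace, contrasts,
        feature_matrices=feature_confusions,
        threshold=config.chance_threshold)
    _stage("UPM analyses", len(contrasts), len(analyses))
    return AcousticArm(
        analyses=analyses, model=model, stepwise=trace,
        confusion=confusion, feature_confusions=feature_confusions)


# ---------------------------------------------------------------------------
# Perceptual arm
# ---------------------------------------------------------------------------

@dataclass
class PerceptualArm:
    analyses: list[OverlapAnalysis]
    confusion: ConfusionMatrix


def run_perceptual_arm(
        responses: Sequence[ClassificationResponse],
        contrasts: Sequence[tuple[str, str]],
        config: StudyConfig | None = None,
        alpha: float = 0.05,
) -> PerceptualArm:
    """Confusion matrix -> above-chance sets -> degrees -> perceived
    distance where complete -> tiers.

    For a completely overlapping contrast the goodness ratings entering
    the perceived-distance test are restricted to trials where the shared
    above-chance category was chosen; a complete contrast without enough
    such ratings is an error (the tier is undefined without them).
    """
    if not contrasts:
        return PerceptualArm(analyses=[], confusion=None)  # type: ignore
    config = config or StudyConfig()
    confusion = confusion_from_responses(
        responses, categories=config.l1_inventory)
    _stage("confusion matrix", len(responses), len(confusion.stimuli))
    threshold = config.chance_threshold
    analyses = []
    for contrast in contrasts:
        a, b = contrast
        row_a, row_b = confusion.row(a), confusion.row(b)
        set_a = above_chance_set(row_a, threshold)
        set_b = above_chance_set(row_b, threshold)
        ratings = None
        if overlap_degree(set_a, set_b) == "complete":
            cat = shared_category(set_a, set_b, row_a, row_b)
            ratings = (goodness_ratings(responses, a, cat),
                       goodness_ratings(responses, b, cat))
            if min(len(ratings[0]), len(ratings[1])) < 2:
                raise ValidationError(
                    f"contrast {format_contrast(contrast)}: complete "
                    f"overlap on {cat!r} but not enough goodness ratings "
                    "for the perceived-distance test")
        analyses.append(analyze_contrast(
            confusion, contrast, threshold=threshold, ratings=ratings,
            alpha=alpha))
    _stage("UPM analyses", len(contrasts), len(analyses))
    return PerceptualArm(analyses=analyses, confusion=confusion)


# ---------------------------------------------------------------------------
# Agreement report
# ---------------------------------------------------------------------------

@dataclass
class ContrastReport:
    contrast: tuple[str, str]
    acoustic_tier: str | None
    perceptual_tier: str | None
    observed_accuracy: float
    observed_tier: str
    acoustic_agrees: bool
    perceptual_agrees: bool
    near_boundary: bool


@dataclass
class PredictionReport:
    """Per-contrast tier comparison of both arms against observation."""

    entries: list[ContrastReport]
    n_acoustic_agree: int
    n_perceptual_agree: int
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "contrasts": [{
                "contrast": format_contrast(e.contrast),
                "acoustic_tier": e.acoustic_tier,
                "perceptual_tier": e.perceptual_tier,
                "observed_accuracy": e.observed_accuracy,
                "observed_tier": e.observed_tier,
                "acoustic_agrees": e.acoustic_agrees,
                "perceptual_agrees": e.perceptual_agrees,
                "near_boundary": e.near_boundary,
            } for e in self.entries],
            "summary": {
                "n_contrasts": len(self.entries),
                "acoustic_agreements": self.n_acoustic_agree,
                "perceptual_agreements": self.n_perceptual_agree,
            },
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), ensure_ascii=False, indent=2,
                          sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def to_markdown(self) -> str:
        lines = [
            "| contrast | acoustic | perceptual | observed acc. "
            "| observed tier | acoustic ok | perceptual ok |",
            "|---|---|---|---|---|---|---|",
        ]
        for e in self.entries:
            flag = " (near band boundary)" if e.near_boundary else ""
            lines.append(
                f"| {format_contrast(e.contrast)} | {e.acoustic_tier} "
                f"| {e.perceptual_tier} | {e.observed_accuracy:.3f}{flag} "
                f"| {e.observed_tier} | "
                f"{'yes' if e.acoustic_agrees else 'no'} | "
                f"{'yes' if e.perceptual_agrees else 'no'} |")
        lines.append("")
        lines.append(
            f"Agreement: acoustic {self.n_acoustic_agree}"
            f"/{len(self.entries)}, perceptual "
            f"{self.n_perceptual_agree}/{len(self.entries)}.")
        return "\n".join(lines)


def evaluate_agreement(
        acoustic: Sequence[OverlapAnalysis],
        perceptual: Sequence[OverlapAnalysis],
        observed: Sequence[AXBResult],
        bands: TierBands = DEFAULT_BANDS,
        provenance: Mapping | None = None,
        boundary_margin: float = 0.02,
) -> PredictionReport:
    """Per-contrast tier equality of each arm against the observed tier.

    Accuracies within ``boundary_margin`` of a band cut point are flagged
    as near-boundary, since their tier assignment is fragile.
    """
    ac = {a.contrast: a for a in acoustic}
    pe = {a.contrast: a for a in perceptual}
    ob = {r.contrast: r for r in observed}
    missing = [format_contrast(c) for c in ac
               if c not in pe or c not in ob]
    missing += [format_contrast(c) for c in pe if c not in ac]
    missing += [format_contrast(c) for c in ob if c not in ac]
    if missing:
        raise ValidationError(
            f"contrast sets do not match across inputs; unmatched: "
            f"{sorted(set(missing))}")
    entries = []
    for contrast, a in ac.items():
        res = ob[contrast]
        observed_tier = tier_from_accuracy(res, bands)
        near = min(abs(res.accuracy - bands.poor_max),
                   abs(res.accuracy - bands.moderate_max)) <= boundary_margin
        entries.append(ContrastReport(
            contrast=contrast,
            acoustic_tier=a.predicted_tier,
            perceptual_tier=pe[contrast].predicted_tier,
            observed_accuracy=res.accuracy,
            observed_tier=observed_tier,
            acoustic_agrees=a.predicted_tier == observed_tier,
            perceptual_agrees=pe[contrast].predicted_tier == observed_tier,
            near_boundary=near))
    return PredictionReport(
        entries=entries,
        n_acoustic_agree=sum(e.acoustic_agrees for e in entries),
        n_perceptual_agree=sum(e.perceptual_agrees for e in entries),
        provenance=dict(provenance or {}))


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class StudyRun:
    acoustic: AcousticArm
    perceptual: PerceptualArm
    observed: list[AXBResult]
    observed_control: list[AXBResult]
    report: PredictionReport


def run_study(seed: int = 0, outdir=None, spec=None) -> StudyRun:
    """Generate the synthetic study and run both arms end to end."""
    from .synthetic import make_study_fixture

    fixture = make_study_fixture(seed=seed, spec=spec)
    contrasts = list(fixture.spec.contrasts)
    acoustic = run_acoustic_arm(
        fixture.cg_tokens, fixture.nl_tokens, contrasts, fixture.config)
    perceptual = run_perceptual_arm(
        fixture.classification_log, contrasts, fixture.config)
    observed = axb_accuracy(fixture.axb_experimental, group="experimental")
    observed_control = axb_accuracy(fixture.axb_control, group="control")
    config_hash = hashlib.sha256(
        json.dumps(fixture.config.to_dict(), sort_keys=True,
                   default=str).encode()).hexdigest()[:12]
    report = evaluate_agreement(
        acoustic.analyses, perceptual.analyses, observed,
        provenance={"seed": seed, "config_sha256": config_hash})
    run = StudyRun(acoustic=acoustic, perceptual=perceptual,
                   observed=observed, observed_control=observed_control,
                   report=report)
    if outdir is not None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_json(outdir / "report.json")
        (outdir / "report.md").write_text(
            report.to_markdown() + "\n", encoding="utf-8")
        acoustic.confusion.to_csv(outdir / "confusion_acoustic.csv")
        perceptual.confusion.to_csv(outdir / "confusion_perceptual.csv")
    return run
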