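"""Domain types, validation, and CSV readers/writers.

The package's interchange format is plain UTF-8 CSV with IPA vowel labels as
literal Unicode strings.  Three kinds of tables circulate through the
pipeline:

* vowel *token* tables — one measured vowel production per row
  (``speaker, language, vowel, f1, f2, f3, duration``);
* *classification* logs — one perceptual-assimilation trial per row
  (``listener, stimulus, choice, goodness, repetition``);
* *AXB* logs — one discrimination trial per row
  (``listener, contrast, configuration, response``).

Correctness of an AXB trial is always recomputed from the configuration and
the response (the middle letter of the configuration is the identity of X),
never trusted from the input file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: Acoustic features carried by a vowel token, in canonical order.
FEATURES: tuple[str, ...] = ("f1", "f2", "f3", "duration")

#: The three formants (duration is never normalized).
FORMANTS: tuple[str, ...] = ("f1", "f2", "f3")

#: Cypriot Greek (L1) vowel inventory, canonical order.
CG_INVENTORY: tuple[str, ...] = ("i", "ε", "ɐ", "ɔ", "u")

#: Dutch (target language) monophthong inventory, canonical order.
NL_INVENTORY: tuple[str, ...] = (
    "a", "ɑ", "i", "u", "ɪ", "ɔ", "ɛ", "ʏ", "o", "e", "ø", "y",
)

#: Glyph variants mapped onto the canonical L1 labels.  The Greek mid-front
#: vowel is written both as Greek epsilon "ε" (U+03B5) and Latin epsilon "ɛ"
#: (U+025B) in common usage; within the L1 response set they are one category.
L1_ALIASES: Mapping[str, str] = {"ɛ": "ε"}

#: The four AXB stimulus configurations; the middle letter identifies X.
AXB_CONFIGURATIONS: tuple[str, ...] = ("AAB", "ABB", "BBA", "BAA")


class VowelmapError(Exception):
    """Base class for package errors."""


class SchemaError(VowelmapError):
    """A table is missing a required column or has the wrong shape."""


class ValidationError(VowelmapError):
    """A row or value violates a domain-type invariant."""


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Inventories, feature set and sample sizes shared across the pipeline.

    ``chance_policy`` fixes how the above-chance threshold is derived;
    ``"inverse-inventory"`` means 1 / len(l1_inventory).
    """

    l1_language: str = "CG"
    l2_language: str = "NL"
    l1_inventory: tuple[str, ...] = CG_INVENTORY
    l2_inventory: tuple[str, ...] = NL_INVENTORY
    features: tuple[str, ...] = FEATURES
    chance_policy: str = "inverse-inventory"
    aliases: Mapping[str, str] = field(default_factory=lambda: dict(L1_ALIASES))
    seed: int = 0
    n_speakers: Mapping[str, int] = field(
        default_factory=lambda: {"CG": 12, "NL": 20})
    n_repetitions: Mapping[str, int] = field(
        default_factory=lambda: {"CG": 4, "NL": 1})
    n_listeners: Mapping[str, int] = field(
        default_factory=lambda: {"experimental": 21, "control": 10})
    classification_repetitions: int = 3

    def __post_init__(self) -> None:
        if not self.l1_inventory or not self.l2_inventory:
            raise ValidationError("inventories must be non-empty")

    @property
    def chance_threshold(self) -> float:
        if self.chance_policy != "inverse-inventory":
            raise ValidationError(
                f"unknown chance policy {self.chance_policy!r}")
        return 1.0 / len(self.l1_inventory)

    def inventory_for(self, language: str) -> tuple[str, ...]:
        if language == self.l1_language:
            return self.l1_inventory
        if language == self.l2_language:
            return self.l2_inventory
        raise ValidationError(f"unknown language {language!r}")

    def canonical_l1(self, label: str) -> str:
        """Map a response label onto the canonical L1 inventory."""
        label = self.aliases.get(label, label)
        if label not in self.l1_inventory:
            raise ValidationError(
                f"unknown L1 category {label!r}; inventory is "
                f"{list(self.l1_inventory)}")
        return label

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            elif isinstance(v, Mapping):
                v = dict(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        kw = dict(d)
        for key in ("l1_inventory", "l2_inventory", "features"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VowelToken:
    """One measured vowel production.

    Formants are in Hz (or pseudo-Hz after normalization and rescaling),
    duration in ms.  The ``f1 < f2 < f3`` ordering is a physical property of
    raw formant measurements; per-formant rescaled values need not preserve
    it, so the check applies only when ``normalized`` is False.
    """

    speaker: str
    language: str
    vowel: str
    f1: float
    f2: float
    f3: float
    duration: float
    normalized: bool = False

    def __post_init__(self) -> None:
        for name in FEATURES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")
        if self.duration <= 0:
            raise ValidationError(
                f"duration must be positive, got {self.duration}")
        if not self.normalized:
            if not (0 < self.f1 < self.f2 < self.f3):
                raise ValidationError(
                    f"formants must satisfy 0 < f1 < f2 < f3, got "
                    f"({self.f1}, {self.f2}, {self.f3}) for vowel "
                    f"{self.vowel!r}")

    def feature_vector(self, features: Sequence[str] = FEATURES) -> np.ndarray:
        return np.array([getattr(self, f) for f in features], dtype=float)

    def with_features(self, **values: float) -> "VowelToken":
        return replace(self, **values)


@dataclass(frozen=True)
class ClassificationResponse:
    """One perceptual-assimilation trial: a stimulus vowel labelled with an
    L1 category and rated for goodness of fit on a 1–5 scale."""

    listener: str
    stimulus: str
    choice: str
    goodness: int
    repetition: int = 0
    talker: str | None = None

    def __post_init__(self) -> None:
        if int(self.goodness) != self.goodness or not 1 <= self.goodness <= 5:
            raise ValidationError(
                f"goodness must be an integer in 1..5, got {self.goodness!r}")
        object.__setattr__(self, "goodness", int(self.goodness))


def axb_correct(configuration: str, response: str) -> bool:
    """Whether ``response`` identifies X for the given AXB configuration.

    The configuration spells the category sequence of the three stimuli,
    so its middle letter is the identity of X.
    """
    if configuration not in AXB_CONFIGURATIONS:
        raise ValidationError(
            f"configuration must be one of {AXB_CONFIGURATIONS}, "
            f"got {configuration!r}")
    if response not in ("A", "B"):
        raise ValidationError(f"response must be 'A' or 'B', got {response!r}")
    return response == configuration[1]


@dataclass(frozen=True)
class AXBTrial:
    """One AXB discrimination trial; ``correct`` is derived, never supplied."""

    listener: str
    contrast: tuple[str, str]
    configuration: str
    response: str
    correct: bool = field(init=False)

    def __post_init__(self) -> None:
        if len(self.contrast) != 2:
            raise ValidationError(
                f"contrast must be a pair, got {self.contrast!r}")
        object.__setattr__(self, "contrast", tuple(self.contrast))
        object.__setattr__(
            self, "correct", axb_correct(self.configuration, self.response))


def format_contrast(contrast: Sequence[str]) -> str:
    return "-".join(contrast)


def parse_contrast(text: str) -> tuple[str, str]:
    for sep in ("-", "–"):  # hyphen or en-dash
        if sep in text:
            parts = tuple(p.strip() for p in text.split(sep))
            if len(parts) == 2 and all(parts):
                return parts  # type: ignore[return-value]
    raise ValidationError(f"cannot parse contrast {text!r}; expected 'a-b'")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}")


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False,
                           encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file with no header") from exc


def _as_float(value: str, column: str, line: int):
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(
            f"line {line}: non-numeric {column} value {value!r}") from exc


def read_tokens(path, config: StudyConfig | None = None) -> list[VowelToken]:
    """Read a vowel-token CSV, validating every row.

    Data rows are numbered from 2 (the header is line 1) so error messages
    point at the offending file line.
    """
    config = config or StudyConfig()
    df = _read_csv(path)
    _require_columns(
        df, ["speaker", "language", "vowel", "f1", "f2", "f3", "duration"],
        path)
    normalized = "normalized" in df.columns
    tokens: list[VowelToken] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        language = row.language
        vowel = row.vowel
        inventory = config.inventory_for(language)
        if language == config.l1_language:
            vowel = config.aliases.get(vowel, vowel)
        if vowel not in inventory:
            raise ValidationError(
                f"line {line}: vowel {row.vowel!r} not in the declared "
                f"{language} inventory {list(inventory)}")
        try:
            tokens.append(VowelToken(
                speaker=row.speaker, language=language, vowel=vowel,
                f1=_as_float(row.f1, "f1", line),
                f2=_as_float(row.f2, "f2", line),
                f3=_as_float(row.f3, "f3", line),
                duration=_as_float(row.duration, "duration", line),
                normalized=(str(row.normalized).lower() == "true")
                if normalized else False,
            ))
        except ValidationError as exc:
            raise ValidationError(f"line {line}: {exc}") from exc
    if not tokens:
        log.warning("%s: token table is empty", path)
    return tokens


def write_tokens(tokens: Iterable[VowelToken], path) -> None:
    df = pd.DataFrame([{
        "speaker": t.speaker, "language": t.language, "vowel": t.vowel,
        "f1": t.f1, "f2": t.f2, "f3": t.f3, "duration": t.duration,
        "normalized": t.normalized,
    } for t in tokens])
    df.to_csv(path, index=False, encoding="utf-8")


def read_classification_log(
        path, config: StudyConfig | None = None,
) -> list[ClassificationResponse]:
    """Read a classification-trial CSV; goodness is coerced to integer."""
    config = config or StudyConfig()
    df = _read_csv(path)
    _require_columns(
        df, ["listener", "stimulus", "choice", "goodness", "repetition"],
        path)
    responses: list[ClassificationResponse] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        stimulus = row.stimulus
        if stimulus not in config.l2_inventory:
            raise ValidationError(
                f"line {line}: stimulus {stimulus!r} not in the "
                f"{config.l2_language} inventory")
        try:
            choice = config.canonical_l1(row.choice)
            goodness = _as_float(row.goodness, "goodness", line)
            responses.append(ClassificationResponse(
                listener=row.listener, stimulus=stimulus, choice=choice,
                goodness=int(goodness) if goodness == int(goodness)
                else goodness,
                repetition=int(_as_float(row.repetition, "repetition", line)),
                talker=getattr(row, "talker", None),
            ))
        except ValidationError as exc:
            raise ValidationError(f"line {line}: {exc}") from exc
    if not responses:
        log.warning("%s: classification log is empty", path)
    else:
        counts = pd.Series([r.listener for r in responses]).value_counts()
        log.info("%s: %d responses from %d listeners (trials/listener: "
                 "min %d, max %d)", path, len(responses), counts.size,
                 counts.min(), counts.max())
    return responses


def write_classification_log(
        responses: Iterable[ClassificationResponse], path) -> None:
    df = pd.DataFrame([{
        "listener": r.listener, "stimulus": r.stimulus, "choice": r.choice,
        "goodness": r.goodness, "repetition": r.repetition,
        **({"talker": r.talker} if r.talker is not None else {}),
    } for r in responses])
    df.to_csv(path, index=False, encoding="utf-8")


def read_axb_log(path, config: StudyConfig | None = None) -> list[AXBTrial]:
    """Read an AXB-trial CSV; correctness is derived, never read."""
    config = config or StudyConfig()
    df = _read_csv(path)
    _require_columns(
        df, ["listener", "contrast", "configuration", "response"], path)
    trials: list[AXBTrial] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            contrast = parse_contrast(row.contrast)
            for member in contrast:
                if member not in config.l2_inventory:
                    raise ValidationError(
                        f"contrast member {member!r} not in the "
                        f"{config.l2_language} inventory")
            trials.append(AXBTrial(
                listener=row.listener, contrast=contrast,
                configuration=row.configuration, response=row.response))
        except ValidationError as exc:
            raise ValidationError(f"line {line}: {exc}") from exc
    if not trials:
        log.warning("%s: AXB log is empty", path)
    return trials


def write_axb_log(trials: Iterable[AXBTrial], path) -> None:
    df = pd.DataFrame([{
        "listener": t.listener, "contrast": format_contrast(t.contrast),
        "configuration": t.configuration, "response": t.response,
    } for t in trials])
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def design_matrix(
        tokens: Sequence[VowelToken],
        features: Sequence[str] = FEATURES,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack tokens into an (n, p) matrix and a label vector."""
    unknown = [f for f in features if f not in FEATURES]
    if unknown:
        raise ValidationError(f"unknown feature(s) {unknown}")
    X = np.array([[getattr(t, f) for f in features] for t in tokens],
                 dtype=float)
    y = np.array([t.vowel for t in tokens], dtype=object)
    return X, y
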