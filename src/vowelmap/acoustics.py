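"""Speaker normalization, pseudo-Hz rescaling, inventory summaries, and
Euclidean acoustic similarity.

Lobanov normalization z-scores each formant within speaker, removing
anatomical (vocal-tract length) differences so that inventories produced by
different speaker sets become comparable.  The z-scores are then mapped back
onto a Hz-like scale with a per-formant affine map so that plots and
distances read in familiar units.  Duration is never normalized.

Acoustic similarity between an L1 vowel and a target-language vowel is the
Euclidean distance between their inventory mean vectors, by default in the
F1 x F2 plane.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    FEATURES,
    FORMANTS,
    ValidationError,
    VowelToken,
)

log = logging.getLogger(__name__)

#: Pseudo-Hz rescaling: z_min maps to RESCALE_OFFSET, z_max to
#: RESCALE_OFFSET + RESCALE_SPAN.  Isolated here so an alternative scaling
#: can be substituted in one place.
RESCALE_OFFSET = 250.0
RESCALE_SPAN = 500.0


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-table style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# Lobanov normalization and rescaling
# ---------------------------------------------------------------------------

@dataclass
class NormalizationState:
    """Per-speaker formant statistics plus pooled z ranges for rescaling.

    ``speaker_stats[(speaker, formant)] = (mean, sd)`` over that speaker's
    raw values; ``z_range[formant] = (z_min, z_max)`` over the pooled
    normalized dataset.
    """

    speaker_stats: dict[tuple[str, str], tuple[float, float]]
    z_range: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for (spk, fmt), (_, sd) in self.speaker_stats.items():
            if sd <= 0:
                raise ValidationError(
                    f"speaker {spk!r} has zero/negative SD for {fmt}")
        for fmt, (lo, hi) in self.z_range.items():
            if not lo < hi:
                raise ValidationError(
                    f"degenerate z range for {fmt}: [{lo}, {hi}]")


def lobanov_normalize(
        tokens: Sequence[VowelToken],
) -> tuple[list[VowelToken], NormalizationState]:
    """Z-score F1–F3 within speaker; duration passes through unchanged.

    Uses the sample SD (n − 1).  Every speaker must contribute at least two
    tokens with non-zero within-speaker spread on each formant.
    """
    if not tokens:
        raise ValidationError("no tokens to normalize")
    by_speaker: dict[str, list[VowelToken]] = {}
    for t in tokens:
        by_speaker.setdefault(t.speaker, []).append(t)

    stats: dict[tuple[str, str], tuple[float, float]] = {}
    for spk, group in by_speaker.items():
        if len(group) < 2:
            raise ValidationError(
                f"speaker {spk!r} has only {len(group)} token(s); "
                "within-speaker SD is undefined")
        for fmt in FORMANTS:
            vals = np.array([getattr(t, fmt) for t in group], dtype=float)
            mean, sd = float(vals.mean()), float(vals.std(ddof=1))
            if sd <= 0:
                raise ValidationError(
                    f"speaker {spk!r} has zero within-speaker SD for {fmt}")
            stats[(spk, fmt)] = (mean, sd)

    out: list[VowelToken] = []
    for t in tokens:
        z = {}
        for fmt in FORMANTS:
            mean, sd = stats[(t.speaker, fmt)]
            z[fmt] = (getattr(t, fmt) - mean) / sd
        out.append(VowelToken(
            speaker=t.speaker, language=t.language, vowel=t.vowel,
            f1=z["f1"], f2=z["f2"], f3=z["f3"], duration=t.duration,
            normalized=True))

    z_range = {}
    for fmt in FORMANTS:
        vals = np.array([getattr(t, fmt) for t in out])
        z_range[fmt] = (float(vals.min()), float(vals.max()))
    state = NormalizationState(speaker_stats=stats, z_range=z_range)
    log.info("normalized %d tokens from %d speakers", len(out),
             len(by_speaker))
    return out, state


def rescale_to_hz(
        z_tokens: Sequence[VowelToken],
        state: NormalizationState,
) -> list[VowelToken]:
    """Map z-scores onto a pseudo-Hz scale.

    Each formant is mapped by ``250 + 500 * (z - z_min) / (z_max - z_min)``
    with the pooled per-formant z range from ``state``, so rescaled values
    lie in [250, 750] and are monotone in z.  Values outside the stored
    range (a frozen state applied to new data) are clamped with a warning.
    """
    out: list[VowelToken] = []
    clamped = 0
    for t in z_tokens:
        scaled = {}
        for fmt in FORMANTS:
            lo, hi = state.z_range[fmt]
            z = getattr(t, fmt)
            if z < lo or z > hi:
                clamped += 1
                z = min(max(z, lo), hi)
            scaled[fmt] = RESCALE_OFFSET + RESCALE_SPAN * (z - lo) / (hi - lo)
        out.append(VowelToken(
            speaker=t.speaker, language=t.language, vowel=t.vowel,
            f1=scaled["f1"], f2=scaled["f2"], f3=scaled["f3"],
            duration=t.duration, normalized=True))
    if clamped:
        warnings.warn(
            f"{clamped} z value(s) fell outside the stored range and were "
            "clamped", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Inventory summaries
# ---------------------------------------------------------------------------

@dataclass
class VowelSummary:
    """Per-vowel mean and sample SD for each acoustic feature.

    ``stats[vowel][feature] = (mean, sd)``.  Houses the printed inventory
    tables and everything derived from token collections.
    """

    language: str
    stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        for vowel, feats in self.stats.items():
            for feat, (_, sd) in feats.items():
                if sd < 0:
                    raise ValidationError(
                        f"negative SD for {vowel!r}/{feat}: {sd}")

    @property
    def vowels(self) -> tuple[str, ...]:
        return tuple(self.stats)

    def mean(self, vowel: str, feature: str) -> float:
        return self.stats[vowel][feature][0]

    def sd(self, vowel: str, feature: str) -> float:
        return self.stats[vowel][feature][1]

    def mean_vector(self, vowel: str,
                    features: Sequence[str] = FEATURES) -> np.ndarray:
        return np.array([self.mean(vowel, f) for f in features], dtype=float)

    def sd_vector(self, vowel: str,
                  features: Sequence[str] = FEATURES) -> np.ndarray:
        return np.array([self.sd(vowel, f) for f in features], dtype=float)

    @classmethod
    def from_table(
            cls, language: str,
            table: Mapping[str, Sequence[tuple[float, float]]],
            features: Sequence[str] = FEATURES) -> "VowelSummary":
        """Build from ``{vowel: [(mean, sd) per feature]}`` rows."""
        stats = {
            v: {f: (float(m), float(s))
                for f, (m, s) in zip(features, row)}
            for v, row in table.items()
        }
        return cls(language=language, stats=stats)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, feats in self.stats.items():
            row: dict[str, object] = {"vowel": v}
            for f, (m, s) in feats.items():
                row[f"{f}_mean"] = m
                row[f"{f}_sd"] = s
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path, language: str) -> "VowelSummary":
        df = pd.read_csv(path, encoding="utf-8")
        stats: dict[str, dict[str, tuple[float, float]]] = {}
        for _, row in df.iterrows():
            feats = {}
            for f in FEATURES:
                if f"{f}_mean" in df.columns:
                    feats[f] = (float(row[f"{f}_mean"]),
                                float(row.get(f"{f}_sd", 0.0)))
            stats[str(row["vowel"])] = feats
        return cls(language=language, stats=stats)


def summarize_inventory(
        tokens: Sequence[VowelToken],
        language: str | None = None,
) -> VowelSummary:
    """Per-vowel mean and sample SD (n − 1) for each feature."""
    if not tokens:
        raise ValidationError("no tokens to summarize")
    language = language or tokens[0].language
    by_vowel: dict[str, list[VowelToken]] = {}
    for t in tokens:
        by_vowel.setdefault(t.vowel, []).append(t)
    stats: dict[str, dict[str, tuple[float, float]]] = {}
    for vowel, group in by_vowel.items():
        if len(group) < 2:
            raise ValidationError(
                f"vowel {vowel!r} has only {len(group)} token(s); "
                "need at least 2 for a sample SD")
        feats = {}
        for f in FEATURES:
            vals = np.array([getattr(t, f) for t in group], dtype=float)
            feats[f] = (float(vals.mean()), float(vals.std(ddof=1)))
        stats[vowel] = feats
    return VowelSummary(language=language, stats=stats)


# ---------------------------------------------------------------------------
# Euclidean similarity
# ---------------------------------------------------------------------------

def euclidean_distance(
        a: Mapping[str, float] | np.ndarray,
        b: Mapping[str, float] | np.ndarray,
        features: Sequence[str] = ("f1", "f2"),
) -> float:
    """d = sqrt(sum of squared per-feature differences).

    Accepts feature mappings (keyed by feature name) or plain vectors
    already aligned to ``features``.
    """
    if isinstance(a, Mapping) or isinstance(b, Mapping):
        if not (isinstance(a, Mapping) and isinstance(b, Mapping)):
            raise ValidationError("mix of mapping and vector inputs")
        missing = [f for f in features
                   if f not in a or f not in b]
        if missing:
            raise ValidationError(
                f"feature(s) {missing} missing from one of the inputs")
        va = np.array([a[f] for f in features], dtype=float)
        vb = np.array([b[f] for f in features], dtype=float)
    else:
        va, vb = np.asarray(a, float), np.asarray(b, float)
        if va.shape != vb.shape or va.shape[-1] != len(features):
            raise ValidationError(
                f"feature vectors do not match the feature set {features}")
    return float(np.sqrt(((va - vb) ** 2).sum()))


@dataclass
class DistanceTable:
    """All (L1 vowel, L2 vowel) distances over one feature subset.

    ``nearest(l1)`` returns the L2 vowels sorted by ascending distance,
    ties broken by the canonical L2 inventory order and recorded in
    ``ties``.
    """

    features: tuple[str, ...]
    l1_vowels: tuple[str, ...]
    l2_vowels: tuple[str, ...]
    distances: dict[tuple[str, str], float]
    ties: set[tuple[str, str, str]] = field(default_factory=set)

    def d(self, l1: str, l2: str) -> float:
        return self.distances[(l1, l2)]

    def rounded(self, l1: str, l2: str) -> int:
        """Distance at printed precision (nearest integer, half up)."""
        return round_half_up(self.d(l1, l2))

    def nearest(self, l1: str) -> list[tuple[str, float]]:
        order = {v: i for i, v in enumerate(self.l2_vowels)}
        return sorted(
            ((l2, self.d(l1, l2)) for l2 in self.l2_vowels),
            key=lambda pair: (pair[1], order[pair[0]]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.d(a, b) for b in self.l2_vowels] for a in self.l1_vowels],
            index=list(self.l1_vowels), columns=list(self.l2_vowels))


def distance_ranking(
        l1: VowelSummary,
        l2: VowelSummary,
        features: Sequence[str] = ("f1", "f2"),
) -> DistanceTable:
    """Pairwise mean-to-mean distances with per-L1-vowel nearest ordering."""
    if not l1.vowels or not l2.vowels:
        raise ValidationError("both summaries must be non-empty")
    features = tuple(features)
    distances: dict[tuple[str, str], float] = {}
    ties: set[tuple[str, str, str]] = set()
    for a in l1.vowels:
        va = l1.mean_vector(a, features)
        for b in l2.vowels:
            distances[(a, b)] = euclidean_distance(
                va, l2.mean_vector(b, features), features)
        ds = sorted((distances[(a, b)], b) for b in l2.vowels)
        for (d1, b1), (d2, b2) in zip(ds, ds[1:]):
            if math.isclose(d1, d2, rel_tol=0, abs_tol=1e-9):
                ties.add((a, b1, b2))
    if ties:
        log.info("distance ties (broken by inventory order): %s", ties)
    return DistanceTable(
        features=features, l1_vowels=l1.vowels, l2_vowels=l2.vowels,
        distances=distances, ties=ties)


def plot_vowel_space(
        summaries: Iterable[VowelSummary], path,
        features: Sequence[str] = ("f2", "f1")) -> None:
    """F1 x F2 scatter of one or more inventories (axes reversed, the
    phonetician's convention).  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fx, fy = features
    fig, ax = plt.subplots(figsize=(6, 5))
    markers = ["o", "s", "^", "D"]
    for i, summ in enumerate(summaries):
        xs = [summ.mean(v, fx) for v in summ.vowels]
        ys = [summ.mean(v, fy) for v in summ.vowels]
        ax.scatter(xs, ys, marker=markers[i % len(markers)],
                   label=summ.language)
        for v, x, y in zip(summ.vowels, xs, ys):
            ax.annotate(v, (x, y), textcoords="offset points",
                        xytext=(4, 4))
    ax.invert_xaxis()
    ax.invert_yaxis()
    ax.set_xlabel(f"{fx.upper()} (Hz)")
    ax.set_ylabel(f"{fy.upper()} (Hz)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
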