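"""Match-quality evaluation: scoring, confusion counts and threshold sweeps.

A scored pair carries a raw distance and the shared normalized similarity
``1 - d / max(|s|, |t|)``.  Given truth labels, a pair is predicted a match
when its similarity is at or above the decision threshold; confusion counts
then yield precision ``TP/(TP+FP)``, recall ``TP/(TP+FN)`` and their
harmonic mean, the F-measure.  The conventional threshold grid for name
matching runs from 0.65 to 0.90 in steps of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .bigrams import ndist, soft_bidist
from .distances import (
    dld_distance,
    lev_distance,
    mdld_distance,
    normalized_similarity,
)
from .names import NameString
from .presets import WeightScale, preset

__all__ = [
    "ScoredPair",
    "ConfusionCounts",
    "EvalMetrics",
    "DEFAULT_THRESHOLDS",
    "ALGORITHMS",
    "score_pair",
    "score_pairs",
    "confusion_counts",
    "precision_recall_f",
    "evaluate_at",
    "threshold_sweep",
    "mean_similarity",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.65, 0.70, 0.75, 0.80, 0.85, 0.90)

#: Algorithm identifiers accepted by :func:`score_pair` and the CLI.
ALGORITHMS: tuple[str, ...] = ("ld", "dld", "mdld", "ndist", "soft-bidist")


@dataclass(frozen=True)
class ScoredPair:
    source: NameString
    target: NameString
    algorithm: str
    distance: float
    similarity: float
    label: bool | None = None
    scale: WeightScale | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalMetrics:
    threshold: float
    counts: ConfusionCounts
    precision: float
    recall: float
    f_measure: float


def _dispatch(
    algorithm: str, scale: WeightScale | None, max_block: int
) -> tuple[Callable[[NameString, NameString], float], WeightScale | None]:
    if algorithm == "ld":
        return lambda s, t: float(lev_distance(s, t)), None
    if algorithm == "dld":
        return lambda s, t: float(dld_distance(s, t)), None
    if algorithm == "mdld":
        return lambda s, t: float(mdld_distance(s, t, max_block=max_block)), None
    if algorithm == "ndist":
        return ndist, None
    if algorithm == "soft-bidist":
        w = scale if scale is not None else preset("applied")
        return lambda s, t: soft_bidist(s, t, w), w
    raise ValueError(
        f"unknown algorithm {algorithm!r}; valid: {', '.join(ALGORITHMS)}"
    )


def score_pair(
    source: "str | NameString",
    target: "str | NameString",
    algorithm: str = "soft-bidist",
    scale: WeightScale | None = None,
    label: bool | None = None,
    max_block: int = 2,
) -> ScoredPair:
    """Compute distance and normalized similarity for one name pair."""
    s = source if isinstance(source, NameString) else NameString.from_text(source)
    t = target if isinstance(target, NameString) else NameString.from_text(target)
    fn, used_scale = _dispatch(algorithm, scale, max_block)
    d = fn(s, t)
    return ScoredPair(
        source=s,
        target=t,
        algorithm=algorithm,
        distance=d,
        similarity=normalized_similarity(d, s, t),
        label=label,
        scale=used_scale,
    )


def score_pairs(
    pairs: Iterable[tuple],
    algorithm: str = "soft-bidist",
    scale: WeightScale | None = None,
    max_block: int = 2,
) -> list[ScoredPair]:
    """Score an iterable of ``(source, target)`` or ``(source, target, label)``."""
    out = []
    for row in pairs:
        source, target = row[0], row[1]
        label = row[2] if len(row) > 2 else None
        out.append(
            score_pair(source, target, algorithm, scale, label, max_block)
        )
    return out


def confusion_counts(
    pairs: Sequence[ScoredPair], threshold: float
) -> ConfusionCounts:
    """Tabulate predictions (similarity >= threshold) against truth labels."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    tp = fp = fn = tn = 0
    for idx, p in enumerate(pairs):
        if p.label is None:
            raise ValueError(
                f"pair {idx} ({p.source.original!r}, {p.target.original!r}) "
                "has no truth label"
            )
        predicted = p.similarity >= threshold
        if p.label and predicted:
            tp += 1
        elif p.label and not predicted:
            fn += 1
        elif not p.label and predicted:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision_recall_f(
    c: ConfusionCounts, threshold: float = 0.0
) -> EvalMetrics:
    """Precision, recall and F-measure with zero-denominator conventions.

    Precision is 0 when no pair is predicted positive, recall is 0 when
    there are no true matches, and F is 0 when precision + recall is 0.
    """
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f = (
        2.0 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return EvalMetrics(
        threshold=threshold,
        counts=c,
        precision=precision,
        recall=recall,
        f_measure=f,
    )


def evaluate_at(pairs: Sequence[ScoredPair], threshold: float) -> EvalMetrics:
    return precision_recall_f(confusion_counts(pairs, threshold), threshold)


def threshold_sweep(
    pairs: Sequence[ScoredPair],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[EvalMetrics]:
    """Evaluate the same scored pairs at every threshold, in input order."""
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    return [evaluate_at(pairs, t) for t in thresholds]


def mean_similarity(pairs: Sequence[ScoredPair]) -> float:
    """Arithmetic mean of the pair similarities (full precision)."""
    if not pairs:
        raise ValueError("mean_similarity of an empty pair list")
    return sum(p.similarity for p in pairs) / len(pairs)
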