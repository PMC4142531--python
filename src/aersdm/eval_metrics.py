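"""Precision / recall / F-measure for drug-name normalization.

Given confusion counts over a manually annotated sample of input strings:

    P = TP / (TP + FP),  R = TP / (TP + FN),  F = 2PR / (P + R)

Percentages are rounded half-up to one decimal at output only; F is
computed from the unrounded P and R. A zero denominator is an undefined
metric, signalled by :class:`UndefinedMetricError` rather than reported
as zero — except F with P = R = 0, which is 0.0 by the usual convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from ._util import round_half_up
from .drug_normalizer import DrugMention


class UndefinedMetricError(ZeroDivisionError):
    """The metric's denominator is zero; the value is undefined, not 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def _precision_raw(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no predictions")
    return 100.0 * c.tp / (c.tp + c.fp)


def _recall_raw(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no gold positives")
    return 100.0 * c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """TP/(TP+FP) as a one-decimal percent."""
    return round_half_up(_precision_raw(c), 1)


def recall(c: ConfusionCounts) -> float:
    """TP/(TP+FN) as a one-decimal percent."""
    return round_half_up(_recall_raw(c), 1)


def f_measure(c: ConfusionCounts) -> float:
    """Harmonic mean of unrounded P and R, as a one-decimal percent."""
    p, r = _precision_raw(c), _recall_raw(c)
    if p + r == 0:
        return 0.0
    return round_half_up(2 * p * r / (p + r), 1)


def score_against_gold(predicted: Iterable[DrugMention],
                       gold: Mapping[str, int | None]) -> ConfusionCounts:
    """Confusion counts of predictions against a gold annotation.

    ``gold`` maps input strings to their annotated RxCUI, or None where
    the annotators judged the string uncodeable. Scoring is per unique
    input string (first prediction wins). A prediction agreeing with a
    gold code is a TP; a prediction whose code differs from the gold code
    counts as one FP and one FN (the gold string was not recovered); a
    prediction where gold says "no code" is an FP; a gold-coded string
    the system left unmatched is an FN. Strings outside the gold set are
    ignored.
    """
    by_string: dict[str, DrugMention] = {}
    for m in predicted:
        by_string.setdefault(m.input_string, m)
    tp = fp = fn = 0
    for text, gold_code in gold.items():
        pred = by_string.get(text)
        pred_code = pred.matched_rxcui if pred is not None else None
        if gold_code is None:
            if pred_code is not None:
                fp += 1
        elif pred_code is None:
            fn += 1
        elif pred_code == gold_code:
            tp += 1
        else:
            fp += 1
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)
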