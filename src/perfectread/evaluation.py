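"""Read-level and base-level evaluation metrics.

Read level (against ground-truth perfect labels):
  TP = perfect reads classified perfect        FN = perfect classified erroneous
  FP = erroneous reads classified perfect      TN = erroneous classified erroneous
  Sp = TN/(TN+FP), Sn = TP/(TP+FN), Pr = TP/(TP+FP)

Base level (for a substitution-only corrector):
  TP = erroneous base changed to the true base, FP = true base changed wrongly,
  TN = true base left unchanged, FN = erroneous base left unchanged,
  WC = erroneous base changed but to a wrong base.
  Gain G = (TP-FP)/(TP+FN), EBA = WC/(TP+WC).

Zero denominators yield None (undefined), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fastq_io import GroundTruthLabel, ReadRecord
from .perfect_classifier import Classification

__all__ = [
    "ConfusionCounts",
    "BaseCorrectionCounts",
    "read_metrics",
    "base_metrics",
    "evaluate_classification",
    "evaluate_correction",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class BaseCorrectionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    wc: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn, self.wc) < 0:
            raise ValueError("correction counts must be non-negative")


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def read_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Specificity, sensitivity and precision of the read classification."""
    return {
        "Sp": _ratio(c.tn, c.tn + c.fp),
        "Sn": _ratio(c.tp, c.tp + c.fn),
        "Pr": _ratio(c.tp, c.tp + c.fp),
    }


def base_metrics(c: BaseCorrectionCounts) -> dict[str, float | None]:
    """Sn, Sp, Gain and EBA of a base-level correction (Gain may be < 0)."""
    return {
        "Sn": _ratio(c.tp, c.tp + c.fn),
        "Sp": _ratio(c.tn, c.tn + c.fp),
        "Gain": (c.tp - c.fp) / (c.tp + c.fn) if c.tp + c.fn > 0 else None,
        "EBA": _ratio(c.wc, c.tp + c.wc),
    }


def evaluate_classification(
    predictions: Iterable[Classification],
    truth: Mapping[str, GroundTruthLabel | bool],
) -> tuple[ConfusionCounts, int]:
    """Tally read-level confusion counts; short reads are excluded.

    Returns (counts, n_short_excluded). Every non-short prediction must
    have a truth label (GroundTruthLabel or plain bool), else KeyError.
    """
    c = ConfusionCounts()
    n_short = 0
    for pred in predictions:
        if pred.is_short:
            n_short += 1
            continue
        label = truth[pred.read_id]
        is_perfect = label.is_perfect if isinstance(label, GroundTruthLabel) else bool(label)
        if is_perfect:
            if pred.is_perfect:
                c.tp += 1
            else:
                c.fn += 1
        else:
            if pred.is_perfect:
                c.fp += 1
            else:
                c.tn += 1
    return c, n_short


def _to_matrix(reads: Sequence[ReadRecord]) -> np.ndarray:
    blob = b"".join(r.sequence.encode("ascii") for r in reads)
    return np.frombuffer(blob, dtype=np.uint8)


def evaluate_correction(
    original: Sequence[ReadRecord],
    corrected: Sequence[ReadRecord],
    truth_sequences: Sequence[ReadRecord] | Sequence[str],
) -> BaseCorrectionCounts:
    """Per-base tally of a substitution-only correction against truth.

    The three collections must be position-aligned: same order, same ids,
    same lengths (no indels).
    """
    if not (len(original) == len(corrected) == len(truth_sequences)):
        raise ValueError("original/corrected/truth must have equal read counts")
    for o, c, t in zip(original, corrected, truth_sequences):
        tseq = t if isinstance(t, str) else t.sequence
        if not (len(o) == len(c) == len(tseq)):
            raise ValueError(f"length mismatch at read {o.read_id!r}")
        if o.read_id != c.read_id:
            raise ValueError("original and corrected ids out of order")
    orig = _to_matrix(original)
    corr = _to_matrix(corrected)
    if truth_sequences and isinstance(truth_sequences[0], str):
        blob = b"".join(s.encode("ascii") for s in truth_sequences)  # type: ignore[union-attr]
        true = np.frombuffer(blob, dtype=np.uint8)
    else:
        true = _to_matrix(truth_sequences)  # type: ignore[arg-type]
    was_err = orig != true
    changed = corr != orig
    now_true = corr == true
    return BaseCorrectionCounts(
        tp=int((was_err & now_true).sum()),
        fp=int((~was_err & changed).sum()),
        tn=int((~was_err & ~changed).sum()),
        fn=int((was_err & ~changed).sum()),
        wc=int((was_err & changed & ~now_true).sum()),
    )
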