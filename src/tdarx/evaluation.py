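"""Evaluation metrics and diagnostics for the RA/nonRA classifier.

Implements the study's report quantities: the 2x2 confusion matrix with RA
as the positive class, precision / recall / accuracy (reported as integer
percentages, rounded half-up, with exact fractions retained), Cohen's kappa
for chance-corrected agreement between two raters, a three-way ablation
comparison (full image vs joints-only vs clinical-only), and a single-field
counterfactual probe that re-renders a record with one value replaced and
asks whether the predicted label flips (the published example flips ACPA
negativity to positivity).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .harness import (TrainingConfig, TrialRun, predict, run_trials)
from .layout import LayoutSpec
from .records import PatientRecord, get_field, set_field
from .rules import Palette, RuleSet, default_rules

LABELS = ("RA", "nonRA")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with RA as the positive class."""

    tp: int  # true RA, predicted RA
    fn: int  # true RA, predicted nonRA
    fp: int  # true nonRA, predicted RA
    tn: int  # true nonRA, predicted nonRA

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_table(self) -> str:
        head = f"{'':12s}{'pred RA':>10s}{'pred nonRA':>12s}"
        r1 = f"{'true RA':12s}{self.tp:>10d}{self.fn:>12d}"
        r2 = f"{'true nonRA':12s}{self.fp:>10d}{self.tn:>12d}"
        return "\n".join((head, r1, r2))


def confusion(true_labels: Sequence[str],
              predicted_labels: Sequence[str]) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    counts = {(t, p): 0 for t in LABELS for p in LABELS}
    for t, p in zip(true_labels, predicted_labels):
        if t not in LABELS or p not in LABELS:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[(t, p)] += 1
    return ConfusionMatrix(tp=counts[("RA", "RA")], fn=counts[("RA", "nonRA")],
                           fp=counts[("nonRA", "RA")],
                           tn=counts[("nonRA", "nonRA")])


def _round_half_up_percent(frac: Fraction) -> int:
    return int((100 * frac) + Fraction(1, 2)) if frac >= 0 else 0


@dataclass(frozen=True)
class Metrics:
    """Integer-percent report values plus the exact fractions behind them.

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    """

    precision_pct: Optional[int]
    recall_pct: Optional[int]
    accuracy_pct: Optional[int]
    precision: Optional[Fraction]
    recall: Optional[Fraction]
    accuracy: Optional[Fraction]


def prf_accuracy(matrix: ConfusionMatrix) -> Metrics:
    """Precision, recall and accuracy (RA positive), rounded half-up to
    integer percent for report parity; exact fractions retained."""
    def ratio(num, den):
        return Fraction(num, den) if den > 0 else None

    precision = ratio(matrix.tp, matrix.tp + matrix.fp)
    recall = ratio(matrix.tp, matrix.tp + matrix.fn)
    accuracy = ratio(matrix.tp + matrix.tn, matrix.total)
    to_pct = (lambda f: None if f is None else _round_half_up_percent(f))
    return Metrics(precision_pct=to_pct(precision), recall_pct=to_pct(recall),
                   accuracy_pct=to_pct(accuracy), precision=precision,
                   recall=recall, accuracy=accuracy)


def cohens_kappa(rater_a: Sequence, rater_b: Sequence) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement rate and p_e the agreement expected from
    the two raters' marginal label frequencies.  Returns 1.0 in the
    degenerate all-agree single-label case (p_e = p_o = 1).
    """
    if len(rater_a) != len(rater_b):
        raise ValueError("rater label lists must have equal length")
    n = len(rater_a)
    if n == 0:
        raise ValueError("need at least one rated case")
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    p_o = float(np.mean(a == b))
    labels = np.union1d(a, b)
    p_e = float(sum(np.mean(a == lab) * np.mean(b == lab) for lab in labels))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# Ablation comparison
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = ("full", "cruciform_only", "clinical_only")


def ablation_report(learning: Sequence[PatientRecord],
                    test: Sequence[PatientRecord],
                    config: Optional[TrainingConfig] = None,
                    rules: RuleSet | None = None,
                    palette: Palette | None = None,
                    layout: LayoutSpec | None = None) -> dict[str, TrialRun]:
    """Best-of-n accuracy for the full image and each ablation half.

    The same cohorts, config and base seed are used for all three variants,
    so the runs differ only in which blocks are visible.
    """
    return {variant: run_trials(learning, test, config, variant=variant,
                                rules=rules, palette=palette, layout=layout)
            for variant in ABLATION_VARIANTS}


def ablation_summary(report: dict[str, TrialRun]) -> dict[str, float]:
    return {variant: run.selected.test_accuracy
            for variant, run in report.items()}


# ---------------------------------------------------------------------------
# Counterfactual probe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeResult:
    field_id: str
    original_value: object
    new_value: object
    original_label: str
    modified_label: str
    original_score: float  # P(RA)
    modified_score: float

    @property
    def changed(self) -> bool:
        return self.original_label != self.modified_label


def counterfactual_probe(model, record: PatientRecord, field_id: str,
                         new_value,
                         rules: RuleSet | None = None,
                         palette: Palette | None = None,
                         layout: LayoutSpec | None = None,
                         resolution: int | None = None) -> ProbeResult:
    """Predict ``record`` as-is and with one field replaced; report the flip.

    The input record is never mutated.  The replacement value must be valid
    for the field (it is discretized before rendering, so an out-of-domain
    value raises).
    """
    from .harness import encode_records

    rules = rules or default_rules()
    rules.categorize(field_id, new_value)  # validate field and value early

    modified = record.copy()
    set_field(modified, field_id, new_value)

    res = resolution or model.input_hw[0]
    x = encode_records([record, modified], resolution=res,
                       rules=rules, palette=palette, layout=layout)
    labels, scores = predict(model, x)
    return ProbeResult(field_id=field_id,
                       original_value=get_field(record, field_id),
                       new_value=new_value,
                       original_label=labels[0], modified_label=labels[1],
                       original_score=float(scores[0]),
                       modified_score=float(scores[1]))


__all__ = [
    "ConfusionMatrix", "Metrics", "ProbeResult", "ablation_report",
    "ablation_summary", "cohens_kappa", "confusion", "counterfactual_probe",
    "prf_accuracy",
]
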