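"""Accuracy of predicted vs reference secondary structures.

Comparison follows four variants over index-matched base pairs:

* I   - canonical and non-canonical pairs together;
* II  - canonical pairs only;
* III - non-canonical pairs only, classification ignored;
* IV  - non-canonical pairs only; a position match counts as a true
  positive only when the LW family also agrees, a misclassified match
  counts as a false positive, and false negatives are the reference
  non-canonical pairs left unpredicted.

Multiplet-member pairs are excluded before matching: dot-bracket notation
cannot represent them, so they are not compared.  Scores are PPV (precision),
TPR (sensitivity) and MCC reported as sqrt(PPV x TPR), the TN-free form
standard for base-pair prediction.  Zero denominators yield 0 with an
``undefined`` flag.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .basepair_annotation import LWFamily
from .errors import EvaluationError
from .secondary_structure import SecondaryStructure


class Variant(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


@dataclass(frozen=True, slots=True)
class EvalPair:
    """A labelled pair for comparison: indices plus optional labels."""

    i: int
    j: int
    canonical: bool
    lw: LWFamily | None = None
    in_multiplet: bool = False

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    variant: Variant

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True, slots=True)
class EvaluationResult:
    ppv: float
    tpr: float
    mcc: float
    counts: ConfusionCounts
    ppv_undefined: bool = False
    tpr_undefined: bool = False


def pairs_from_secondary_structure(ss: SecondaryStructure) -> list[EvalPair]:
    """Bracket-encoded pairs of a structure as comparison inputs."""
    return [
        EvalPair(i=p.i, j=p.j, canonical=p.canonical, lw=p.lw)
        for p in ss.paired
    ]


def round_half_up(x: float, digits: int = 2) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def match_pairs(pred: list[EvalPair], ref: list[EvalPair]) -> list[tuple[EvalPair, EvalPair]]:
    """Index-identical matches, multiplet members excluded first."""
    ref_by_key = {p.key: p for p in ref if not p.in_multiplet}
    return [
        (p, ref_by_key[p.key])
        for p in pred
        if not p.in_multiplet and p.key in ref_by_key
    ]


def _variant_subset(pairs: list[EvalPair], variant: Variant) -> list[EvalPair]:
    pairs = [p for p in pairs if not p.in_multiplet]
    if variant is Variant.I:
        return pairs
    if variant is Variant.II:
        return [p for p in pairs if p.canonical]
    return [p for p in pairs if not p.canonical]


def confusion(pred: list[EvalPair], ref: list[EvalPair],
              variant: Variant) -> ConfusionCounts:
    """TP/FP/FN under the chosen comparison variant."""
    pred_s = _variant_subset(pred, variant)
    ref_s = _variant_subset(ref, variant)
    matches = match_pairs(pred_s, ref_s)
    if variant is Variant.IV:
        if any(p.lw is None for p, _ in matches) or any(r.lw is None for _, r in matches):
            raise EvaluationError("variant IV requires LW labels on matched pairs")
        tp = sum(1 for p, r in matches if p.lw == r.lw)
        misclassified = len(matches) - tp
        fp = (len(pred_s) - len(matches)) + misclassified
        fn = len(ref_s) - len(matches)
    else:
        tp = len(matches)
        fp = len(pred_s) - tp
        fn = len(ref_s) - tp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, variant=variant)


def ppv(counts: ConfusionCounts) -> float:
    """Precision tp/(tp+fp); 0 when the denominator is 0."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def tpr(counts: ConfusionCounts) -> float:
    """Sensitivity tp/(tp+fn); 0 when the denominator is 0."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def mcc(ppv_value: float, tpr_value: float) -> float:
    """Matthews coefficient in the TN-free sqrt(PPV x TPR) form."""
    if not (0 <= ppv_value <= 1 and 0 <= tpr_value <= 1):
        raise ValueError("ppv and tpr must lie in [0, 1]")
    return math.sqrt(ppv_value * tpr_value)


def evaluate_counts(counts: ConfusionCounts) -> EvaluationResult:
    p, t = ppv(counts), tpr(counts)
    return EvaluationResult(
        ppv=p, tpr=t, mcc=mcc(p, t), counts=counts,
        ppv_undefined=(counts.tp + counts.fp == 0),
        tpr_undefined=(counts.tp + counts.fn == 0),
    )


def evaluate(pred: SecondaryStructure, ref: SecondaryStructure,
             variant: Variant) -> EvaluationResult:
    """Compare two structures of equal length under one variant."""
    if pred.length != ref.length:
        raise EvaluationError(
            f"sequence length mismatch: predicted {pred.length}, reference {ref.length}"
        )
    return evaluate_counts(confusion(
        pairs_from_secondary_structure(pred),
        pairs_from_secondary_structure(ref),
        variant,
    ))


def arc_categories(pred: list[EvalPair], ref: list[EvalPair]) -> pd.DataFrame:
    """Arc-diagram table: TP_upper / FN_upper arcs above, FP_lower below."""
    pred_keys = {p.key for p in pred if not p.in_multiplet}
    ref_keys = {p.key for p in ref if not p.in_multiplet}
    rows = (
        [(i, j, "TP_upper") for i, j in sorted(ref_keys & pred_keys)]
        + [(i, j, "FN_upper") for i, j in sorted(ref_keys - pred_keys)]
        + [(i, j, "FP_lower") for i, j in sorted(pred_keys - ref_keys)]
    )
    return pd.DataFrame(rows, columns=["i", "j", "category"])


def percent_correct(n_correct: int, n_ref: int) -> float:
    """Percentage (2 dp, half-up) of reference pairs that were predicted."""
    if n_ref <= 0:
        raise EvaluationError("reference count must be positive")
    if n_correct > n_ref:
        raise EvaluationError("correct count exceeds reference count")
    return round_half_up(100.0 * n_correct / n_ref, 2)


@dataclass(slots=True)
class DatasetSummary:
    """Per-subset bookkeeping with the layout of a benchmark summary table."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def total_structures(self) -> int:
        return int(self.table["n_structures"].sum())


def summarize(records: list[tuple[str, ConfusionCounts]]) -> DatasetSummary:
    """Aggregate per-structure variant-III confusions by subset label.

    Per subset: number of structures, summed reference non-canonical pair
    count (tp+fn), correctly predicted count (tp), its percentage, and the
    total number of predicted pairs (tp+fp).
    """
    if not records:
        raise EvaluationError("no records to summarize")
    order: list[str] = []
    acc: dict[str, dict[str, int]] = {}
    for label, counts in records:
        if counts.variant is not Variant.III:
            raise EvaluationError("summaries are defined over variant III confusions")
        if label not in acc:
            order.append(label)
            acc[label] = {"n_structures": 0, "n_reference_noncanonical": 0,
                          "n_correct": 0, "n_predicted_total": 0}
        a = acc[label]
        a["n_structures"] += 1
        a["n_reference_noncanonical"] += counts.tp + counts.fn
        a["n_correct"] += counts.tp
        a["n_predicted_total"] += counts.tp + counts.fp
    rows = []
    for label in order:
        a = acc[label]
        if a["n_reference_noncanonical"] == 0:
            raise EvaluationError(f"subset {label!r} has no reference pairs")
        rows.append({
            "subset": label,
            **a,
            "percent": percent_correct(a["n_correct"], a["n_reference_noncanonical"]),
        })
    table = pd.DataFrame(rows).set_index("subset")[
        ["n_structures", "n_reference_noncanonical", "n_correct",
         "percent", "n_predicted_total"]
    ]
    return DatasetSummary(table=table)


def report_tsv(results: dict[Variant, EvaluationResult]) -> str:
    """CLI-facing TSV: variant, counts and 2-dp scores."""
    lines = ["variant\ttp\tfp\tfn\tppv\ttpr\tmcc"]
    for variant, res in results.items():
        lines.append(
            f"{variant.value}\t{res.counts.tp}\t{res.counts.fp}\t{res.counts.fn}\t"
            f"{round_half_up(res.ppv):.2f}\t{round_half_up(res.tpr):.2f}\t"
            f"{round_half_up(res.mcc):.2f}"
        )
    return "\n".join(lines) + "\n"
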