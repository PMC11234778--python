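"""Scoring merged (or raw per-caller) call sets against a truth set.

Matching follows the conventions used in bacterial SV benchmarking:
an interval prediction (DEL/DUP/INV) is a true positive when it
overlaps a same-class truth interval by at least 1 bp; an insertion
prediction matches when its breakpoint lies within ±50 bp of the truth
breakpoint.  A truth event matched by several (e.g. fragmented)
predictions counts once as TP and the extra predictions are not
penalised.  True negatives are undefined for interval detection unless
an explicit negative-region set is supplied, so accuracy and
specificity are only reported in that case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .merge import MergeParams, sweep_min_callers
from .model import SV_CLASSES, ConsensvError, GenomeInfo, MergedSV, SVCall, TruthSV


@dataclass(frozen=True)
class MatchingRules:
    """How predictions are matched to truth events.

    ins_window:
        Breakpoint tolerance in bp for insertions (default ±50).
    one_to_many:
        Whether several predictions may match one truth event (counted
        once truth-side).  When off, every extra prediction on an
        already-matched truth becomes a false positive.
    reciprocal_overlap:
        Optional stricter rule for interval classes: required mutual
        overlap fraction (e.g. 0.5); ``None`` (default) means any
        overlap of >= 1 bp.
    """

    ins_window: int = 50
    one_to_many: bool = True
    reciprocal_overlap: float | None = None

    def __post_init__(self) -> None:
        if self.ins_window < 0:
            raise ConsensvError("ins_window must be >= 0")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int | None = None

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn):
            if v < 0:
                raise ConsensvError("confusion counts must be non-negative")


@dataclass
class MatchResult:
    counts: ConfusionCounts
    #: truth_id -> list of matching prediction indices
    truth_matches: dict[str, list[int]] = field(default_factory=dict)
    #: prediction index -> list of matching truth ids
    pred_matches: dict[int, list[str]] = field(default_factory=dict)


def _is_match(pred, truth: TruthSV, rules: MatchingRules) -> bool:
    if pred.contig != truth.contig or pred.sv_class != truth.sv_class:
        return False
    if truth.sv_class == "INS":
        # distance from the truth breakpoint to the prediction footprint
        bp = truth.start
        if pred.start <= bp < pred.end:
            return True
        dist = min(abs(bp - pred.start), abs(bp - (pred.end - 1)))
        return dist <= rules.ins_window
    overlap = min(pred.end, truth.end) - max(pred.start, truth.start)
    if overlap < 1:
        return False
    if rules.reciprocal_overlap is not None:
        need = rules.reciprocal_overlap
        if overlap < need * (pred.end - pred.start) or overlap < need * (truth.end - truth.start):
            return False
    return True


def match_calls(
    predictions: Sequence[MergedSV | SVCall],
    truth: Sequence[TruthSV],
    rules: MatchingRules | None = None,
) -> MatchResult:
    """Match predictions to truth events and tally the confusion counts.

    Truth events with at least one match count once toward ``tp``;
    unmatched truth events are ``fn``; predictions matching no truth
    event are ``fp``.
    """
    if rules is None:
        rules = MatchingRules()
    for p in predictions:
        if p.sv_class not in SV_CLASSES:
            raise ConsensvError(f"unsupported prediction class {p.sv_class!r}")
    truth_matches: dict[str, list[int]] = {t.truth_id: [] for t in truth}
    pred_matches: dict[int, list[str]] = {i: [] for i in range(len(predictions))}
    for i, p in enumerate(predictions):
        for t in truth:
            if _is_match(p, t, rules):
                truth_matches[t.truth_id].append(i)
                pred_matches[i].append(t.truth_id)
    tp = sum(1 for ids in truth_matches.values() if ids)
    fn = len(truth) - tp
    fp = sum(1 for ids in pred_matches.values() if not ids)
    if not rules.one_to_many:
        # every matching prediction beyond the first per truth event is an FP
        extra = sum(max(0, len(ids) - 1) for ids in truth_matches.values())
        fp += extra
    return MatchResult(
        counts=ConfusionCounts(tp=tp, fp=fp, fn=fn),
        truth_matches=truth_matches,
        pred_matches=pred_matches,
    )


def match_with_negatives(
    predictions: Sequence[MergedSV | SVCall],
    truth: Sequence[TruthSV],
    negatives: Sequence[TruthSV],
    rules: MatchingRules | None = None,
) -> ConfusionCounts:
    """Event-wise scoring with an explicit negative-region set.

    ``negatives`` are regions asserted to carry no event of their
    class; a negative region counts as TN when no same-class prediction
    matches it (same overlap rule as truth matching).  This is the only
    route to defined accuracy/specificity — interval detection has no
    natural TN otherwise.
    """
    if rules is None:
        rules = MatchingRules()
    base = match_calls(predictions, truth, rules).counts
    tn = sum(
        1
        for neg in negatives
        if not any(_is_match(p, neg, rules) for p in predictions)
    )
    return ConfusionCounts(tp=base.tp, fp=base.fp, fn=base.fn, tn=tn)


def compute_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Performance metrics as percentages rounded to 1 decimal.

    ``sensitivity`` (= recall), ``precision`` and ``f1`` are always
    attempted; ``accuracy`` and ``specificity`` require ``tn``.
    Degenerate denominators yield ``None`` rather than an exception;
    F1 is computed directly as ``2·tp / (2·tp + fp + fn)`` so printed
    1-decimal rounding of P and R never distorts it.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    out: dict[str, float | None] = {}
    out["sensitivity"] = round(100 * tp / (tp + fn), 1) if tp + fn else None
    out["precision"] = round(100 * tp / (tp + fp), 1) if tp + fp else None
    out["f1"] = round(100 * 2 * tp / (2 * tp + fp + fn), 1) if 2 * tp + fp + fn else None
    if tn is not None:
        total = tp + tn + fp + fn
        out["accuracy"] = round(100 * (tp + tn) / total, 1) if total else None
        out["specificity"] = round(100 * tn / (tn + fp), 1) if tn + fp else None
    else:
        out["accuracy"] = None
        out["specificity"] = None
    return out


def evaluate_callset(
    predictions: Sequence[MergedSV | SVCall],
    truth: Sequence[TruthSV],
    rules: MatchingRules | None = None,
) -> pd.DataFrame:
    """Per-class and overall metric table (the EvalReport).

    Columns: sv_class, tp, fp, fn, sensitivity, precision, f1.
    The ``overall`` row pools the per-class counts.
    """
    if rules is None:
        rules = MatchingRules()
    rows = []
    totals = {"tp": 0, "fp": 0, "fn": 0}
    for sv_class in SV_CLASSES:
        preds = [p for p in predictions if p.sv_class == sv_class]
        truths = [t for t in truth if t.sv_class == sv_class]
        if not preds and not truths:
            continue
        res = match_calls(preds, truths, rules)
        c = res.counts
        totals["tp"] += c.tp
        totals["fp"] += c.fp
        totals["fn"] += c.fn
        rows.append({"sv_class": sv_class, "tp": c.tp, "fp": c.fp, "fn": c.fn,
                     **compute_metrics(c)})
    overall = ConfusionCounts(**totals)
    rows.append({"sv_class": "overall", **totals, **compute_metrics(overall)})
    df = pd.DataFrame(rows)
    return df.drop(columns=["accuracy", "specificity"])


def caller_overlap_table(merged: Iterable[MergedSV]) -> pd.DataFrame:
    """Membership table behind an UpSet plot: one row per distinct
    caller combination with its event count (counts sum to the number
    of events)."""
    combos: dict[str, int] = {}
    for e in merged:
        key = ",".join(sorted(e.callers))
        combos[key] = combos.get(key, 0) + 1
    rows = [
        {"callers": k, "n_callers": len(k.split(",")) if k else 0, "count": v}
        for k, v in combos.items()
    ]
    df = pd.DataFrame(rows, columns=["callers", "n_callers", "count"])
    return df.sort_values(["count", "callers"], ascending=[False, True]).reset_index(drop=True)


def pr_sweep(
    calls: Sequence[SVCall],
    truth: Sequence[TruthSV],
    genome: GenomeInfo,
    base_params: MergeParams,
    sv_class: str,
    thresholds: Sequence[int],
    rules: MatchingRules | None = None,
) -> pd.DataFrame:
    """Precision/recall/F1 of one SV class as its consensus threshold
    varies, other parameters fixed.

    Columns: threshold, n_events, tp, fp, fn, sensitivity, precision, f1.
    """
    if rules is None:
        rules = MatchingRules()
    truths = [t for t in truth if t.sv_class == sv_class]
    rows = []
    for k, n_events, events in sweep_min_callers(calls, genome, base_params, sv_class, thresholds):
        res = match_calls(events, truths, rules)
        c = res.counts
        rows.append({"threshold": k, "n_events": n_events, "tp": c.tp, "fp": c.fp,
                     "fn": c.fn, **compute_metrics(c)})
    return pd.DataFrame(rows).drop(columns=["accuracy", "specificity"])
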