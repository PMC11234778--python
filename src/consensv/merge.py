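"""Signal-summing consensus merging of multi-caller SV calls.

The model: per contig and per SV class, every caller's calls are turned
into a binary occupancy signal over the reference (1 where that caller
reports the rearrangement, 0 elsewhere; overlapping calls from the same
caller count once).  Each caller's signal is scaled by an integer weight
(default 1) and the weighted signals are summed, so a value of three
marks a region supported by three unit-weight callers.  Regions where
the sum reaches the class's ``minCallers`` threshold are kept; kept
regions closer together than ``maxGap`` are fused into one event.  For
each event we report the outer (widest) span, the *maxSup* interval —
the narrowest coordinates where support peaks — and a backtrack to the
original caller records (per-caller subevent counts and the fraction of
the event each caller covers).

DEL and DUP share one threshold (the CNV group); inversions and
insertions get their own, because fewer callers can call them.
Weighting exists chiefly so a trusted insertion specialist can be
counted double on INS: with a weight of 2 and ``min_callers_ins = 2``
its solo insertions pass the consensus on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    SV_CLASSES,
    ConsensvError,
    GenomeInfo,
    MergedSV,
    SVCall,
    sort_events,
    validate_calls,
)
from .vcf_io import dedup_calls

Segment = tuple[int, int]

#: Caller treated as the insertion specialist in the default weighting.
INSERTION_SPECIALIST = "insurveyor"


def resolve_weight(
    weights: Mapping[str, int | Mapping[str, int]], caller: str, sv_class: str
) -> int:
    """Weight of ``caller`` for ``sv_class``.

    ``weights`` maps a caller either to a flat integer (all classes) or
    to a per-class map; absent entries default to 1.
    """
    w = weights.get(caller, 1)
    if isinstance(w, Mapping):
        w = w.get(sv_class, 1)
    w = int(w)
    if w < 1:
        raise ConsensvError(f"weight for {caller!r}/{sv_class} must be >= 1, got {w}")
    return w


def default_weights() -> dict[str, dict[str, int]]:
    """Unit weights everywhere except the insertion specialist, counted
    double on INS."""
    return {INSERTION_SPECIALIST: {"INS": 2}}


@dataclass(frozen=True)
class MergeParams:
    """Tuning knobs of the consensus merge.

    min_callers_cnv / min_callers_inv / min_callers_ins:
        Minimal weighted caller support required to report a region, set
        separately for the CNV group (DEL + DUP), inversions and
        insertions.  Default 2 for all three.
    max_gap:
        Maximal distance in bp between supra-threshold regions still
        fused into one event.  Default 100 bp (configurable; there is no
        canonical value).
    weights:
        Per-caller (optionally per-class) integer weights.
    """

    min_callers_cnv: int = 2
    min_callers_inv: int = 2
    min_callers_ins: int = 2
    max_gap: int = 100
    weights: Mapping[str, int | Mapping[str, int]] = field(default_factory=default_weights)

    def __post_init__(self) -> None:
        for name in ("min_callers_cnv", "min_callers_inv", "min_callers_ins"):
            if getattr(self, name) < 1:
                raise ConsensvError(f"{name} must be >= 1")
        if self.max_gap < 0:
            raise ConsensvError("max_gap must be >= 0")

    def threshold_for(self, sv_class: str) -> int:
        if sv_class in ("DEL", "DUP"):
            return self.min_callers_cnv
        if sv_class == "INV":
            return self.min_callers_inv
        if sv_class == "INS":
            return self.min_callers_ins
        raise ConsensvError(f"unsupported SV class {sv_class!r}")

    def weight(self, caller: str, sv_class: str) -> int:
        return resolve_weight(self.weights, caller, sv_class)

    def with_threshold(self, sv_class: str, value: int) -> "MergeParams":
        if sv_class in ("DEL", "DUP"):
            return replace(self, min_callers_cnv=value)
        if sv_class == "INV":
            return replace(self, min_callers_inv=value)
        if sv_class == "INS":
            return replace(self, min_callers_ins=value)
        raise ConsensvError(f"unsupported SV class {sv_class!r}")


@dataclass
class SignalTrack:
    """Weighted occupancy signal for one contig and one SV class."""

    contig: str
    sv_class: str
    values: np.ndarray  # int array, length == contig length

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)


def build_class_signal(
    calls: Sequence[SVCall],
    genome_length: int,
    weights: Mapping[str, int | Mapping[str, int]] | None = None,
) -> SignalTrack:
    """Sum the per-caller binary occupancy signals for one contig/class.

    Each caller contributes the union of its intervals (binary — a
    caller's overlapping calls count once), scaled by its weight.
    """
    if weights is None:
        weights = {}
    if not calls:
        raise ConsensvError("build_class_signal requires at least one call")
    contig = calls[0].contig
    sv_class = calls[0].sv_class
    for c in calls:
        if c.contig != contig or c.sv_class != sv_class:
            raise ConsensvError("build_class_signal: calls must share contig and class")
        if c.end > genome_length:
            raise ConsensvError(
                f"call {c.key()} exceeds genome length {genome_length}"
            )
    total = np.zeros(genome_length, dtype=np.int64)
    by_caller: dict[str, list[SVCall]] = {}
    for c in calls:
        by_caller.setdefault(c.caller, []).append(c)
    for caller, caller_calls in by_caller.items():
        diff = np.zeros(genome_length + 1, dtype=np.int64)
        for c in caller_calls:
            diff[c.start] += 1
            diff[c.end] -= 1
        occupancy = np.cumsum(diff[:-1]) > 0
        total += occupancy * resolve_weight(weights, caller, sv_class)
    return SignalTrack(contig=contig, sv_class=sv_class, values=total)


def threshold_segments(track: SignalTrack, min_callers: int) -> list[Segment]:
    """Maximal runs where the summed signal reaches ``min_callers``."""
    if min_callers < 1:
        raise ConsensvError("min_callers must be >= 1")
    mask = track.values >= min_callers
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def gap_merge(segments: Sequence[Segment], max_gap: int) -> list[Segment]:
    """Fuse consecutive segments separated by at most ``max_gap`` bp.

    Fusion is transitive; the result is disjoint with all inter-segment
    gaps strictly greater than ``max_gap``.
    """
    if max_gap < 0:
        raise ConsensvError("max_gap must be >= 0")
    out: list[Segment] = []
    for s, e in segments:
        if out and s - out[-1][1] <= max_gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def compute_maxsup(track: SignalTrack, span: Segment) -> tuple[int, int, int]:
    """Peak support and its narrowest coordinates within an event span.

    Returns ``(maxsup_start, maxsup_end, support)`` where support is the
    maximum signal value inside ``span`` and the maxSup interval is the
    longest maximal run attaining it (leftmost on ties).
    """
    s, e = span
    vals = track.values[s:e]
    if len(vals) == 0:
        raise ConsensvError(f"empty span {span}")
    support = int(vals.max())
    if support <= 0:
        raise ConsensvError(f"span {span} carries no signal")
    mask = vals == support
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]
    best = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    return (s + best[0], s + best[1], support)


def backtrack(
    event_span: Segment, calls: Iterable[SVCall]
) -> tuple[frozenset[str], dict[str, int], dict[str, float]]:
    """Re-associate an event span with the original caller records.

    For each caller with at least one call overlapping the span:
    ``subevents`` is the count of its overlapping calls and ``coverage``
    the fraction of the span covered by the union of those calls
    (clipped to the span).
    """
    s, e = event_span
    span_len = e - s
    subevents: dict[str, int] = {}
    per_caller: dict[str, list[Segment]] = {}
    for c in calls:
        if c.start < e and c.end > s:
            subevents[c.caller] = subevents.get(c.caller, 0) + 1
            per_caller.setdefault(c.caller, []).append((max(c.start, s), min(c.end, e)))
    coverage: dict[str, float] = {}
    for caller, segs in per_caller.items():
        segs.sort()
        covered = 0
        cur_s, cur_e = segs[0]
        for ns, ne in segs[1:]:
            if ns <= cur_e:
                cur_e = max(cur_e, ne)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = ns, ne
        covered += cur_e - cur_s
        coverage[caller] = covered / span_len
    return frozenset(subevents), subevents, coverage


def merge_all(
    calls: Sequence[SVCall], genome: GenomeInfo, params: MergeParams | None = None
) -> list[MergedSV]:
    """Run the full consensus merge over all contigs and SV classes.

    Classes never mix: each (contig, class) pair gets its own summed
    signal, thresholded with the class-appropriate ``minCallers``, gap
    fused, and backtracked.  Output is sorted by contig (genome order),
    start, class.  Per-caller duplicate records are dropped first.
    """
    if params is None:
        params = MergeParams()
    validate_calls(calls, genome)
    calls = dedup_calls(calls)
    events: list[MergedSV] = []
    for contig, length in genome.contigs:
        for sv_class in SV_CLASSES:
            subset = [c for c in calls if c.contig == contig and c.sv_class == sv_class]
            if not subset:
                continue
            track = build_class_signal(subset, length, params.weights)
            segments = threshold_segments(track, params.threshold_for(sv_class))
            for span in gap_merge(segments, params.max_gap):
                ms, me, support = compute_maxsup(track, span)
                callers, subevents, coverage = backtrack(span, subset)
                events.append(
                    MergedSV(
                        contig=contig,
                        sv_class=sv_class,
                        start=span[0],
                        end=span[1],
                        maxsup_start=ms,
                        maxsup_end=me,
                        support=support,
                        callers=callers,
                        subevents=subevents,
                        coverage=coverage,
                    )
                )
    return sort_events(events, genome)


def sweep_min_callers(
    calls: Sequence[SVCall],
    genome: GenomeInfo,
    base_params: MergeParams,
    sv_class: str,
    values: Sequence[int],
) -> list[tuple[int, int, list[MergedSV]]]:
    """Re-merge at each threshold in ``values`` (ascending), other
    parameters fixed.  Returns ``(threshold, event count, events)`` rows,
    with events filtered to ``sv_class``.
    """
    if list(values) != sorted(values):
        raise ConsensvError("threshold values must be sorted ascending")
    callers = {c.caller for c in calls}
    max_support = sum(resolve_weight(base_params.weights, c, sv_class) for c in callers)
    rows = []
    for k in values:
        if k > max_support:
            raise ConsensvError(
                f"threshold {k} exceeds total weighted caller support {max_support} "
                f"for class {sv_class}"
            )
        merged = merge_all(calls, genome, base_params.with_threshold(sv_class, k))
        merged = [e for e in merged if e.sv_class == sv_class]
        rows.append((k, len(merged), merged))
    return rows
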