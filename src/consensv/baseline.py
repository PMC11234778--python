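"""Baseline and oracle mergers.

Two reference implementations live here:

* :func:`survivor_merge` — an interval-distance consensus rule in the
  style of the SURVIVOR toolkit: two same-class calls belong together
  when both their start and their end coordinates lie within a maximum
  distance (1 kbp in the canonical setting), closed under single
  linkage.
* :func:`bruteforce_signal_merge` — a deliberately unoptimised
  per-base re-statement of the signal-summing merge, used as the
  differential-testing oracle for :func:`consensv.merge.merge_all`.
  It materializes every signal literally as a Python list and scans it
  position by position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .merge import MergeParams, resolve_weight
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

#: Largest total genome length the brute-force oracle will accept.
ORACLE_GENOME_CAP = 100_000


@dataclass(frozen=True)
class SurvivorParams:
    """Settings of the interval-distance merger.

    The canonical benchmarking configuration is ``max_distance=1000``,
    ``min_callers=2``, ``min_sv_len=1``.
    """

    max_distance: int = 1000
    min_callers: int = 2
    min_sv_len: int = 1

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise ConsensvError("max_distance must be >= 0")
        if self.min_callers < 1:
            raise ConsensvError("min_callers must be >= 1")


def _lower_median(values: Sequence[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def survivor_merge(calls: Sequence[SVCall], params: SurvivorParams | None = None) -> list[MergedSV]:
    """Cluster same-class calls whose breakpoints agree within a distance.

    Two calls of the same class on the same contig are linked when
    ``|startA - startB| <= max_distance`` and ``|endA - endB| <=
    max_distance``; clusters are the single-linkage closure of that
    relation.  Clusters supported by at least ``min_callers`` distinct
    callers are emitted with outer coordinates (min start, max end);
    the maxSup fields carry the lower-median start and end of the
    cluster members (a documented representative convention — support
    here is the distinct-caller count, there is no summed signal).
    """
    if params is None:
        params = SurvivorParams()
    calls = [c for c in dedup_calls(calls) if c.length >= params.min_sv_len]
    events: list[MergedSV] = []
    groups: dict[tuple[str, str], list[SVCall]] = {}
    for c in calls:
        groups.setdefault((c.contig, c.sv_class), []).append(c)
    for (contig, sv_class), members in sorted(groups.items()):
        members = sorted(members, key=lambda c: (c.start, c.end, c.caller))
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = members[i], members[j]
                if (
                    abs(a.start - b.start) <= params.max_distance
                    and abs(a.end - b.end) <= params.max_distance
                ):
                    parent[find(i)] = find(j)
        clusters: dict[int, list[SVCall]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(members[i])
        for cluster in clusters.values():
            callers = frozenset(c.caller for c in cluster)
            if len(callers) < params.min_callers:
                continue
            start = min(c.start for c in cluster)
            end = max(c.end for c in cluster)
            ms = _lower_median([c.start for c in cluster])
            me = _lower_median([c.end for c in cluster])
            if not (start <= ms < me <= end):  # degenerate medians
                ms, me = start, end
            subevents: dict[str, int] = {}
            per_caller: dict[str, list[tuple[int, int]]] = {}
            for c in cluster:
                subevents[c.caller] = subevents.get(c.caller, 0) + 1
                per_caller.setdefault(c.caller, []).append((c.start, c.end))
            span_len = end - start
            coverage = {}
            for caller, segs in per_caller.items():
                segs.sort()
                covered, cur_s, cur_e = 0, *segs[0]
                for ns, ne in segs[1:]:
                    if ns <= cur_e:
                        cur_e = max(cur_e, ne)
                    else:
                        covered += cur_e - cur_s
                        cur_s, cur_e = ns, ne
                covered += cur_e - cur_s
                coverage[caller] = covered / span_len
            events.append(
                MergedSV(
                    contig=contig,
                    sv_class=sv_class,
                    start=start,
                    end=end,
                    maxsup_start=ms,
                    maxsup_end=me,
                    support=len(callers),
                    callers=callers,
                    subevents=subevents,
                    coverage=coverage,
                )
            )
    return sorted(events, key=lambda e: (e.contig, e.start, SV_CLASSES.index(e.sv_class)))


def bruteforce_signal_merge(
    calls: Sequence[SVCall], genome: GenomeInfo, params: MergeParams | None = None
) -> list[MergedSV]:
    """Literal per-base restatement of the signal-summing merge.

    Builds every occupancy signal as a plain Python list, scans it
    position by position, and applies the stated rules (threshold runs,
    gap fusion, longest-then-leftmost peak run, per-base backtrack
    coverage) with no shortcuts.  Only for small genomes (total length
    at most ``ORACLE_GENOME_CAP``); use
    :func:`consensv.merge.merge_all` for real data.
    """
    if params is None:
        params = MergeParams()
    if genome.total_length > ORACLE_GENOME_CAP:
        raise ConsensvError(
            f"genome of {genome.total_length} bp exceeds the {ORACLE_GENOME_CAP} bp "
            "oracle cap; use merge.merge_all"
        )
    validate_calls(calls, genome)
    calls = dedup_calls(calls)
    events: list[MergedSV] = []
    for contig, length in genome.contigs:
        for sv_class in SV_CLASSES:
            subset = [c for c in calls if c.contig == contig and c.sv_class == sv_class]
            if not subset:
                continue
            callers = sorted({c.caller for c in subset})
            # per-caller binary signals, then the weighted sum
            binary: dict[str, list[int]] = {}
            for caller in callers:
                sig = [0] * length
                for c in subset:
                    if c.caller == caller:
                        for pos in range(c.start, c.end):
                            sig[pos] = 1
                binary[caller] = sig
            summed = [0] * length
            for caller in callers:
                w = resolve_weight(params.weights, caller, sv_class)
                sig = binary[caller]
                for pos in range(length):
                    summed[pos] += w * sig[pos]
            # maximal runs at or above the class threshold
            threshold = params.threshold_for(sv_class)
            runs: list[tuple[int, int]] = []
            pos = 0
            while pos < length:
                if summed[pos] >= threshold:
                    start = pos
                    while pos < length and summed[pos] >= threshold:
                        pos += 1
                    runs.append((start, pos))
                else:
                    pos += 1
            # transitive gap fusion
            spans: list[tuple[int, int]] = []
            for s, e in runs:
                if spans and s - spans[-1][1] <= params.max_gap:
                    spans[-1] = (spans[-1][0], e)
                else:
                    spans.append((s, e))
            for s, e in spans:
                support = max(summed[s:e])
                # longest, then leftmost, run at the peak value
                best_s = best_e = -1
                pos = s
                while pos < e:
                    if summed[pos] == support:
                        rs = pos
                        while pos < e and summed[pos] == support:
                            pos += 1
                        if pos - rs > best_e - best_s:
                            best_s, best_e = rs, pos
                    else:
                        pos += 1
                subevents: dict[str, int] = {}
                coverage: dict[str, float] = {}
                for caller in callers:
                    count = sum(
                        1
                        for c in subset
                        if c.caller == caller and c.start < e and c.end > s
                    )
                    if count == 0:
                        continue
                    subevents[caller] = count
                    covered = sum(binary[caller][pos] for pos in range(s, e))
                    coverage[caller] = covered / (e - s)
                events.append(
                    MergedSV(
                        contig=contig,
                        sv_class=sv_class,
                        start=s,
                        end=e,
                        maxsup_start=best_s,
                        maxsup_end=best_e,
                        support=support,
                        callers=frozenset(subevents),
                        subevents=subevents,
                        coverage=coverage,
                    )
                )
    return sort_events(events, genome)
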