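"""Synthetic multi-caller SV datasets.

Emulates, at the *call* level, the artificial benchmark design used for
bacterial SV consensus studies: a megabase-scale genome carrying 100
randomly placed truth events per class (deletion, duplication,
inversion, insertion) with lengths between 50 and 10,000 bp, observed
through several imperfect callers.  Caller imperfection is modelled
with a per-caller error profile — missed events, breakpoint jitter,
false positives, fragmentation of long events into several shorter
calls, and class confusion (inversions reported as duplications).

No reads are simulated and no external caller is run; the error
profiles describe caller *behaviour*, not its mechanism.  The coverage
presets ("5x", "20x", "100x") are illustrative mappings from sequencing
depth to error severity chosen by this package, not measured caller
characteristics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pysam

from .model import SV_CLASSES, ConsensvError, GenomeInfo, SVCall, TruthSV

#: Default synthetic chromosome: one 4 Mb contig, the scale of an
#: Escherichia coli genome.
DEFAULT_GENOME_LENGTH = 4_000_000


def default_genome(length: int = DEFAULT_GENOME_LENGTH, name: str = "chr1") -> GenomeInfo:
    return GenomeInfo(((name, length),))


@dataclass(frozen=True)
class TruthSpec:
    """Recipe for a ground-truth event set.

    100 events per class with lengths uniform in 50–10,000 bp, placed
    without overlap and with at least ``min_spacing`` bp between
    consecutive events.  The 500 bp default spacing keeps distinct truth
    events from abutting, so consensus events map one-to-one onto truth
    under the default 100 bp maxGap.
    """

    genome: GenomeInfo = field(default_factory=default_genome)
    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {c: 100 for c in SV_CLASSES}
    )
    length_range: tuple[int, int] = (50, 10_000)
    min_spacing: int = 500
    seed: int = 0


@dataclass(frozen=True)
class CallerProfile:
    """Error model for one synthetic caller.

    miss_rate:
        Probability of not reporting a truth event of a handled class.
    jitter_sd:
        Standard deviation (bp) of rounded-normal noise applied
        independently to each breakpoint (position only, for
        insertions).
    fp_rate:
        Expected false calls per Mb per handled class (Poisson).
    fragmentation:
        ``(probability, expected fragment count)`` — with the given
        probability a long event is reported as several sub-calls whose
        union stays inside the (jittered) event span, separated by small
        internal gaps.
    confusion:
        ``{(true class, reported class): probability}``; applied only
        when the caller can call the reported class.
    """

    name: str
    classes_called: frozenset[str]
    miss_rate: float = 0.0
    jitter_sd: float = 0.0
    fp_rate: float = 0.0
    fragmentation: tuple[float, float] = (0.0, 0.0)
    confusion: Mapping[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.miss_rate, self.fp_rate, self.fragmentation[0], *self.confusion.values()):
            if p < 0:
                raise ConsensvError(f"profile {self.name}: negative probability/rate")
        if not (0 <= self.miss_rate <= 1 and 0 <= self.fragmentation[0] <= 1):
            raise ConsensvError(f"profile {self.name}: probabilities must be in [0,1]")
        unknown = set(self.classes_called) - set(SV_CLASSES)
        if unknown:
            raise ConsensvError(f"profile {self.name}: unknown classes {sorted(unknown)}")


#: Smallest event length eligible for fragmentation: below this a
#: "fragmented" report would be indistinguishable from jitter.
_MIN_FRAGMENT_SPAN = 300
#: Largest internal gap between fragments of one event, in bp.
_MAX_FRAGMENT_GAP = 50


def simulate_truth(spec: TruthSpec) -> list[TruthSV]:
    """Draw a non-overlapping ground-truth event set, reproducibly.

    Events are laid out left to right: class labels are shuffled, the
    residual free space (after event widths and mandatory spacing) is
    split by sorted uniform draws, and each event is shifted by its
    share.  This guarantees exact per-class counts, uniform lengths and
    feasible placement in one pass.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    if not (0 < lo <= hi):
        raise ConsensvError("invalid length_range")
    items: list[tuple[str, int, int | None]] = []  # (class, width, ins_len)
    for sv_class in SV_CLASSES:
        n = int(spec.n_per_class.get(sv_class, 0))
        for _ in range(n):
            length = int(rng.integers(lo, hi + 1))
            if sv_class == "INS":
                items.append((sv_class, 1, length))
            else:
                items.append((sv_class, length, None))
    if not items:
        return []
    rng.shuffle(items)
    # pack across contigs proportionally to contig length
    truths: list[TruthSV] = []
    remaining = list(items)
    counters = {c: 0 for c in SV_CLASSES}
    for ci, (contig, length) in enumerate(spec.genome.contigs):
        if ci == len(spec.genome.contigs) - 1:
            share = remaining
        else:
            frac = length / spec.genome.total_length
            k = min(len(remaining), int(round(frac * len(items))))
            share = remaining[:k]
        remaining = remaining[len(share):]
        if not share:
            continue
        widths = [w for _, w, _ in share]
        needed = sum(widths) + spec.min_spacing * len(share)
        slack = length - needed
        if slack < 0:
            raise ConsensvError(
                f"cannot place {len(share)} events ({needed} bp incl. spacing) on "
                f"contig {contig!r} of {length} bp; use a larger genome"
            )
        offsets = np.sort(rng.integers(0, slack + 1, size=len(share)))
        cursor = 0
        for (sv_class, width, ins_len), off in zip(share, offsets):
            start = int(cursor + off)
            counters[sv_class] += 1
            truths.append(
                TruthSV(
                    contig=contig,
                    sv_class=sv_class,
                    start=start,
                    end=start + width,
                    truth_id=f"{sv_class}_{counters[sv_class]:04d}",
                    ins_len=ins_len,
                )
            )
            cursor = start + width + spec.min_spacing - off
    if remaining:
        raise ConsensvError("internal packing error: unplaced events")
    return sorted(truths, key=lambda t: (t.contig, t.start))


def _jitter(rng: np.random.Generator, value: int, sd: float) -> int:
    if sd <= 0:
        return value
    return value + int(round(rng.normal(0.0, sd)))


def _fragment_span(
    rng: np.random.Generator, s: int, e: int, expected_k: float
) -> list[tuple[int, int]]:
    """Split ``[s, e)`` into >= 2 sub-intervals separated by small gaps.

    The union of the fragments stays inside the span; every fragment is
    at least 2 bp wide and internal gaps are 1..`_MAX_FRAGMENT_GAP` bp.
    """
    span = e - s
    k = max(2, min(int(rng.poisson(expected_k)), span // 100))
    gaps = [int(rng.integers(1, _MAX_FRAGMENT_GAP + 1)) for _ in range(k - 1)]
    extra = span - sum(gaps) - 2 * k
    cuts = np.sort(rng.integers(0, extra + 1, size=k - 1))
    shares = np.diff(np.concatenate(([0], cuts, [extra])))
    widths = [2 + int(w) for w in shares]
    out = []
    pos = s
    for i, w in enumerate(widths):
        out.append((pos, pos + w))
        pos += w + (gaps[i] if i < k - 1 else 0)
    return out


def emit_caller_calls(
    truth: Sequence[TruthSV], profile: CallerProfile, genome: GenomeInfo
) -> list[SVCall]:
    """Observe a truth set through one caller's error profile.

    Reproducible under ``profile.seed``.  Every emitted non-FP call
    derives from exactly one truth event; with zero jitter its span
    stays inside the truth span (fragmentation shrinks, never grows).
    """
    rng = np.random.default_rng(profile.seed)
    lengths = genome.lengths
    calls: list[SVCall] = []
    serial = 0
    frag_p, frag_n = profile.fragmentation
    for t in truth:
        # class confusion first: the event may surface under another label
        reported = t.sv_class
        for (src, dst), p in sorted(profile.confusion.items()):
            if src == t.sv_class and dst in profile.classes_called and rng.random() < p:
                reported = dst
                break
        if reported not in profile.classes_called:
            continue
        if rng.random() < profile.miss_rate:
            continue
        L = lengths[t.contig]
        serial += 1
        sid = f"{profile.name}_{serial:05d}"
        if reported == "INS" and t.sv_class == "INS":
            pos = _jitter(rng, t.start, profile.jitter_sd)
            pos = max(0, min(pos, L - 1))
            calls.append(
                SVCall(profile.name, t.contig, "INS", pos, pos + 1, svlen=t.ins_len, source_id=sid)
            )
            continue
        s = _jitter(rng, t.start, profile.jitter_sd)
        e = _jitter(rng, t.end, profile.jitter_sd)
        if e < s:
            s, e = e, s
        s = max(0, min(s, L - 2))
        e = max(s + 2, min(e, L))  # >= 2 bp: a 1 bp symbolic record has no usable END
        if reported == "INS":  # interval event confused into an insertion call
            calls.append(SVCall(profile.name, t.contig, "INS", s, s + 1, source_id=sid))
            continue
        if frag_p > 0 and e - s >= _MIN_FRAGMENT_SPAN and rng.random() < frag_p:
            for fi, (fs, fe) in enumerate(_fragment_span(rng, s, e, frag_n)):
                calls.append(
                    SVCall(profile.name, t.contig, reported, fs, fe,
                           source_id=f"{sid}_f{fi + 1}")
                )
        else:
            calls.append(SVCall(profile.name, t.contig, reported, s, e, source_id=sid))
    # false positives: Poisson per handled class, anywhere on the genome
    lo, hi = 50, 10_000
    for contig, L in genome.contigs:
        for sv_class in sorted(profile.classes_called):
            n_fp = int(rng.poisson(profile.fp_rate * L / 1e6))
            for j in range(n_fp):
                serial += 1
                if sv_class == "INS":
                    pos = int(rng.integers(0, L - 1))
                    calls.append(
                        SVCall(profile.name, contig, "INS", pos, pos + 1,
                               svlen=int(rng.integers(lo, hi + 1)),
                               source_id=f"{profile.name}_fp{serial:05d}")
                    )
                else:
                    length = int(rng.integers(lo, min(hi, L - 1) + 1))
                    start = int(rng.integers(0, L - length))
                    calls.append(
                        SVCall(profile.name, contig, sv_class, start, start + length,
                               source_id=f"{profile.name}_fp{serial:05d}")
                    )
    return sorted(calls, key=lambda c: (c.contig, c.sv_class, c.start, c.end))


# ---------------------------------------------------------------------------
# default caller panel

#: Class capabilities of the default six-caller panel: four callers
#: handle the breakpoint classes, two are depth-based CNV callers, one
#: is an insertion specialist.
PANEL_CLASSES: dict[str, frozenset[str]] = {
    "delly2": frozenset({"DEL", "DUP", "INV", "INS"}),
    "lumpy": frozenset({"DEL", "DUP", "INV", "INS"}),
    "pindel": frozenset({"DEL", "DUP", "INV", "INS"}),
    "cnvnator": frozenset({"DEL", "DUP"}),
    "cnproscan": frozenset({"DEL", "DUP"}),
    "insurveyor": frozenset({"INS"}),
}

#: Coverage-tier noise presets (our own illustrative mapping from depth
#: to error severity): (miss_rate, jitter_sd, fp_rate, frag_prob).
PRESETS: dict[str, tuple[float, float, float, float]] = {
    "clean": (0.0, 0.0, 0.0, 0.0),
    "5x": (0.35, 60.0, 3.0, 0.25),
    "20x": (0.15, 30.0, 1.5, 0.20),
    "100x": (0.05, 15.0, 1.0, 0.15),
}


def default_profiles(preset: str = "20x", seed: int = 0) -> list[CallerProfile]:
    """The six-caller default panel under a named noise preset.

    Split-read callers confuse a small share of inversions into
    duplications; the two CNV callers are noisier on false positives;
    the insertion specialist misses fewer insertions.  Per-caller seeds
    are derived deterministically from ``seed``.
    """
    try:
        miss, jitter, fp, frag_p = PRESETS[preset]
    except KeyError:
        raise ConsensvError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    profiles = []
    for i, (name, classes) in enumerate(PANEL_CLASSES.items()):
        m, f = miss, fp
        confusion: dict[tuple[str, str], float] = {}
        if preset != "clean":
            if name in ("pindel", "cnproscan"):
                f = fp * 2.0  # the chatty callers
            if name == "insurveyor":
                m = miss / 2.0
            if "INV" in classes and "DUP" in classes:
                confusion[("INV", "DUP")] = 0.05
        profiles.append(
            CallerProfile(
                name=name,
                classes_called=classes,
                miss_rate=m,
                jitter_sd=jitter,
                fp_rate=f,
                fragmentation=(frag_p, 3.0),
                confusion=confusion,
                seed=(seed * 1009 + i * 101) % (2**31 - 1),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# VCF emission


def write_caller_vcfs(
    calls_by_caller: Mapping[str, Sequence[SVCall]],
    genome: GenomeInfo,
    directory: str,
) -> dict[str, str]:
    """Write one minimal valid VCF per caller; returns caller → path.

    Interval classes carry SVTYPE and END (via the record end);
    insertions carry SVTYPE and, when known, SVLEN.  The files parse
    back through :func:`consensv.vcf_io.read_caller_vcf` to the
    identical call multiset.
    """
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    for caller, calls in sorted(calls_by_caller.items()):
        header = pysam.VariantHeader()
        for name, length in genome.contigs:
            header.contigs.add(name, length=length)
        header.info.add("SVTYPE", 1, "String", "Type of structural variant")
        header.info.add("END", 1, "Integer", "End position of the variant")
        header.info.add("SVLEN", 1, "Integer", "Length of the variant")
        path = os.path.join(directory, f"{caller}.vcf")
        with pysam.VariantFile(path, "w", header=header) as out:
            ordered = sorted(calls, key=lambda c: (genome.contig_index(c.contig), c.start, c.end))
            for i, c in enumerate(ordered):
                rec = out.new_record(
                    contig=c.contig,
                    start=c.start,
                    stop=c.end,
                    alleles=("N", f"<{c.sv_class}>"),
                    id=c.source_id or f"{caller}_{i + 1}",
                    info={"SVTYPE": c.sv_class},
                )
                if c.sv_class == "INS" and c.svlen is not None:
                    # SVLEN after the end: htslib rederives END from SVLEN
                    # for interval classes, so those records never carry it
                    rec.info["SVLEN"] = int(c.svlen)
                out.write(rec)
        paths[caller] = path
    return paths
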