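"""Core domain types shared across the package.

All coordinates are 0-based, half-open ``[start, end)``.  VCF input
(1-based, END inclusive) is converted at the I/O boundary and nowhere
else.  Insertions are represented as width-1 footprints at the
breakpoint (``end == start + 1``); the inserted-sequence length, when
known, lives in :attr:`SVCall.svlen`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

#: The four supported structural-variant classes, in canonical order.
#: DEL and DUP together form the copy-number (CNV) group that shares one
#: consensus threshold.
SV_CLASSES: tuple[str, ...] = ("DEL", "DUP", "INV", "INS")

_CLASS_ORDER = {c: i for i, c in enumerate(SV_CLASSES)}


class ConsensvError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class GenomeInfo:
    """Ordered set of reference contigs with their lengths in bp.

    Bacterial samples typically carry one chromosome plus plasmids;
    every contig is processed independently (signals are linear, never
    wrapped across the replication origin of a circular chromosome).
    """

    contigs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        for name, length in self.contigs:
            if length < 1:
                raise ValueError(f"contig {name!r} has non-positive length {length}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeInfo":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @classmethod
    def from_fai(cls, path: str) -> "GenomeInfo":
        """Read a FASTA-index style table (contig name, length in the
        first two whitespace-separated columns)."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                pairs.append((fields[0], int(fields[1])))
        if not pairs:
            raise ValueError(f"no contigs found in {path}")
        return cls.from_pairs(pairs)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.contigs)

    def length_of(self, contig: str) -> int:
        try:
            return self.lengths[contig]
        except KeyError:
            raise ConsensvError(f"contig {contig!r} not present in genome") from None

    def contig_index(self, contig: str) -> int:
        for i, (n, _) in enumerate(self.contigs):
            if n == contig:
                return i
        raise ConsensvError(f"contig {contig!r} not present in genome")


@dataclass(frozen=True)
class SVCall:
    """One normalized call from one caller.

    ``raw_info`` and ``source_id`` are provenance only and excluded from
    equality so that a write/read round trip compares clean.
    """

    caller: str
    contig: str
    sv_class: str
    start: int
    end: int
    svlen: int | None = None
    source_id: str = field(default="", compare=False)
    raw_info: Mapping[str, str] = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unsupported SV class {self.sv_class!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.caller} {self.sv_class}"
            )
        if self.sv_class == "INS" and self.end != self.start + 1:
            raise ValueError("insertions must have a width-1 footprint (end == start + 1)")

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, str, str, int, int]:
        """Identity used for per-caller deduplication."""
        return (self.caller, self.contig, self.sv_class, self.start, self.end)


@dataclass(frozen=True)
class TruthSV:
    """A ground-truth event for benchmarking.

    For insertions the interval is the width-1 breakpoint footprint and
    ``ins_len`` stores the length of the inserted sequence.
    """

    contig: str
    sv_class: str
    start: int
    end: int
    truth_id: str
    ins_len: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unsupported SV class {self.sv_class!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}) for {self.truth_id}")


@dataclass(frozen=True)
class MergedSV:
    """One consensus event produced by a merging backend.

    ``start``/``end`` are the outer (widest) coordinates; ``maxsup_*``
    the narrowest interval at which weighted caller support peaks.
    ``support`` is that peak weighted sum.  ``subevents`` counts each
    contributing caller's original calls overlapping the event and
    ``coverage`` the fraction of the outer span its calls cover.
    """

    contig: str
    sv_class: str
    start: int
    end: int
    maxsup_start: int
    maxsup_end: int
    support: int
    callers: frozenset[str]
    subevents: Mapping[str, int] = field(default_factory=dict)
    coverage: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.start <= self.maxsup_start < self.maxsup_end <= self.end):
            raise ValueError(
                f"maxsup [{self.maxsup_start},{self.maxsup_end}) not nested in "
                f"[{self.start},{self.end})"
            )

    @property
    def n_callers(self) -> int:
        return len(self.callers)

    @property
    def length(self) -> int:
        return self.end - self.start


def validate_calls(calls: Iterable[SVCall], genome: GenomeInfo) -> None:
    """Check every call lies within its contig; raise on the first violation."""
    lengths = genome.lengths
    for c in calls:
        if c.contig not in lengths:
            raise ConsensvError(f"call {c.source_id or c.key()} on unknown contig {c.contig!r}")
        if c.end > lengths[c.contig]:
            raise ConsensvError(
                f"call {c.source_id or c.key()} ends at {c.end} beyond contig "
                f"{c.contig!r} length {lengths[c.contig]}"
            )


def sort_events(events: list[MergedSV], genome: GenomeInfo) -> list[MergedSV]:
    """Canonical output order: contig (genome order), start, class."""
    return sorted(
        events,
        key=lambda e: (genome.contig_index(e.contig), e.start, _CLASS_ORDER[e.sv_class]),
    )
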