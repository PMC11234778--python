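"""Reading heterogeneous caller VCFs and the package's TSV formats.

The six commonly used bacterial SV callers (DELLY2, LUMPY, Pindel,
CNVnator, CNproScan, INSurVeyor) emit VCF 4.x with different mixes of
symbolic ALT alleles and SVTYPE/END/SVLEN INFO keys.  Everything is
normalized here into :class:`~consensv.model.SVCall` with 0-based
half-open coordinates; the merge core never sees VCF.

pysam resolves the record end for us: htslib uses INFO/END when present
and otherwise derives it from SVLEN (``POS + |SVLEN|``).  A symbolic
record that carries neither key has ``stop == start + len(REF)``, which
is how we detect and skip it.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .model import SV_CLASSES, ConsensvError, GenomeInfo, MergedSV, SVCall, TruthSV

logger = logging.getLogger(__name__)

#: Subtype prefixes mapped onto the four base classes.  Anything whose
#: SVTYPE (or symbolic ALT) does not start with one of these prefixes —
#: BND, TRA, direction-less CNV records, … — is skipped and tallied.
_CLASS_PREFIXES = ("DEL", "DUP", "INV", "INS")

MERGED_TSV_COLUMNS = [
    "contig",
    "sv_class",
    "start",
    "end",
    "maxsup_start",
    "maxsup_end",
    "support",
    "n_callers",
    "callers",
    "subevents",
    "coverage",
]


def _base_class(svtype: str | None) -> str | None:
    if not svtype:
        return None
    t = svtype.upper().lstrip("<").rstrip(">")
    for prefix in _CLASS_PREFIXES:
        if t.startswith(prefix):
            return prefix
    return None


def _symbolic_alt(rec: "pysam.VariantRecord") -> str | None:
    alts = rec.alts or ()
    for alt in alts:
        if alt and alt.startswith("<") and alt.endswith(">"):
            return alt[1:-1]
    return None


def read_caller_vcf(
    path: str,
    caller: str,
    genome: GenomeInfo,
    min_sv_len: int = 1,
    skipped: Counter | None = None,
) -> list[SVCall]:
    """Parse one caller's VCF into normalized calls.

    Parameters
    ----------
    path:
        VCF 4.x file, plain or bgzipped.
    caller:
        Identifier attached to every returned call.
    genome:
        Reference contigs; a record on a contig absent from the genome
        is a hard error.
    min_sv_len:
        Records shorter than this many bp are dropped (insertions use
        ``|SVLEN|`` when reported, else their 1 bp footprint).
    skipped:
        Optional counter updated in place with per-reason tallies of
        skipped records (``unsupported_type``, ``missing_end``,
        ``inverted_coordinates``, ``below_min_len``).

    Notes
    -----
    A 1 bp symbolic record whose explicit ``END`` equals ``POS`` is
    indistinguishable, after htslib normalization, from a record with no
    end information at all; both are skipped.  FILTER is ignored.
    """
    if skipped is None:
        skipped = Counter()
    lengths = genome.lengths
    calls: list[SVCall] = []
    with pysam.VariantFile(path) as vf:
        for i, rec in enumerate(vf):
            sv_class = _base_class(rec.info.get("SVTYPE")) or _base_class(_symbolic_alt(rec))
            source = rec.id or f"{path}:{i + 1}"
            if sv_class is None:
                skipped["unsupported_type"] += 1
                continue
            if rec.contig not in lengths:
                raise ConsensvError(
                    f"{path}: record {source} references contig {rec.contig!r} "
                    "absent from the genome table"
                )
            start = rec.start
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            svlen = int(svlen) if svlen is not None else None
            if sv_class == "INS":
                end = start + 1
                length = abs(svlen) if svlen else 1
            else:
                end = rec.stop
                ref_len = len(rec.ref or "N")
                if svlen is None and ref_len == 1 and end == start + 1:
                    warnings.warn(
                        f"{path}: record {source} has neither END nor SVLEN; skipped",
                        stacklevel=2,
                    )
                    skipped["missing_end"] += 1
                    continue
                if end <= start:
                    warnings.warn(
                        f"{path}: record {source} has END <= POS; skipped", stacklevel=2
                    )
                    skipped["inverted_coordinates"] += 1
                    continue
                length = end - start
            end = min(end, lengths[rec.contig])
            if length < min_sv_len:
                skipped["below_min_len"] += 1
                continue
            calls.append(
                SVCall(
                    caller=caller,
                    contig=rec.contig,
                    sv_class=sv_class,
                    start=start,
                    end=end,
                    svlen=svlen,
                    source_id=source,
                    raw_info={k: str(v) for k, v in rec.info.items()},
                )
            )
    logger.info("read %d calls from %s (%d skipped)", len(calls), path, sum(skipped.values()))
    return calls


# ---------------------------------------------------------------------------
# truth tables


def read_truth_table(path: str, genome: GenomeInfo) -> list[TruthSV]:
    """Read a ground-truth SV table.

    TSV with header columns ``contig  class  start  end  id`` (optional
    ``ins_len``), 0-based half-open coordinates, ``#`` comment lines
    allowed.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"contig": str, "id": str})
    required = {"contig", "class", "start", "end", "id"}
    missing = required - set(df.columns)
    if missing:
        raise ConsensvError(f"{path}: missing truth-table columns {sorted(missing)}")
    df = df.rename(columns={"class": "sv_class"})
    lengths = genome.lengths
    truths: list[TruthSV] = []
    for idx, row in enumerate(df.to_dict("records")):
        line = idx + 2  # header is line 1
        if row["contig"] not in lengths:
            raise ConsensvError(f"{path}:{line}: unknown contig {row['contig']!r}")
        start, end = int(row["start"]), int(row["end"])
        if not (0 <= start < end <= lengths[row["contig"]]):
            raise ConsensvError(
                f"{path}:{line}: interval [{start},{end}) outside contig "
                f"{row['contig']!r} (length {lengths[row['contig']]})"
            )
        if row["sv_class"] not in SV_CLASSES:
            raise ConsensvError(f"{path}:{line}: unsupported class {row['sv_class']!r}")
        ins_len = row.get("ins_len")
        ins_len = None if ins_len in (None, "") or pd.isna(ins_len) else int(ins_len)
        truths.append(
            TruthSV(
                contig=row["contig"],
                sv_class=row["sv_class"],
                start=start,
                end=end,
                truth_id=str(row["id"]),
                ins_len=ins_len,
            )
        )
    return truths


def write_truth_table(truths: Sequence[TruthSV], path: str) -> None:
    df = pd.DataFrame(
        {
            "contig": [t.contig for t in truths],
            "class": [t.sv_class for t in truths],
            "start": [t.start for t in truths],
            "end": [t.end for t in truths],
            "id": [t.truth_id for t in truths],
            "ins_len": [t.ins_len if t.ins_len is not None else "" for t in truths],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# merged-event TSV


def _fmt_map(d, fmt: str) -> str:
    return ";".join(f"{k}:{fmt.format(v)}" for k, v in sorted(d.items()))


def write_merged_tsv(events: Sequence[MergedSV], path: str, genome: GenomeInfo | None = None) -> None:
    """Write merged events as the canonical tab-separated table.

    Events are sorted by (contig, start, class) if a genome is given,
    else by (contig name, start).  An empty list yields a header-only
    file.  The layout round-trips losslessly through
    :func:`read_merged_tsv` (coverage at 4 decimal places).
    """
    events = list(events)
    if genome is not None:
        from .model import sort_events

        events = sort_events(events, genome)
    else:
        events = sorted(events, key=lambda e: (e.contig, e.start, e.sv_class))
    rows = []
    for e in events:
        rows.append(
            {
                "contig": e.contig,
                "sv_class": e.sv_class,
                "start": e.start,
                "end": e.end,
                "maxsup_start": e.maxsup_start,
                "maxsup_end": e.maxsup_end,
                "support": e.support,
                "n_callers": e.n_callers,
                "callers": ",".join(sorted(e.callers)),
                "subevents": _fmt_map(e.subevents, "{}"),
                "coverage": _fmt_map(e.coverage, "{:.4f}"),
            }
        )
    pd.DataFrame(rows, columns=MERGED_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_merged_tsv(path: str) -> list[MergedSV]:
    """Read back a merged-event table written by :func:`write_merged_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    events: list[MergedSV] = []
    for row in df.itertuples(index=False):
        subevents = {}
        if isinstance(row.subevents, str) and row.subevents:
            for item in row.subevents.split(";"):
                k, v = item.rsplit(":", 1)
                subevents[k] = int(v)
        coverage = {}
        if isinstance(row.coverage, str) and row.coverage:
            for item in row.coverage.split(";"):
                k, v = item.rsplit(":", 1)
                coverage[k] = float(v)
        callers = frozenset(str(row.callers).split(",")) if row.callers else frozenset()
        events.append(
            MergedSV(
                contig=row.contig,
                sv_class=row.sv_class,
                start=int(row.start),
                end=int(row.end),
                maxsup_start=int(row.maxsup_start),
                maxsup_end=int(row.maxsup_end),
                support=int(row.support),
                callers=callers,
                subevents=subevents,
                coverage=coverage,
            )
        )
    return events


def write_genome_table(genome: GenomeInfo, path: str) -> None:
    """Write a FASTA-index style contig/length table."""
    with open(path, "w") as fh:
        for name, length in genome.contigs:
            fh.write(f"{name}\t{length}\n")


def dedup_calls(calls: Iterable[SVCall]) -> list[SVCall]:
    """Drop per-caller duplicate records (same caller/contig/class/span).

    The per-caller signal is binary, so duplicates cannot add support.
    """
    seen: set[tuple] = set()
    out: list[SVCall] = []
    for c in calls:
        k = c.key()
        if k in seen:
            continue
        seen.add(k)
        out.append(c)
    return out
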