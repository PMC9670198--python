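"""Excision-event calling from gapped alignments on the MAC+IES reference.

A candidate excision is a deletion or skip (CIGAR ``D`` or ``N``) of at
least ``min_gap`` bp flanked by at least ``min_anchor`` aligned bases on
both sides of the read.  A candidate is accepted only if the excised
reference segment is TA-bounded in the same two-TA sense as canonical
IESs (the segment begins with ``TA`` and a second ``TA`` starts at the
gap end).  Accepted gaps are classified against the IES annotation by
interval arithmetic:

* exact interval match            -> CORRECT
* contained in the matched IES    -> ALT_INTERNAL
* containing the matched IES      -> ALT_EXTERNAL
* overlapping one boundary only   -> ALT_OVERLAPPING
* overlapping no annotated IES    -> CRYPTIC

When a gap overlaps several IESs the one with the largest reciprocal
overlap wins; ties break by smaller length difference, then leftmost.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam

from .genome import GenomeAssembly, IesAnnotation

__all__ = [
    "AlignedRead",
    "CandidateGap",
    "ExcisionEvent",
    "Rejection",
    "EventClass",
    "parse_alignments",
    "extract_gaps",
    "classify_gap",
    "aggregate_events",
    "call_events",
    "write_events_gff3",
]

logger = logging.getLogger(__name__)

CORRECT = "CORRECT"
ALT_INTERNAL = "ALT_INTERNAL"
ALT_EXTERNAL = "ALT_EXTERNAL"
ALT_OVERLAPPING = "ALT_OVERLAPPING"
CRYPTIC = "CRYPTIC"
ALT_CLASSES = (ALT_INTERNAL, ALT_EXTERNAL, ALT_OVERLAPPING)
EventClass = str

_REF_OPS = frozenset({0, 7, 8})  # M, =, X consume both read and reference
_GAP_OPS = frozenset({2, 3})  # D, N consume reference only


@dataclass
class AlignedRead:
    """Alignment operations of one primary mapped read."""

    read_id: str
    contig: str
    pos: int  # leftmost reference position, 0-based
    cigar: tuple[tuple[int, int], ...]
    mapq: int = 60
    is_proper_pair: bool = False
    template_length: int = 0

    @property
    def reference_end(self) -> int:
        return self.pos + sum(ln for op, ln in self.cigar if op in _REF_OPS | _GAP_OPS)

    def aligned_blocks(self) -> list[tuple[int, int]]:
        """Reference intervals covered by aligned (non-gap) bases."""
        blocks = []
        ref = self.pos
        for op, ln in self.cigar:
            if op in _REF_OPS:
                if blocks and blocks[-1][1] == ref:
                    blocks[-1] = (blocks[-1][0], ref + ln)
                else:
                    blocks.append((ref, ref + ln))
                ref += ln
            elif op in _GAP_OPS:
                ref += ln
        return blocks


@dataclass(frozen=True)
class CandidateGap:
    contig: str
    gap_start: int
    gap_end: int
    left_anchor: int
    right_anchor: int
    read_id: str

    @property
    def length(self) -> int:
        return self.gap_end - self.gap_start


@dataclass
class ExcisionEvent:
    contig: str
    gap_start: int
    gap_end: int
    classification: EventClass
    matched_ies_id: str  # empty for CRYPTIC
    supporting_read_ids: list[str] = field(default_factory=list)

    @property
    def excised_length(self) -> int:
        return self.gap_end - self.gap_start

    @property
    def support(self) -> int:
        return len(self.supporting_read_ids)


@dataclass(frozen=True)
class Rejection:
    contig: str
    gap_start: int
    gap_end: int
    reason: str  # "no-TA-left" | "no-TA-right"
    read_id: str


def parse_alignments(
    path: str | Path, min_mapq: int = 10
) -> Iterator[AlignedRead]:
    """Stream primary mapped alignments from SAM/BAM.

    Secondary, supplementary, and unmapped records are dropped, as are
    records below ``min_mapq``.  Malformed records are skipped with a
    counted warning.
    """
    skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            try:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                if rec.cigartuples is None:
                    skipped += 1
                    continue
                yield AlignedRead(
                    read_id=rec.query_name,
                    contig=rec.reference_name,
                    pos=rec.reference_start,
                    cigar=tuple(rec.cigartuples),
                    mapq=rec.mapping_quality,
                    is_proper_pair=rec.is_proper_pair,
                    template_length=rec.template_length,
                )
            except (ValueError, TypeError):
                skipped += 1
    if skipped:
        logger.warning("skipped %d malformed alignment records", skipped)


def extract_gaps(
    read: AlignedRead, min_gap: int = 20, min_anchor: int = 10
) -> list[CandidateGap]:
    """Candidate excision gaps of one read.

    Only D/N operations of length >= min_gap flanked by >= min_anchor
    aligned bases (summed over all aligned ops on that side of the read)
    qualify; a read may contribute several gaps.
    """
    aligned_total = sum(ln for op, ln in read.cigar if op in _REF_OPS)
    gaps = []
    ref = read.pos
    left = 0
    for op, ln in read.cigar:
        if op in _REF_OPS:
            left += ln
            ref += ln
        elif op in _GAP_OPS:
            right = aligned_total - left
            if ln >= min_gap and left >= min_anchor and right >= min_anchor:
                gaps.append(
                    CandidateGap(
                        contig=read.contig,
                        gap_start=ref,
                        gap_end=ref + ln,
                        left_anchor=left,
                        right_anchor=right,
                        read_id=read.read_id,
                    )
                )
            ref += ln
    return gaps


class _IesIndex:
    """Sorted per-contig interval lookup over the IES annotation."""

    def __init__(self, annotations: Sequence[IesAnnotation]):
        self.by_contig: dict[str, list[IesAnnotation]] = {}
        for a in sorted(annotations):
            self.by_contig.setdefault(a.contig, []).append(a)
        self._starts = {c: [a.start for a in v] for c, v in self.by_contig.items()}

    def overlapping(self, contig: str, start: int, end: int) -> list[IesAnnotation]:
        anns = self.by_contig.get(contig, [])
        if not anns:
            return []
        i = bisect.bisect_left(self._starts[contig], start)
        # step back while preceding IESs may still reach into [start, end)
        j = i
        while j > 0 and anns[j - 1].end > start:
            j -= 1
        out = []
        for a in anns[j:]:
            if a.start >= end:
                break
            if a.end > start:
                out.append(a)
        return out


def classify_gap(
    gap: CandidateGap,
    annotations: Sequence[IesAnnotation] | _IesIndex,
    genome: GenomeAssembly,
) -> ExcisionEvent | Rejection:
    """TA check and interval classification of one candidate gap."""
    seq = genome.sequence(gap.contig)
    if seq[gap.gap_start : gap.gap_start + 2] != "TA":
        return Rejection(gap.contig, gap.gap_start, gap.gap_end, "no-TA-left", gap.read_id)
    if seq[gap.gap_end : gap.gap_end + 2] != "TA":
        return Rejection(gap.contig, gap.gap_start, gap.gap_end, "no-TA-right", gap.read_id)
    index = annotations if isinstance(annotations, _IesIndex) else _IesIndex(annotations)
    hits = index.overlapping(gap.contig, gap.gap_start, gap.gap_end)
    if not hits:
        return ExcisionEvent(
            gap.contig, gap.gap_start, gap.gap_end, CRYPTIC, "", [gap.read_id]
        )
    best = max(
        hits,
        key=lambda a: (
            _reciprocal_overlap(gap.gap_start, gap.gap_end, a.start, a.end),
            -abs(gap.length - a.length),
            -a.start,
        ),
    )
    if (gap.gap_start, gap.gap_end) == best.interval:
        cls = CORRECT
    elif gap.gap_start >= best.start and gap.gap_end <= best.end:
        cls = ALT_INTERNAL
    elif gap.gap_start <= best.start and gap.gap_end >= best.end:
        cls = ALT_EXTERNAL
    else:
        cls = ALT_OVERLAPPING
    return ExcisionEvent(
        gap.contig, gap.gap_start, gap.gap_end, cls, best.ies_id, [gap.read_id]
    )


def _reciprocal_overlap(s1: int, e1: int, s2: int, e2: int) -> float:
    ov = min(e1, e2) - max(s1, s2)
    if ov <= 0:
        return 0.0
    return min(ov / (e1 - s1), ov / (e2 - s2))


def aggregate_events(
    classified: Iterable[ExcisionEvent],
) -> tuple[list[ExcisionEvent], pd.DataFrame, pd.DataFrame]:
    """Merge identical gaps and tabulate per-IES and cryptic support.

    Returns (merged events, per-IES table with n_correct / n_alt read
    counts, cryptic event table).
    """
    merged: dict[tuple, ExcisionEvent] = {}
    for ev in classified:
        key = (ev.contig, ev.gap_start, ev.gap_end, ev.classification, ev.matched_ies_id)
        if key in merged:
            merged[key].supporting_read_ids.extend(ev.supporting_read_ids)
        else:
            merged[key] = ExcisionEvent(
                ev.contig, ev.gap_start, ev.gap_end, ev.classification,
                ev.matched_ies_id, list(ev.supporting_read_ids),
            )
    events = sorted(
        merged.values(), key=lambda e: (e.contig, e.gap_start, e.gap_end, e.classification)
    )
    per_ies: dict[str, dict[str, int]] = {}
    cryptic_rows = []
    for ev in events:
        if ev.classification == CRYPTIC:
            cryptic_rows.append(
                {
                    "contig": ev.contig,
                    "gap_start": ev.gap_start,
                    "gap_end": ev.gap_end,
                    "length": ev.excised_length,
                    "support": ev.support,
                }
            )
            continue
        row = per_ies.setdefault(
            ev.matched_ies_id, {"n_correct": 0, "n_alt": 0}
        )
        if ev.classification == CORRECT:
            row["n_correct"] += ev.support
        else:
            row["n_alt"] += ev.support
    per_ies_df = pd.DataFrame(
        [{"ies_id": k, **v} for k, v in sorted(per_ies.items())],
        columns=["ies_id", "n_correct", "n_alt"],
    )
    cryptic_df = pd.DataFrame(
        cryptic_rows, columns=["contig", "gap_start", "gap_end", "length", "support"]
    )
    return events, per_ies_df, cryptic_df


def call_events(
    reads: Iterable[AlignedRead],
    annotations: Sequence[IesAnnotation],
    genome: GenomeAssembly,
    min_gap: int = 20,
    min_anchor: int = 10,
) -> tuple[list[ExcisionEvent], pd.DataFrame, pd.DataFrame, list[Rejection]]:
    """End-to-end event calling over a read stream."""
    index = _IesIndex(annotations)
    accepted: list[ExcisionEvent] = []
    rejected: list[Rejection] = []
    for read in reads:
        for gap in extract_gaps(read, min_gap=min_gap, min_anchor=min_anchor):
            result = classify_gap(gap, index, genome)
            if isinstance(result, Rejection):
                rejected.append(result)
            else:
                accepted.append(result)
    events, per_ies, cryptic = aggregate_events(accepted)
    return events, per_ies, cryptic, rejected


def write_events_gff3(
    events: Sequence[ExcisionEvent], path: str | Path, source: str = "ieskit"
) -> None:
    """Event table in a MILORD-like GFF3 shape."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for i, ev in enumerate(events, 1):
            attrs = (
                f"ID=event_{i:06d};class={ev.classification};"
                f"matched_ies={ev.matched_ies_id or '.'};support={ev.support};"
                f"read_ids={','.join(ev.supporting_read_ids)}"
            )
            out.write(
                "\t".join(
                    [
                        ev.contig,
                        source,
                        "excision",
                        str(ev.gap_start + 1),
                        str(ev.gap_end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
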