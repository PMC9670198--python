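"""Per-IES retention scoring from boundary-spanning read counts.

The IES retention score (IRS) summarises, per IES, the balance between
reads that still carry germline sequence across an IES boundary and
reads that document its correct somatic excision: 0 means complete
excision, 1 complete failure of excision.

Counting rules: a read supports retention at the left (right) boundary
if it aligns continuously across it with at least ``min_flank`` aligned
bases on each side; it supports excision if it carries a gap exactly
matching the annotated interval (a CORRECT excision event).  A retained
read that spans a whole short IES increments both boundary counts, so
the score uses

    IRS = (a + b) / (a + b + 2 c)

with the factor 2 compensating excision reads for being countable at
only one junction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .excision import (
    CORRECT,
    AlignedRead,
    _IesIndex,
    classify_gap,
    extract_gaps,
)
from .genome import GenomeAssembly, IesAnnotation

__all__ = [
    "RetentionRecord",
    "count_boundary_reads",
    "compute_irs",
    "retention_table",
    "irs_table",
    "irs_correlation",
    "irs_by_length",
    "subterminal_base_frequencies",
]

_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass
class RetentionRecord:
    ies_id: str
    a: int  # left-boundary retention support
    b: int  # right-boundary retention support
    c: int  # correct-excision support
    irs: float  # NaN when a + b + 2c == 0


def compute_irs(a: int, b: int, c: int) -> float:
    """(a+b)/(a+b+2c); NaN when no informative reads exist."""
    denom = a + b + 2 * c
    if denom == 0:
        return math.nan
    return (a + b) / denom


def _spans(blocks: list[tuple[int, int]], boundary: int, min_flank: int) -> bool:
    lo, hi = boundary - min_flank, boundary + min_flank
    return any(bs <= lo and hi <= be for bs, be in blocks)


def count_boundary_reads(
    reads: Iterable[AlignedRead],
    ies: IesAnnotation,
    min_flank: int = 5,
    genome: GenomeAssembly | None = None,
    min_gap: int = 20,
    min_anchor: int | None = None,
) -> tuple[int, int, int]:
    """Boundary counts (a, b, c) for a single IES.

    ``min_anchor`` defaults to ``min_flank`` so the junction-support rule
    for excised reads demands the same evidence as the boundary-support
    rule for retained reads; unequal thresholds give the two read classes
    unequal capture windows and bias the score.

    Convenience wrapper over :func:`retention_table` semantics for one
    annotation; prefer the table form for whole-genome scoring.
    """
    if min_anchor is None:
        min_anchor = min_flank
    a = b = c = 0
    for read in reads:
        blocks = read.aligned_blocks()
        if _spans(blocks, ies.start, min_flank):
            a += 1
        if _spans(blocks, ies.end, min_flank):
            b += 1
        for gap in extract_gaps(read, min_gap=min_gap, min_anchor=min_anchor):
            if (gap.gap_start, gap.gap_end) != ies.interval:
                continue
            if genome is not None:
                ev = classify_gap(gap, [ies], genome)
                if getattr(ev, "classification", None) != CORRECT:
                    continue
            c += 1
    return a, b, c


def retention_table(
    reads: Iterable[AlignedRead],
    annotations: Sequence[IesAnnotation],
    genome: GenomeAssembly,
    min_flank: int = 5,
    min_gap: int = 20,
    min_anchor: int | None = None,
) -> pd.DataFrame:
    """Single-pass (a, b, c, IRS) table over all IESs for one sample.

    ``n_reads`` counts the distinct reads contributing to (a, b, c);
    a short IES fully spanned by one retained read gains both boundary
    counts from that single read, so ``n_reads`` — not a+b+2c — is the
    right denominator for sampling-error estimates.

    ``min_anchor`` defaults to ``min_flank``: requiring the same number
    of aligned bases around an excision junction as around a retained
    boundary gives retained and excised molecules identical capture
    windows, which keeps the score unbiased.
    """
    if min_anchor is None:
        min_anchor = min_flank
    index = _IesIndex(annotations)
    counts = {a.ies_id: [0, 0, 0] for a in annotations}
    informative = {a.ies_id: 0 for a in annotations}
    for read in reads:
        blocks = read.aligned_blocks()
        if not blocks:
            continue
        hit: set[str] = set()
        span_lo, span_hi = blocks[0][0], blocks[-1][1]
        for ann in index.overlapping(read.contig, span_lo - 1, span_hi + 1):
            row = counts[ann.ies_id]
            if _spans(blocks, ann.start, min_flank):
                row[0] += 1
                hit.add(ann.ies_id)
            if _spans(blocks, ann.end, min_flank):
                row[1] += 1
                hit.add(ann.ies_id)
        for gap in extract_gaps(read, min_gap=min_gap, min_anchor=min_anchor):
            ev = classify_gap(gap, index, genome)
            if getattr(ev, "classification", None) == CORRECT:
                counts[ev.matched_ies_id][2] += 1
                hit.add(ev.matched_ies_id)
        for ies_id in hit:
            informative[ies_id] += 1
    rows = [
        {
            "ies_id": ies_id,
            "a": a,
            "b": b,
            "c": c,
            "n_reads": informative[ies_id],
            "irs": compute_irs(a, b, c),
        }
        for ies_id, (a, b, c) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["ies_id", "a", "b", "c", "n_reads", "irs"])


def irs_table(
    samples: Mapping[str, Iterable[AlignedRead]],
    annotations: Sequence[IesAnnotation],
    genome: GenomeAssembly,
    **kwargs,
) -> pd.DataFrame:
    """IES x sample matrix of retention scores (NaN preserved)."""
    if not samples:
        raise ValueError("at least one sample is required")
    cols = {}
    for name, reads in samples.items():
        tab = retention_table(reads, annotations, genome, **kwargs)
        cols[name] = tab.set_index("ies_id")["irs"]
    return pd.DataFrame(cols)


def irs_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson r over pairwise-complete pairs; NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        return math.nan
    xv, yv = x[mask], y[mask]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return math.nan
    return float(np.corrcoef(xv, yv)[0, 1])


def irs_by_length(
    irs: Mapping[str, float],
    annotations: Sequence[IesAnnotation],
    bins: Sequence[tuple[int, float]] | None = None,
) -> pd.DataFrame:
    """Mean/median IRS per IES-length bin.

    Default binning: 1-bp bins up to 150 bp, then [150, 200) and
    [200, inf).
    """
    if bins is None:
        bins = [(l, l + 1) for l in range(1, 150)] + [(150, 200), (200, math.inf)]
    lengths = {a.ies_id: a.length for a in annotations}
    rows = []
    for lo, hi in bins:
        vals = [
            irs[i]
            for i, ln in lengths.items()
            if lo <= ln < hi and i in irs and not math.isnan(irs[i])
        ]
        rows.append(
            {
                "length_min": lo,
                "length_max": hi,
                "n": len(vals),
                "mean_irs": float(np.mean(vals)) if vals else math.nan,
                "median_irs": float(np.median(vals)) if vals else math.nan,
            }
        )
    return pd.DataFrame(rows)


def subterminal_base_frequencies(
    annotations: Sequence[IesAnnotation],
    genome: GenomeAssembly,
    irs: Mapping[str, float],
    irs_bins: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0 + 1e-9),
    length_class: tuple[int, float] | None = None,
) -> pd.DataFrame:
    """Base frequencies at the first three positions after the terminal TA.

    Both IES ends contribute: the left end is read on the forward strand
    after the leading TA, the right end on the reverse complement after
    the (palindromic) junction TA.  Frequencies within each retention-score
    bin sum to one at each position.
    """
    rows = []
    counts: dict[tuple[int, int, str], int] = {}
    totals: dict[tuple[int, int], int] = {}
    for a in annotations:
        if length_class is not None and not (
            length_class[0] <= a.length < length_class[1]
        ):
            continue
        score = irs.get(a.ies_id, math.nan)
        if math.isnan(score):
            continue
        if a.length < 5:
            continue
        b = int(np.digitize(score, irs_bins)) - 1
        b = min(max(b, 0), len(irs_bins) - 2)
        seq = genome.sequence(a.contig)
        fwd = seq[a.start + 2 : a.start + 5]
        rev = seq[a.end - 3 : a.end].translate(_RC)[::-1]
        for end_seq in (fwd, rev):
            for pos, base in enumerate(end_seq, start=1):
                counts[(b, pos, base)] = counts.get((b, pos, base), 0) + 1
                totals[(b, pos)] = totals.get((b, pos), 0) + 1
    for (b, pos, base), n in sorted(counts.items()):
        rows.append(
            {
                "irs_bin": b,
                "irs_lo": irs_bins[b],
                "irs_hi": irs_bins[b + 1],
                "position": pos,
                "base": base,
                "frequency": n / totals[(b, pos)],
                "n": totals[(b, pos)],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["irs_bin", "irs_lo", "irs_hi", "position", "base", "frequency", "n"],
    )
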