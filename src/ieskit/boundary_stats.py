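"""Alternative/cryptic excision statistics and length distributions.

Percentages follow the read-based definitions used for knockdown
comparisons: alternative excision (%) is 100 * alt / (alt + correct)
supporting reads, and cryptic excision (%) is 100 * cryptic reads /
all mapped reads.  Histograms are 1-bp integer binned and, by default,
read weighted (each supporting read counts once); event weighting is
available via ``weight_by_reads=False``.

The "forbidden peak" is the strongly under-represented excised-length
class around 35 bp; its mass within a configurable window (default
[32, 38] bp) quantifies how much excision violates the species' length
periodicity constraint.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .excision import (
    ALT_CLASSES,
    ALT_EXTERNAL,
    ALT_INTERNAL,
    ALT_OVERLAPPING,
    CORRECT,
    CRYPTIC,
    ExcisionEvent,
)
from .genome import IesAnnotation

__all__ = [
    "alt_excision_percent",
    "cryptic_excision_percent",
    "fraction_ies_with_alt",
    "per_ies_alt_summary",
    "excision_length_histograms",
    "forbidden_peak_mass",
    "boundary_offset_distribution",
    "excision_summary",
]


def alt_excision_percent(n_alt: int, n_correct: int) -> float:
    """100 * alt / (alt + correct); NaN when no excision reads exist."""
    total = n_alt + n_correct
    if total == 0:
        return math.nan
    return 100.0 * n_alt / total


def cryptic_excision_percent(n_cryptic_reads: int, n_all_reads: int) -> float:
    """100 * cryptic reads / all mapped reads."""
    if n_all_reads == 0:
        return math.nan
    return 100.0 * n_cryptic_reads / n_all_reads


def fraction_ies_with_alt(
    per_ies: pd.DataFrame,
    annotations: Sequence[IesAnnotation],
    min_reads: int = 1,
) -> float:
    """Fraction of all annotated IESs with >= min_reads alternative reads."""
    if not annotations:
        raise ValueError("empty annotation set")
    if per_ies.empty:
        return 0.0
    with_alt = (per_ies["n_alt"] >= min_reads).sum()
    return float(with_alt) / len(annotations)


def per_ies_alt_summary(per_ies: pd.DataFrame) -> tuple[float, float]:
    """(median, mean) per-IES alternative excision percent over IESs with
    at least one excision-supporting read."""
    eligible = per_ies[(per_ies["n_alt"] + per_ies["n_correct"]) > 0]
    if eligible.empty:
        raise ValueError("no IES with excision-supporting reads")
    pct = 100.0 * eligible["n_alt"] / (eligible["n_alt"] + eligible["n_correct"])
    return float(pct.median()), float(pct.mean())


def _weight(ev: ExcisionEvent, weight_by_reads: bool) -> int:
    return ev.support if weight_by_reads else 1


def excision_length_histograms(
    events: Iterable[ExcisionEvent],
    annotations: Sequence[IesAnnotation],
    weight_by_reads: bool = True,
) -> dict[str, Counter]:
    """1-bp length histograms: annotated reference IESs, alternatively
    excised segments (split internal/external), and cryptic segments.

    One-boundary-overlap events enter the external histogram, since one
    end extends beyond the matched IES.
    """
    hists: dict[str, Counter] = {
        "reference": Counter(),
        "alt_all": Counter(),
        "alt_internal": Counter(),
        "alt_external": Counter(),
        "cryptic": Counter(),
        "correct": Counter(),
    }
    for a in annotations:
        hists["reference"][a.length] += 1
    for ev in events:
        w = _weight(ev, weight_by_reads)
        ln = ev.excised_length
        if ev.classification == CORRECT:
            hists["correct"][ln] += w
        elif ev.classification == ALT_INTERNAL:
            hists["alt_all"][ln] += w
            hists["alt_internal"][ln] += w
        elif ev.classification in (ALT_EXTERNAL, ALT_OVERLAPPING):
            hists["alt_all"][ln] += w
            hists["alt_external"][ln] += w
        elif ev.classification == CRYPTIC:
            hists["cryptic"][ln] += w
    return hists


def forbidden_peak_mass(
    histogram: Mapping[int, int], window: tuple[int, int] = (32, 38)
) -> float:
    """Fraction of histogram mass with length in the closed window."""
    total = sum(histogram.values())
    if total == 0:
        return math.nan
    lo, hi = window
    return sum(v for k, v in histogram.items() if lo <= k <= hi) / total


def boundary_offset_distribution(
    events: Iterable[ExcisionEvent],
    annotations: Sequence[IesAnnotation],
    weight_by_reads: bool = True,
    within_bp: int = 20,
) -> tuple[Counter, Counter, float]:
    """Signed offsets of matched (non-cryptic) excisions.

    Returns (length-offset histogram: excised length minus reference
    length; per-boundary offset histogram over both ends; fraction of
    weight with both boundary offsets within +/-within_bp).
    """
    by_id = {a.ies_id: a for a in annotations}
    length_offsets: Counter = Counter()
    boundary_offsets: Counter = Counter()
    near = 0
    total = 0
    for ev in events:
        if ev.classification == CRYPTIC:
            continue
        a = by_id[ev.matched_ies_id]
        w = _weight(ev, weight_by_reads)
        length_offsets[ev.excised_length - a.length] += w
        dl = ev.gap_start - a.start
        dr = ev.gap_end - a.end
        boundary_offsets[dl] += w
        boundary_offsets[dr] += w
        total += w
        if abs(dl) <= within_bp and abs(dr) <= within_bp:
            near += w
    frac_near = near / total if total else math.nan
    return length_offsets, boundary_offsets, frac_near


def excision_summary(
    per_ies: pd.DataFrame,
    annotations: Sequence[IesAnnotation],
    events: Sequence[ExcisionEvent],
    n_all_reads: int,
    forbidden_window: tuple[int, int] = (32, 38),
) -> dict:
    """Headline excision statistics of one sample as a JSON-ready dict."""
    n_alt = int(per_ies["n_alt"].sum()) if not per_ies.empty else 0
    n_correct = int(per_ies["n_correct"].sum()) if not per_ies.empty else 0
    n_cryptic = sum(ev.support for ev in events if ev.classification == CRYPTIC)
    hists = excision_length_histograms(events, annotations)
    try:
        median_alt, mean_alt = per_ies_alt_summary(per_ies)
    except ValueError:
        median_alt = mean_alt = math.nan
    _, _, frac_near = boundary_offset_distribution(events, annotations)
    return {
        "n_correct_reads": n_correct,
        "n_alt_reads": n_alt,
        "n_cryptic_reads": int(n_cryptic),
        "global_alt_percent": alt_excision_percent(n_alt, n_correct),
        "fraction_ies_with_alt": fraction_ies_with_alt(per_ies, annotations),
        "median_alt_percent": median_alt,
        "mean_alt_percent": mean_alt,
        "cryptic_percent": cryptic_excision_percent(n_cryptic, n_all_reads),
        "forbidden_mass_alt": forbidden_peak_mass(hists["alt_all"], forbidden_window),
        "fraction_offsets_within_20bp": frac_near,
    }


def histogram_frame(histogram: Mapping[int, int], value: str = "length") -> pd.DataFrame:
    """Counter -> sorted two-column DataFrame for TSV export."""
    items = sorted(histogram.items())
    return pd.DataFrame(items, columns=[value, "count"]).astype(
        {value: int, "count": int}
    )
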