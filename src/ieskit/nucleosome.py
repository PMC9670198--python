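"""DNA-seq-normalized nucleosome density over IESs.

Nucleosome profiling reads (double-strand-specific nuclease digestion of
anlagen chromatin) are filtered to mononucleosome-sized proper pairs
(outer distance 100-175 bp inclusive), counted per IES under a >=9
aligned-bp overlap rule, and normalized against DNA-seq read counts from
the same nuclei:

    r = (n / N) / (d / D)

with n, d the per-IES nucleosomal and DNA counts and N, D the library
totals (after any downsampling).  IES-length normalizations cancel, so r
is dimensionless.  Densities are compared between IES strata (weakly vs
strongly retained; length classes) with a two-sample Kolmogorov-Smirnov
test.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .excision import AlignedRead, _IesIndex
from .genome import IesAnnotation

__all__ = [
    "Fragment",
    "LibraryCounts",
    "filter_nucleosomal_pairs",
    "count_ies_reads",
    "downsample_reads",
    "normalized_density",
    "density_table",
    "stratified_density_distributions",
    "ks_two_sample",
    "fragment_length_histogram",
]


@dataclass(frozen=True)
class Fragment:
    """Outer span of one properly-paired sequenced fragment."""

    frag_id: str
    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LibraryCounts:
    """Post-downsampling library totals for the density denominator."""

    D_c: int
    N_c: int
    D_e: int
    N_e: int

    def __post_init__(self) -> None:
        for name in ("D_c", "N_c", "D_e", "N_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"LibraryCounts.{name} must be > 0")


def filter_nucleosomal_pairs(
    reads: Iterable[AlignedRead], min_outer: int = 100, max_outer: int = 175
) -> list[Fragment]:
    """Mononucleosome-sized fragments from properly-paired alignments.

    Keeps proper pairs with |outer distance| in [min_outer, max_outer]
    (inclusive on both sides) and emits one fragment per pair, anchored
    at the leftmost mate.  Single-end input is an error: outer distance
    is undefined without a mate.
    """
    fragments = []
    saw_any = False
    for read in reads:
        saw_any = True
        tlen = read.template_length
        if tlen == 0 and not read.is_proper_pair:
            raise ValueError(
                "filter_nucleosomal_pairs requires paired-end alignments "
                "with template lengths (single-end record "
                f"{read.read_id!r} found)"
            )
        if not read.is_proper_pair:
            continue
        if tlen <= 0:  # count each pair once, from its leftmost mate
            continue
        if min_outer <= tlen <= max_outer:
            fragments.append(
                Fragment(read.read_id, read.contig, read.pos, read.pos + tlen)
            )
    return fragments


def count_ies_reads(
    items: Iterable[AlignedRead | Fragment],
    annotations: Sequence[IesAnnotation],
    min_overlap_bp: int = 9,
) -> pd.DataFrame:
    """Per-IES counts of reads/fragments with >= min_overlap_bp aligned
    bases inside the IES interval.

    Aligned means non-gap: a read whose deletion spans the IES contributes
    nothing there.  A read may count for several IESs.
    """
    index = _IesIndex(annotations)
    counts = {a.ies_id: 0 for a in annotations}
    for item in items:
        if isinstance(item, Fragment):
            blocks = [(item.start, item.end)]
            contig = item.contig
        else:
            blocks = item.aligned_blocks()
            contig = item.contig
        if not blocks:
            continue
        span_lo, span_hi = blocks[0][0], blocks[-1][1]
        for ann in index.overlapping(contig, span_lo, span_hi):
            overlap = sum(
                max(0, min(be, ann.end) - max(bs, ann.start)) for bs, be in blocks
            )
            if overlap >= min_overlap_bp:
                counts[ann.ies_id] += 1
    return pd.DataFrame(
        [{"ies_id": k, "count": v} for k, v in sorted(counts.items())],
        columns=["ies_id", "count"],
    )


def downsample_reads(
    reads: Iterable[AlignedRead], fraction: float, seed: int
) -> list[AlignedRead]:
    """Bernoulli downsampling, pair-coherent and deterministic.

    The keep decision is a hash of (seed, read name), so both mates of a
    pair share it and reruns with the same seed reproduce the subsample
    exactly.  Statistically equivalent to ``samtools view -s`` without
    replicating its hashing bit-for-bit.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1:
        return list(reads)
    kept = []
    for read in reads:
        digest = hashlib.blake2b(
            f"{seed}:{read.read_id}".encode(), digest_size=8
        ).digest()
        u = int.from_bytes(digest, "big") / 2**64
        if u < fraction:
            kept.append(read)
    return kept


def normalized_density(n: int, N: int, d: int, D: int) -> float:
    """r = (n/N) / (d/D); NaN when the IES has no DNA-seq coverage."""
    if N <= 0 or D <= 0:
        raise ValueError("library totals N and D must be positive")
    if d == 0:
        return math.nan
    return (n / N) / (d / D)


def density_table(
    nucleosomal_counts: pd.DataFrame,
    dna_counts: pd.DataFrame,
    N: int,
    D: int,
    suffix: str = "",
) -> pd.DataFrame:
    """Join per-IES nucleosomal/DNA counts and compute r for one library
    pair."""
    merged = nucleosomal_counts.rename(columns={"count": "n"}).merge(
        dna_counts.rename(columns={"count": "d"}), on="ies_id", how="outer"
    ).fillna(0)
    merged["n"] = merged["n"].astype(int)
    merged["d"] = merged["d"].astype(int)
    merged["r"] = [
        normalized_density(n, N, d, D) for n, d in zip(merged["n"], merged["d"])
    ]
    if suffix:
        merged = merged.rename(
            columns={"n": f"n_{suffix}", "d": f"d_{suffix}", "r": f"r_{suffix}"}
        )
    return merged


def stratified_density_distributions(
    records: pd.DataFrame,
    irs: Mapping[str, float],
    annotations: Sequence[IesAnnotation],
    irs_threshold: float = 0.2,
    length_strata: Sequence[tuple[str, int, float]] = (
        ("all", 0, math.inf),
        ("peak1_26_31", 26, 32),
        ("long_150_200", 150, 201),
    ),
    density_col: str = "r",
) -> dict[str, np.ndarray]:
    """Density vectors per {weak, strong} retention x length stratum.

    Weak means IRS < irs_threshold, strong IRS >= irs_threshold; IESs with
    missing IRS or missing density are excluded.  Keys look like
    ``weak_all``, ``strong_peak1_26_31``.
    """
    lengths = {a.ies_id: a.length for a in annotations}
    out: dict[str, np.ndarray] = {}
    rec = records.set_index("ies_id")[density_col]
    for name, lo, hi in length_strata:
        weak, strong = [], []
        for ies_id, r in rec.items():
            score = irs.get(ies_id, math.nan)
            ln = lengths.get(ies_id)
            if ln is None or math.isnan(score) or math.isnan(r):
                continue
            if not lo <= ln < hi:
                continue
            (weak if score < irs_threshold else strong).append(r)
        out[f"weak_{name}"] = np.asarray(weak, dtype=float)
        out[f"strong_{name}"] = np.asarray(strong, dtype=float)
    return out


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximal absolute ECDF difference; the p-value uses the
    asymptotic Kolmogorov distribution with effective sample size
    n_eff = |x||y| / (|x| + |y|).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / len(x)
    cdf_y = np.searchsorted(y, grid, side="right") / len(y)
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    n_eff = len(x) * len(y) / (len(x) + len(y))
    p = float(kolmogorov(math.sqrt(n_eff) * d))
    return d, min(max(p, 0.0), 1.0)


def fragment_length_histogram(
    reads: Iterable[AlignedRead], max_len: int = 500, density: bool = False
) -> pd.DataFrame:
    """1-bp histogram of outer distances of proper pairs, lengths 1..max_len.

    With ``density=True`` counts are normalized to sum to one.
    """
    counts = np.zeros(max_len + 1, dtype=float)
    for read in reads:
        tlen = read.template_length
        if read.is_proper_pair and 0 < tlen <= max_len:
            counts[tlen] += 1
    if density and counts.sum() > 0:
        counts = counts / counts.sum()
    return pd.DataFrame(
        {"outer_distance": np.arange(1, max_len + 1), "count": counts[1:]}
    )
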