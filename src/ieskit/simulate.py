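"""Synthetic MAC+IES genomes, DNA-seq reads, and nucleosomal fragments.

The generator emulates, at toy scale, the structure of the *Paramecium
tetraurelia* germline-inclusive assembly: short TA-bounded IESs with the
species' periodic length distribution (first peak 26-31 bp, a strongly
suppressed "forbidden" peak near 35 bp, then peaks near 45 and 55 bp),
embedded in AT-rich (~72% AT) MAC-destined sequence.  Every IES is
constructed so that alternative TA boundaries exist within +/-20 bp of
both canonical boundaries, so alternative excision is always realisable.

Ground truth is explicit: per-IES retention probability rho, alternative-
excision probability alpha, nucleosomal density multiplier lambda, and a
genome-wide cryptic excision rate kappa (events per read per kb of
MAC-destined sequence).  Reads are emitted pre-aligned (SAM with true
coordinates, excision gaps as CIGAR deletions) in addition to FASTQ, so
the downstream pipeline is testable without an external aligner.

All randomness flows from a single mandatory seed; identical config and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import truncnorm

from .genome import (
    AssemblyFlavor,
    GenomeAssembly,
    IesAnnotation,
    write_genome,
    write_ies_annotations,
)

__all__ = [
    "SimConfig",
    "TruthTable",
    "SimulatedRead",
    "generate_genome",
    "simulate_dna_reads",
    "simulate_nucleosomal_fragments",
    "write_sam",
    "write_fastq",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

# Base composition approximating the ~72% AT Paramecium somatic genome.
_BASES = np.array(list("ATCG"))
_BASE_P = np.array([0.36, 0.36, 0.14, 0.14])


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    ``ies_length_peaks`` is a mixture over the periodic IES length peaks:
    (center, weight) pairs; lengths are drawn uniformly from center +/- 2.
    The near-zero weight on the 35-bp component reflects the depleted
    "forbidden" length class of wild-type excision.
    """

    n_contigs: int = 2
    contig_length: int = 25_000
    n_ies: int = 50
    ies_length_peaks: tuple[tuple[int, float], ...] = (
        (28, 0.55),
        (35, 0.02),
        (45, 0.25),
        (55, 0.18),
    )
    read_length: int = 100
    coverage: float = 100.0
    paired: bool = False
    insert_mean: float = 250.0
    insert_sd: float = 25.0
    error_rate: float = 0.0
    # nucleosomal fragment model (mononucleosome-sized outer distances)
    frag_size_mean: float = 147.0
    frag_size_sd: float = 15.0
    frag_size_min: int = 80
    frag_size_max: int = 250
    nucleosome_read_length: int = 50
    seed: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        for name in ("n_contigs", "contig_length", "n_ies", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one simulation stage."""
        return np.random.default_rng([int(self.seed) % 2**31, stream])


@dataclass
class TruthTable:
    """Ground truth the pipeline must recover.

    retention_prob rho_i maps to the IES retention score; alt_prob alpha_i
    to the alternative-excision share of excision events; density_multiplier
    lambda_i to the normalized nucleosome density r; cryptic_rate kappa is
    the expected number of cryptic excisions per read per kb of MAC-destined
    sequence it covers.
    """

    retention_prob: dict[str, float]
    alt_prob: dict[str, float]
    density_multiplier: dict[str, float]
    cryptic_rate: float = 0.0

    def __post_init__(self) -> None:
        for d, lo in ((self.retention_prob, 0.0), (self.alt_prob, 0.0)):
            for k, v in d.items():
                if not lo <= v <= 1.0:
                    raise ValueError(f"probability out of range for {k}: {v}")
        for k, v in self.density_multiplier.items():
            if v <= 0:
                raise ValueError(f"density multiplier must be > 0 for {k}")
        if self.cryptic_rate < 0:
            raise ValueError("cryptic_rate must be >= 0")

    @classmethod
    def constant(
        cls,
        annotations: Sequence[IesAnnotation],
        retention: float = 0.5,
        alt: float = 0.0,
        density: float = 1.0,
        cryptic_rate: float = 0.0,
    ) -> "TruthTable":
        ids = [a.ies_id for a in annotations]
        return cls(
            retention_prob={i: retention for i in ids},
            alt_prob={i: alt for i in ids},
            density_multiplier={i: density for i in ids},
            cryptic_rate=cryptic_rate,
        )

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.retention_prob)
        return pd.DataFrame(
            {
                "ies_id": ids,
                "retention_prob": [self.retention_prob[i] for i in ids],
                "alt_prob": [self.alt_prob[i] for i in ids],
                "density_multiplier": [self.density_multiplier[i] for i in ids],
                "cryptic_rate": self.cryptic_rate,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            retention_prob=dict(zip(df.ies_id, df.retention_prob)),
            alt_prob=dict(zip(df.ies_id, df.alt_prob)),
            density_multiplier=dict(zip(df.ies_id, df.density_multiplier)),
            cryptic_rate=float(df.cryptic_rate.iloc[0]) if len(df) else 0.0,
        )


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n, p=_BASE_P))


def _plant_ta(seq: list[str], pos: int) -> None:
    seq[pos] = "T"
    seq[pos + 1] = "A"


def _scrub_ta(seq: list[str], lo: int, hi: int) -> None:
    """Remove accidental TA dinucleotides from seq[lo:hi] (in place)."""
    for p in range(max(lo, 0), min(hi, len(seq) - 1)):
        if seq[p] == "T" and seq[p + 1] == "A":
            seq[p] = "C"


def _make_ies_seq(rng: np.random.Generator, length: int) -> list[str]:
    """IES sequence beginning with TA, with interior alternative TA sites
    planted just inside both boundaries when there is room.

    Plant distances of 2-4 bp model excision slipping to the next closest
    TA, so alternative lengths stay close to the reference length.
    """
    s = _random_seq(rng, length)
    _plant_ta(s, 0)
    if length >= 26:
        _plant_ta(s, int(rng.integers(2, 5)))
        _plant_ta(s, length - int(rng.integers(2, 5)))
    return s


def _draw_ies_length(rng: np.random.Generator, cfg: SimConfig) -> int:
    centers = np.array([c for c, _ in cfg.ies_length_peaks])
    weights = np.array([w for _, w in cfg.ies_length_peaks], dtype=float)
    weights /= weights.sum()
    c = int(rng.choice(centers, p=weights))
    return max(22, c + int(rng.integers(-2, 3)))


def generate_genome(
    cfg: SimConfig,
) -> tuple[GenomeAssembly, GenomeAssembly, list[IesAnnotation]]:
    """Build a MAC+IES assembly, its MAC counterpart, and IES annotations.

    Each IES satisfies the two-TA convention by construction; its flanks
    carry at least one additional TA within 20 bp outside each canonical
    boundary, and (for IESs >= 26 bp) interior TA sites near each boundary,
    so both internal and external alternative excisions are possible.
    IESs are separated by at least one read length of MAC-destined
    sequence.
    """
    rng = cfg.rng(0)
    per_contig = [cfg.n_ies // cfg.n_contigs] * cfg.n_contigs
    for i in range(cfg.n_ies % cfg.n_contigs):
        per_contig[i] += 1

    mac_plus: dict[str, str] = {}
    mac: dict[str, str] = {}
    annotations: list[IesAnnotation] = []
    ies_counter = 0

    for ci in range(cfg.n_contigs):
        name = f"contig_{ci + 1}"
        n = per_contig[ci]
        lengths = [_draw_ies_length(rng, cfg) for _ in range(n)]
        spacing = (cfg.contig_length - sum(lengths)) // (n + 1) if n else cfg.contig_length
        if n and spacing < cfg.read_length + 60:
            raise ValueError(
                f"cannot place {n} IESs in a {cfg.contig_length} bp contig "
                f"with >= {cfg.read_length + 60} bp separation"
            )
        chunks: list[str] = []
        mac_chunks: list[str] = []
        pos = 0
        for k in range(n):
            mds = _random_seq(rng, spacing)
            if k == 0:
                # keep the promoter-side flank clear of stray boundary TAs
                _scrub_ta(mds, spacing - 24, spacing)
            # external alternative site just upstream of the canonical left TA
            _plant_ta(mds, spacing - int(rng.integers(2, 6)))
            ies_len = lengths[k]
            ies = _make_ies_seq(rng, ies_len)
            start = pos + spacing
            end = start + ies_len
            ies_counter += 1
            annotations.append(
                IesAnnotation(
                    contig=name, start=start, end=end, ies_id=f"ies_{ies_counter:05d}"
                )
            )
            chunks.append("".join(mds))
            chunks.append("".join(ies))
            mac_chunks.append("".join(mds))
            pos = end
        tail = _random_seq(rng, spacing if n else cfg.contig_length)
        if n:
            # the retained junction TA, plus an external alternative site
            _plant_ta(tail, 0)
            _plant_ta(tail, int(rng.integers(3, 7)))
        chunks.append("".join(tail))
        mac_chunks.append("".join(tail))
        mac_plus[name] = "".join(chunks)
        mac[name] = "".join(mac_chunks)

    # junction TA for every non-terminal IES: the first two bases of the
    # following MDS chunk must read TA.  The loop above emits MDS chunks
    # before their IES, so fix up in a second pass over the flat string.
    fixed = {}
    for name in mac_plus:
        s = list(mac_plus[name])
        for a in annotations:
            if a.contig != name:
                continue
            _plant_ta(s, a.end)
            # external alternative site just beyond the junction TA
            _plant_ta(s, a.end + int(rng.integers(3, 7)))
        fixed[name] = "".join(s)
    mac_plus = fixed
    # rebuild MAC from MAC+IES so junction edits are reflected
    mac = {}
    for name in mac_plus:
        s = mac_plus[name]
        keep = []
        prev = 0
        for a in sorted(x for x in annotations if x.contig == name):
            keep.append(s[prev : a.start])
            prev = a.end
        keep.append(s[prev:])
        mac[name] = "".join(keep)

    annotations.sort()
    return (
        GenomeAssembly(contigs=mac_plus, flavor=AssemblyFlavor.MAC_PLUS_IES),
        GenomeAssembly(contigs=mac, flavor=AssemblyFlavor.MAC),
        annotations,
    )


@dataclass
class SimulatedRead:
    """One simulated alignment on the MAC+IES reference."""

    read_id: str
    contig: str
    pos: int
    cigar: list[tuple[int, int]]  # pysam op codes: 0=M, 2=D
    seq: str
    category: str  # non_ies | retained | correct | alternative | cryptic
    ies_ids: str  # comma-joined IESs whose boundaries the read informs
    gaps: str  # comma-joined "start-end:kind"

    @property
    def cigarstring(self) -> str:
        return "".join(f"{ln}{'MIDNSHP=X'[op]}" for op, ln in self.cigar)


def _alt_boundary(
    seq: str,
    canonical: int,
    window: int = 20,
    geom_p: float = 0.45,
) -> list[tuple[int, float]]:
    """Candidate TA boundaries within +/-window of a canonical one, weighted
    geometrically by distance rank (nearest alternatives favoured)."""
    lo = max(0, canonical - window)
    hi = min(len(seq) - 2, canonical + window)
    sites = [
        p
        for p in range(lo, hi + 1)
        if seq[p : p + 2] == "TA" and p != canonical
    ]
    sites.sort(key=lambda p: (abs(p - canonical), p))
    return [(p, geom_p * (1 - geom_p) ** r) for r, p in enumerate(sites)]


def _choose_gap(
    rng: np.random.Generator,
    seq: str,
    ies: IesAnnotation,
    alt: bool,
    min_len: int = 20,
) -> tuple[int, int, str]:
    """Excision interval for one IES molecule: canonical or alternative."""
    if not alt:
        return ies.start, ies.end, "correct"
    lefts = _alt_boundary(seq, ies.start) + [(ies.start, 1.0)]
    rights = _alt_boundary(seq, ies.end) + [(ies.end, 1.0)]
    pairs = []
    for lp, lw in lefts:
        for rp, rw in rights:
            if (lp, rp) == (ies.start, ies.end):
                continue
            if rp - lp >= min_len:
                pairs.append(((lp, rp), lw * rw))
    if not pairs:
        return ies.start, ies.end, "correct"  # no alternative pair: fall back
    w = np.array([p[1] for p in pairs])
    idx = rng.choice(len(pairs), p=w / w.sum())
    lp, rp = pairs[idx][0]
    return lp, rp, "alternative"


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hit = rng.random(len(arr)) < rate
    if hit.any():
        subs = rng.choice(_BASES, size=int(hit.sum()))
        for i, j in enumerate(np.flatnonzero(hit)):
            cur = arr[j]
            arr[j] = subs[i] if subs[i] != cur else ("A" if cur != "A" else "C")
    return "".join(arr)


def simulate_dna_reads(
    genome: GenomeAssembly,
    annotations: Sequence[IesAnnotation],
    truth: TruthTable,
    cfg: SimConfig,
    stream: int = 1,
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Anlagen DNA-seq reads over the MAC+IES reference.

    ``stream`` selects an independent random stream under the same seed,
    e.g. for biological-replicate libraries over one genome and truth.

    Each read is drawn from an independent molecule: per overlapped IES the
    molecule is retained with probability rho_i, otherwise excised at the
    canonical TA pair (probability 1 - alpha_i) or at an alternative TA
    pair within +/-20 bp of the canonical boundaries.  Cryptic excisions
    between MDS TA pairs occur at rate kappa per read per kb covered.
    Excision gaps appear as CIGAR deletions; reads are returned coordinate
    sorted.
    """
    rng = cfg.rng(stream)
    for a in annotations:
        if a.ies_id not in truth.retention_prob:
            raise ValueError(f"truth table missing IES {a.ies_id}")
    contigs = genome.names
    lens = np.array([genome.length(c) for c in contigs], dtype=float)
    n_reads = int(round(cfg.coverage * lens.sum() / cfg.read_length))
    by_contig = {c: sorted(a for a in annotations if a.contig == c) for c in contigs}

    reads: list[SimulatedRead] = []
    truth_rows: list[dict] = []

    contig_choice = rng.choice(len(contigs), size=n_reads, p=lens / lens.sum())
    for ri in range(n_reads):
        contig = contigs[contig_choice[ri]]
        seq = genome.sequence(contig)
        L = len(seq)
        anns = by_contig[contig]
        for _attempt in range(8):
            p = int(rng.integers(0, max(1, L - cfg.read_length)))
            # molecule decisions for IESs near the read window
            window_hi = p + cfg.read_length + 400
            gaps: list[tuple[int, int, str, str]] = []
            informative: list[str] = []
            retained_any = False
            ok = True
            for a in anns:
                if a.end + 20 < p or a.start - 20 > window_hi:
                    continue
                if rng.random() < truth.retention_prob[a.ies_id]:
                    retained_any = True
                    informative.append(a.ies_id)
                    continue
                alt = rng.random() < truth.alt_prob[a.ies_id]
                gs, ge, kind = _choose_gap(rng, seq, a, alt)
                if gs <= p < ge:  # read cannot start inside an excised span
                    ok = False
                    break
                gaps.append((gs, ge, kind, a.ies_id))
            if ok:
                break
        else:
            continue
        gaps.sort()

        # cryptic excisions between MDS TA pairs inside the window
        kappa = truth.cryptic_rate
        if kappa > 0:
            n_cryptic = rng.poisson(kappa * cfg.read_length / 1000.0)
            for _ in range(n_cryptic):
                cg = _draw_cryptic_gap(rng, seq, anns, gaps, p, cfg.read_length)
                if cg is not None:
                    gaps.append((cg[0], cg[1], "cryptic", ""))
            gaps.sort()

        cigar, read_seq, used = _build_alignment(seq, p, cfg.read_length, gaps)
        read_seq = _apply_errors(rng, read_seq, cfg.error_rate)
        kinds = {k for _, _, k, _ in used}
        if "cryptic" in kinds:
            category = "cryptic"
        elif "alternative" in kinds:
            category = "alternative"
        elif "correct" in kinds:
            category = "correct"
        elif retained_any and _crosses_boundary(p, p + _ref_span(cigar), anns):
            category = "retained"
        else:
            category = "non_ies"
        ies_ids = sorted({g[3] for g in used if g[3]} | set(informative))
        read = SimulatedRead(
            read_id=f"read_{ri:08d}",
            contig=contig,
            pos=p,
            cigar=cigar,
            seq=read_seq,
            category=category,
            ies_ids=",".join(ies_ids),
            gaps=",".join(f"{g[0]}-{g[1]}:{g[2]}" for g in used),
        )
        reads.append(read)
        truth_rows.append(
            {
                "read_id": read.read_id,
                "contig": contig,
                "pos": p,
                "category": category,
                "ies_ids": read.ies_ids,
                "gaps": read.gaps,
            }
        )

    order = sorted(range(len(reads)), key=lambda i: (reads[i].contig, reads[i].pos))
    reads = [reads[i] for i in order]
    truth_df = pd.DataFrame(truth_rows).iloc[order].reset_index(drop=True)
    return reads, truth_df


def _ref_span(cigar: list[tuple[int, int]]) -> int:
    return sum(ln for op, ln in cigar if op in (0, 2, 3))


def _crosses_boundary(start: int, end: int, anns: Sequence[IesAnnotation]) -> bool:
    for a in anns:
        if start < a.start < end or start < a.end < end:
            return True
    return False


def _draw_cryptic_gap(
    rng: np.random.Generator,
    seq: str,
    anns: Sequence[IesAnnotation],
    gaps: list,
    p: int,
    read_length: int,
) -> tuple[int, int] | None:
    """A TA-bounded gap of 20-70 bp in MDS sequence inside the read window,
    clear of annotated IESs and already-chosen gaps."""
    lo, hi = p + 12, p + read_length + 30
    candidates = []
    q = seq.find("TA", lo)
    while 0 <= q < hi:
        candidates.append(q)
        q = seq.find("TA", q + 1)

    def clear(a: int, b: int) -> bool:
        for ann in anns:
            if a < ann.end + 20 and ann.start - 20 < b:
                return False
        for gs, ge, *_ in gaps:
            if a < ge and gs < b:
                return False
        return True

    rng.shuffle(candidates)
    for left in candidates:
        rights = [r for r in candidates if 20 <= r - left <= 70]
        rng.shuffle(rights)
        for right in rights:
            if clear(left, right):
                return left, right
    return None


def _build_alignment(
    seq: str, p: int, read_length: int, gaps: list
) -> tuple[list[tuple[int, int]], str, list]:
    """Walk the reference from p, skipping excised intervals, until
    read_length bases are matched.  Returns (cigar, read sequence,
    gaps actually spanned)."""
    cigar: list[tuple[int, int]] = []
    pieces: list[str] = []
    used = []
    cur = p
    matched = 0
    gi = 0
    gaps = [g for g in gaps if g[1] > p]
    L = len(seq)
    while matched < read_length and cur < L:
        next_gap = gaps[gi] if gi < len(gaps) else None
        limit = next_gap[0] if next_gap else L
        take = min(read_length - matched, limit - cur)
        if take > 0:
            cigar.append((0, take))
            pieces.append(seq[cur : cur + take])
            cur += take
            matched += take
        if matched >= read_length:
            break
        if next_gap and cur == next_gap[0]:
            cigar.append((2, next_gap[1] - next_gap[0]))
            used.append(next_gap)
            cur = next_gap[1]
            gi += 1
        elif next_gap is None:
            break
    # merge adjacent M ops
    merged: list[tuple[int, int]] = []
    for op, ln in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    # trailing deletion carries no information: drop it
    while merged and merged[-1][0] == 2:
        merged.pop()
        used.pop()
    return merged, "".join(pieces), used


@dataclass
class SimulatedFragment:
    """One paired-end nucleosomal (or DNA) fragment on the MAC+IES assembly."""

    frag_id: str
    contig: str
    start: int
    size: int
    segment: str  # "MDS" or an ies_id


def simulate_nucleosomal_fragments(
    genome: GenomeAssembly,
    annotations: Sequence[IesAnnotation],
    truth: TruthTable,
    cfg: SimConfig,
    n_fragments: int,
    stream: int = 2,
) -> tuple[list[SimulatedFragment], pd.DataFrame]:
    """Paired-end mononucleosome-like fragments.

    Fragment midpoints land with base rate 1 per bp of MAC-destined
    sequence and rate lambda_i per bp over IES i; outer sizes follow a
    normal(mean 147, sd 15) truncated to [80, 250], so the downstream
    [100, 175] mononucleosome filter is exercised on both sides.
    """
    rng = cfg.rng(stream)
    segments: list[tuple[str, int, int, str, float]] = []
    for contig in genome.names:
        L = genome.length(contig)
        prev = 0
        for a in sorted(x for x in annotations if x.contig == contig):
            if a.start > prev:
                segments.append((contig, prev, a.start, "MDS", 1.0))
            segments.append(
                (contig, a.start, a.end, a.ies_id, truth.density_multiplier[a.ies_id])
            )
            prev = a.end
        if prev < L:
            segments.append((contig, prev, L, "MDS", 1.0))

    weights = np.array([(e - s) * w for _, s, e, _, w in segments], dtype=float)
    probs = weights / weights.sum()
    a_t = (cfg.frag_size_min - cfg.frag_size_mean) / cfg.frag_size_sd
    b_t = (cfg.frag_size_max - cfg.frag_size_mean) / cfg.frag_size_sd

    frags: list[SimulatedFragment] = []
    rows: list[dict] = []
    seg_idx = rng.choice(len(segments), size=n_fragments, p=probs)
    sizes = truncnorm.rvs(
        a_t, b_t, loc=cfg.frag_size_mean, scale=cfg.frag_size_sd,
        size=n_fragments, random_state=rng,
    )
    for fi in range(n_fragments):
        contig, s, e, label, _ = segments[seg_idx[fi]]
        size = int(round(sizes[fi]))
        mid = int(rng.integers(s, e))
        start = mid - size // 2
        L = genome.length(contig)
        start = max(0, min(start, L - size))
        if start < 0:  # contig shorter than the fragment
            continue
        frag = SimulatedFragment(
            frag_id=f"frag_{fi:08d}", contig=contig, start=start, size=size,
            segment=label,
        )
        frags.append(frag)
        rows.append(dataclasses.asdict(frag))
    frags.sort(key=lambda f: (f.contig, f.start))
    truth_df = pd.DataFrame(
        rows, columns=["frag_id", "contig", "start", "size", "segment"]
    ).sort_values(["contig", "start"], kind="stable").reset_index(drop=True)
    return frags, truth_df


def _sam_header(genome: GenomeAssembly) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": genome.length(name)} for name in genome.names
            ],
        }
    )


def to_aligned_reads(reads: Sequence[SimulatedRead]):
    """In-memory adapter: simulated reads as analysis-layer AlignedRead."""
    from .excision import AlignedRead

    return [
        AlignedRead(
            read_id=r.read_id, contig=r.contig, pos=r.pos, cigar=tuple(r.cigar)
        )
        for r in reads
    ]


def to_fragments(frags: Sequence[SimulatedFragment]):
    """In-memory adapter: simulated fragments as analysis-layer Fragment."""
    from .nucleosome import Fragment

    return [
        Fragment(f.frag_id, f.contig, f.start, f.start + f.size) for f in frags
    ]


def write_sam(
    reads: Sequence[SimulatedRead], genome: GenomeAssembly, path: str | Path
) -> None:
    """Coordinate-sorted SAM of simulated single-end reads."""
    header = _sam_header(genome)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in sorted(reads, key=lambda x: (x.contig, x.pos)):
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_id
            seg.query_sequence = r.seq
            seg.flag = 0
            seg.reference_id = genome.names.index(r.contig)
            seg.reference_start = r.pos
            seg.mapping_quality = 60
            seg.cigartuples = r.cigar
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            out.write(seg)


def write_fragment_sam(
    frags: Sequence[SimulatedFragment],
    genome: GenomeAssembly,
    path: str | Path,
    read_length: int = 50,
) -> None:
    """Coordinate-sorted paired-end SAM of fragments; mates anchor the two
    fragment ends and TLEN records the outer distance."""
    header = _sam_header(genome)
    records = []
    for f in frags:
        rl = min(read_length, f.size)
        seq = genome.sequence(f.contig)
        tid = genome.names.index(f.contig)
        r1 = pysam.AlignedSegment(header)
        r1.query_name = f.frag_id
        r1.flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate-reverse, first
        r1.reference_id = tid
        r1.reference_start = f.start
        r1.mapping_quality = 60
        r1.cigartuples = [(0, rl)]
        r1.query_sequence = seq[f.start : f.start + rl]
        r1.next_reference_id = tid
        r1.next_reference_start = f.start + f.size - rl
        r1.template_length = f.size
        r2 = pysam.AlignedSegment(header)
        r2.query_name = f.frag_id
        r2.flag = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second
        r2.reference_id = tid
        r2.reference_start = f.start + f.size - rl
        r2.mapping_quality = 60
        r2.cigartuples = [(0, rl)]
        r2.query_sequence = seq[f.start + f.size - rl : f.start + f.size]
        r2.next_reference_id = tid
        r2.next_reference_start = f.start
        r2.template_length = -f.size
        records.extend([r1, r2])
    records.sort(key=lambda s: (s.reference_id, s.reference_start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)


def write_fastq(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as out:
        for r in reads:
            out.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_dataset(
    outdir: str | Path,
    cfg: SimConfig,
    truth: TruthTable,
    n_nucleosomal: int = 0,
) -> dict[str, str]:
    """Generate and write a complete synthetic dataset; returns a manifest
    of output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mac_plus, mac, annotations = generate_genome(cfg)
    if set(truth.retention_prob) != {a.ies_id for a in annotations}:
        truth = TruthTable(
            retention_prob={a.ies_id: truth.retention_prob.get(a.ies_id, 0.0) for a in annotations},
            alt_prob={a.ies_id: truth.alt_prob.get(a.ies_id, 0.0) for a in annotations},
            density_multiplier={a.ies_id: truth.density_multiplier.get(a.ies_id, 1.0) for a in annotations},
            cryptic_rate=truth.cryptic_rate,
        )
    manifest = {}
    write_genome(mac_plus, outdir / "mac_plus_ies.fa")
    write_genome(mac, outdir / "mac.fa")
    write_ies_annotations(annotations, outdir / "ies.gff3")
    truth.to_tsv(outdir / "truth_ies.tsv")
    reads, read_truth = simulate_dna_reads(mac_plus, annotations, truth, cfg)
    write_sam(reads, mac_plus, outdir / "dna.sam")
    write_fastq(reads, outdir / "dna.fastq")
    read_truth.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    manifest.update(
        {
            "mac_plus_ies_fasta": str(outdir / "mac_plus_ies.fa"),
            "mac_fasta": str(outdir / "mac.fa"),
            "ies_gff3": str(outdir / "ies.gff3"),
            "truth_ies": str(outdir / "truth_ies.tsv"),
            "dna_sam": str(outdir / "dna.sam"),
            "dna_fastq": str(outdir / "dna.fastq"),
            "truth_reads": str(outdir / "truth_reads.tsv"),
        }
    )
    if n_nucleosomal > 0:
        frags, frag_truth = simulate_nucleosomal_fragments(
            mac_plus, annotations, truth, cfg, n_nucleosomal
        )
        write_fragment_sam(frags, mac_plus, outdir / "nucleosomal.sam",
                           read_length=cfg.nucleosome_read_length)
        frag_truth.to_csv(outdir / "truth_fragments.tsv", sep="\t", index=False)
        manifest["nucleosomal_sam"] = str(outdir / "nucleosomal.sam")
        manifest["truth_fragments"] = str(outdir / "truth_fragments.tsv")
    return manifest
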