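"""Reference-genome data model for *Paramecium* IES analysis.

The germline-inclusive assembly ("MAC+IES") carries every internal
eliminated sequence (IES) inserted at its somatic position; the somatic
assembly ("MAC") is the same sequence with all IES intervals deleted.
Internally every interval is 0-based half-open; GFF3 input/output converts
to and from the 1-based inclusive convention at the boundary.

The TA convention used throughout: an annotated IES interval [start, end)
begins with the dinucleotide ``TA`` and the reference carries a second
``TA`` at [end, end+2).  Excision removes [start, end) exactly, so the
retained downstream copy reconstitutes a single ``TA`` at the somatic
junction and the excised-read gap length equals the annotated IES length.
"""

from __future__ import annotations

import bisect
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

__all__ = [
    "AssemblyFlavor",
    "GenomeAssembly",
    "IesAnnotation",
    "CoordinateMap",
    "IesInternalPosition",
    "GenomeError",
    "load_genome",
    "write_genome",
    "load_ies_annotations",
    "write_ies_annotations",
    "validate_ta_boundaries",
    "enumerate_ta_sites",
    "project_to_mac",
]

_ALPHABET = frozenset("ACGTN")

IES_FEATURE_TYPE = "internal_eliminated_sequence"


class GenomeError(ValueError):
    """Malformed genome or annotation input."""


class AssemblyFlavor(str, enum.Enum):
    MAC = "MAC"
    MAC_PLUS_IES = "MAC_PLUS_IES"


@dataclass
class GenomeAssembly:
    """An ordered collection of uppercase contig sequences."""

    contigs: dict[str, str]
    flavor: AssemblyFlavor

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - _ALPHABET
            if bad:
                raise GenomeError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def sequence(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise GenomeError(f"unknown contig {contig!r}") from None

    def length(self, contig: str) -> int:
        return len(self.sequence(contig))

    @property
    def names(self) -> list[str]:
        return list(self.contigs)


@dataclass(frozen=True, order=True)
class IesAnnotation:
    """One annotated IES on the MAC+IES assembly (0-based half-open)."""

    contig: str
    start: int
    end: int
    ies_id: str = field(compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise GenomeError(
                f"IES {self.ies_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


class IesInternalPosition(Exception):
    """Raised when projecting a MAC+IES position that lies inside an IES.

    Such positions have no somatic (MAC) image; callers must handle the
    signal explicitly rather than receive a silently clamped coordinate.
    """

    def __init__(self, contig: str, pos: int, ies_id: str):
        self.contig, self.pos, self.ies_id = contig, pos, ies_id
        super().__init__(f"{contig}:{pos} lies inside IES {ies_id}")


class CoordinateMap:
    """Projection between MAC+IES and MAC coordinates of one assembly.

    Built from the sorted IES intervals of each contig; a MAC+IES position
    maps to MAC by subtracting the total IES length strictly upstream.
    """

    def __init__(self, annotations: Iterable[IesAnnotation]):
        per_contig: dict[str, list[IesAnnotation]] = {}
        for a in annotations:
            per_contig.setdefault(a.contig, []).append(a)
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._cum: dict[str, list[int]] = {}
        self._ids: dict[str, list[str]] = {}
        for contig, anns in per_contig.items():
            anns.sort()
            prev_end = -1
            for a in anns:
                if a.start < prev_end:
                    raise GenomeError(f"overlapping IESs on {contig}")
                prev_end = a.end
            self._starts[contig] = [a.start for a in anns]
            self._ends[contig] = [a.end for a in anns]
            self._ids[contig] = [a.ies_id for a in anns]
            cum, tot = [], 0
            for a in anns:
                tot += a.length
                cum.append(tot)
            self._cum[contig] = cum

    def to_mac(self, contig: str, pos: int) -> int:
        starts = self._starts.get(contig, [])
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and pos < self._ends[contig][i]:
            raise IesInternalPosition(contig, pos, self._ids[contig][i])
        upstream = self._cum[contig][i] if i >= 0 else 0
        return pos - upstream

    def to_mac_plus_ies(self, contig: str, mac_pos: int) -> int:
        """Inverse projection; total by construction on MAC positions."""
        starts = self._starts.get(contig, [])
        ends = self._ends.get(contig, [])
        cum = self._cum.get(contig, [])
        pos = mac_pos
        for i in range(len(starts)):
            upstream = cum[i - 1] if i > 0 else 0
            if mac_pos + upstream >= starts[i]:
                pos = mac_pos + cum[i]
            else:
                break
        return pos


def load_genome(path: str | Path, flavor: AssemblyFlavor) -> GenomeAssembly:
    """Read a FASTA assembly, uppercasing sequences and preserving order."""
    path = Path(path)
    contigs: dict[str, str] = {}
    n = 0
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            n += 1
            if record.id in contigs:
                raise GenomeError(f"duplicate contig name {record.id!r} in {path}")
            contigs[record.id] = str(record.seq).upper()
    if n == 0:
        raise GenomeError(f"no FASTA records in {path}")
    return GenomeAssembly(contigs=contigs, flavor=flavor)


def write_genome(assembly: GenomeAssembly, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in assembly.contigs.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=80)
        writer.write_file(records)


def load_ies_annotations(
    path: str | Path, genome: GenomeAssembly
) -> list[IesAnnotation]:
    """Read IES features from GFF3 (1-based inclusive) into internal 0-based
    half-open annotations, sorted by (contig, start)."""
    if genome.flavor is not AssemblyFlavor.MAC_PLUS_IES:
        raise GenomeError("IES annotations require a MAC_PLUS_IES assembly")
    annotations: list[IesAnnotation] = []
    seen: set[str] = set()
    with open(path) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype != IES_FEATURE_TYPE:
                continue
            ids = feat.attributes.get("ID", [])
            ies_id = ids[0] if ids else f"{feat.seqid}:{feat.start}-{feat.end}"
            if ies_id in seen:
                raise GenomeError(f"duplicate IES ID {ies_id!r}")
            seen.add(ies_id)
            if feat.seqid not in genome:
                raise GenomeError(f"IES {ies_id} on unknown contig {feat.seqid!r}")
            start, end = feat.start - 1, feat.end  # GFF3 -> half-open
            if not 0 <= start < end <= genome.length(feat.seqid):
                raise GenomeError(f"IES {ies_id} outside contig bounds")
            annotations.append(
                IesAnnotation(contig=feat.seqid, start=start, end=end, ies_id=ies_id)
            )
    annotations.sort()
    return annotations


def write_ies_annotations(
    annotations: Iterable[IesAnnotation], path: str | Path, source: str = "ieskit"
) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for a in sorted(annotations):
            handle.write(
                "\t".join(
                    [
                        a.contig,
                        source,
                        IES_FEATURE_TYPE,
                        str(a.start + 1),
                        str(a.end),
                        ".",
                        "+",
                        ".",
                        f"ID={a.ies_id}",
                    ]
                )
                + "\n"
            )


def validate_ta_boundaries(
    genome: GenomeAssembly, annotations: Iterable[IesAnnotation]
) -> pd.DataFrame:
    """Check the two-TA structure of every IES.

    An IES passes iff its interval begins with ``TA`` and the reference
    carries the retained junction copy ``TA`` immediately downstream.
    Failures are reported, never raised.
    """
    rows = []
    for a in annotations:
        seq = genome.sequence(a.contig)
        if a.end + 2 > len(seq):
            ok, reason = False, "truncated"
        elif seq[a.start : a.start + 2] != "TA":
            ok, reason = False, "no left TA"
        elif seq[a.end : a.end + 2] != "TA":
            ok, reason = False, "no right TA"
        else:
            ok, reason = True, ""
        rows.append({"ies_id": a.ies_id, "pass": ok, "reason": reason})
    return pd.DataFrame(rows, columns=["ies_id", "pass", "reason"])


def enumerate_ta_sites(
    genome: GenomeAssembly, contig: str, window: tuple[int, int]
) -> list[int]:
    """All positions p with sequence[p:p+2] == "TA" and [p, p+2) inside
    the window.  ``N`` never matches.
    """
    seq = genome.sequence(contig)
    lo, hi = window
    if not 0 <= lo <= hi <= len(seq):
        raise GenomeError(f"window {window} out of bounds for {contig}")
    sites = []
    p = seq.find("TA", lo)
    while 0 <= p and p + 2 <= hi:
        sites.append(p)
        p = seq.find("TA", p + 1)
    return sites


def project_to_mac(cm: CoordinateMap, contig: str, pos: int) -> int:
    """MAC coordinate of a MAC+IES position; raises IesInternalPosition
    for positions inside an IES."""
    return cm.to_mac(contig, pos)
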