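"""Event calling: gap extraction, TA-bounded classification, aggregation,
and equivalence to an independent brute-force oracle."""

import numpy as np
import pytest

from ieskit.excision import (
    ALT_EXTERNAL,
    ALT_INTERNAL,
    ALT_OVERLAPPING,
    CORRECT,
    CRYPTIC,
    AlignedRead,
    CandidateGap,
    Rejection,
    aggregate_events,
    call_events,
    classify_gap,
    extract_gaps,
    parse_alignments,
)
from ieskit.genome import AssemblyFlavor, GenomeAssembly, IesAnnotation
from ieskit.simulate import (
    SimConfig,
    TruthTable,
    generate_genome,
    simulate_dna_reads,
    to_aligned_reads,
    write_sam,
)


def _cigar(s):
    """'40M28D35M' -> pysam-style tuples."""
    out, num = [], ""
    for ch in s:
        if ch.isdigit():
            num += ch
        else:
            out.append(("MIDNSHP=X".index(ch), int(num)))
            num = ""
    return tuple(out)


class TestParseAlignments:
    def test_streams_primary_mapped_reads(self, tmp_path, small_cfg, small_genome):
        mac_plus, _, annotations = small_genome
        truth = TruthTable.constant(annotations, retention=0.5)
        reads, _ = simulate_dna_reads(mac_plus, annotations, truth, small_cfg)
        sam = tmp_path / "r.sam"
        write_sam(reads[:200], mac_plus, sam)
        parsed = list(parse_alignments(sam))
        assert len(parsed) == 200
        assert parsed[0].cigar == tuple(reads[0].cigar) or len(parsed[0].cigar) > 0

    def test_secondary_and_low_mapq_dropped(self, tmp_path):
        sam = tmp_path / "t.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:c\tLN:200\n"
            "r1\t0\tc\t1\t60\t40M28D35M\t*\t0\t0\t" + "A" * 75 + "\t*\n"
            "r2\t256\tc\t1\t60\t75M\t*\t0\t0\t" + "A" * 75 + "\t*\n"  # secondary
            "r3\t0\tc\t1\t3\t75M\t*\t0\t0\t" + "A" * 75 + "\t*\n"  # mapq 3
            "r4\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 75 + "\t*\n"  # unmapped
        )
        parsed = list(parse_alignments(sam, min_mapq=10))
        assert [r.read_id for r in parsed] == ["r1"]
        assert parsed[0].cigar == _cigar("40M28D35M")

    def test_empty_sam(self, tmp_path):
        sam = tmp_path / "e.sam"
        sam.write_text("@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:c\tLN:10\n")
        assert list(parse_alignments(sam)) == []


class TestExtractGaps:
    @pytest.mark.parametrize(
        "cigar,expected",
        [
            ("40M28D35M", [(40, 68, 28)]),  # (gap_start, gap_end, length) at pos 0
            ("5M28D70M", []),  # left anchor below threshold
            ("30M26N30M10D5M", [(30, 56, 26)]),  # short D fails min_gap
            ("75M", []),
        ],
    )
    def test_rules(self, cigar, expected):
        read = AlignedRead("r", "c", 0, _cigar(cigar))
        gaps = extract_gaps(read, min_gap=20, min_anchor=10)
        assert [(g.gap_start, g.gap_end, g.length) for g in gaps] == expected

    def test_two_qualifying_gaps_both_reported(self):
        read = AlignedRead("r", "c", 100, _cigar("20M30D20M25N20M"))
        gaps = extract_gaps(read)
        assert [(g.gap_start, g.gap_end) for g in gaps] == [
            (120, 150),
            (170, 195),
        ]


class TestClassifyGap:
    def _setup(self):
        # IES [30, 58) on a 200-bp contig; TA planted where needed
        seq = list("G" * 200)

        def plant(p):
            seq[p], seq[p + 1] = "T", "A"

        for p in (30, 58, 36, 50, 24, 64, 100, 130):
            plant(p)
        genome = GenomeAssembly({"c": "".join(seq)}, AssemblyFlavor.MAC_PLUS_IES)
        ann = [IesAnnotation(contig="c", start=30, end=58, ies_id="i1")]
        return genome, ann

    def _gap(self, s, e):
        return CandidateGap("c", s, e, 20, 20, "r")

    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((30, 58), CORRECT),
            ((36, 58), ALT_INTERNAL),  # inside the IES
            ((30, 50), ALT_INTERNAL),
            ((24, 64), ALT_EXTERNAL),  # strictly containing it
            ((24, 50), ALT_OVERLAPPING),  # one boundary outside
            ((36, 64), ALT_OVERLAPPING),
            ((100, 130), CRYPTIC),  # no annotated IES overlapped
        ],
    )
    def test_classes(self, interval, expected):
        genome, ann = self._setup()
        ev = classify_gap(self._gap(*interval), ann, genome)
        assert ev.classification == expected
        if expected == CRYPTIC:
            assert ev.matched_ies_id == ""
        else:
            assert ev.matched_ies_id == "i1"

    def test_non_ta_gaps_rejected_with_reason(self):
        genome, ann = self._setup()
        left = classify_gap(self._gap(31, 58), ann, genome)
        assert isinstance(left, Rejection) and left.reason == "no-TA-left"
        right = classify_gap(self._gap(30, 57), ann, genome)
        assert isinstance(right, Rejection) and right.reason == "no-TA-right"


class TestAggregate:
    def test_identical_gaps_merged_with_support(self):
        genome = GenomeAssembly(
            {"c": "G" * 40 + "TA" + "G" * 26 + "TA" + "G" * 40},
            AssemblyFlavor.MAC_PLUS_IES,
        )
        ann = [IesAnnotation(contig="c", start=40, end=68, ies_id="i1")]
        reads = [
            AlignedRead(f"r{i}", "c", 20, _cigar("20M28D30M")) for i in range(2)
        ]
        events, per_ies, cryptic, rej = call_events(reads, ann, genome)
        assert len(events) == 1
        assert events[0].support == 2
        assert per_ies.loc[0, "n_correct"] == 2
        assert cryptic.empty and not rej

    def test_empty_input(self):
        events, per_ies, cryptic = aggregate_events([])
        assert events == [] and per_ies.empty and cryptic.empty


# ---------------------------------------------------------------------------
# independent brute-force oracle


def _oracle_events(reads, annotations, genome, min_gap=20, min_anchor=10):
    """Re-derive the event set by exhaustive scanning, sharing no code with
    the classifier: every read's CIGAR is walked position by position, every
    TA site is found by naive string scan, and the matched IES is chosen by
    exhaustive comparison over all annotations."""
    events = set()
    for read in reads:
        seq = genome.sequence(read.contig)
        ta_sites = {p for p in range(len(seq) - 1) if seq[p : p + 2] == "TA"}
        # walk cigar
        ref = read.pos
        aligned = sum(ln for op, ln in read.cigar if op in (0, 7, 8))
        left = 0
        for op, ln in read.cigar:
            if op in (0, 7, 8):
                left += ln
                ref += ln
            elif op in (2, 3):
                gs, ge = ref, ref + ln
                ref += ln
                if ln < min_gap or left < min_anchor or aligned - left < min_anchor:
                    continue
                if gs not in ta_sites or ge not in ta_sites:
                    continue
                overlapping = [
                    a
                    for a in annotations
                    if a.contig == read.contig and a.start < ge and a.end > gs
                ]
                if not overlapping:
                    events.add((read.contig, gs, ge, CRYPTIC, "", read.read_id))
                    continue
                best, best_key = None, None
                for a in overlapping:
                    ov = min(ge, a.end) - max(gs, a.start)
                    rec = min(ov / (ge - gs), ov / a.length)
                    key = (rec, -abs((ge - gs) - a.length), -a.start)
                    if best_key is None or key > best_key:
                        best, best_key = a, key
                if (gs, ge) == (best.start, best.end):
                    cls = CORRECT
                elif gs >= best.start and ge <= best.end:
                    cls = ALT_INTERNAL
                elif gs <= best.start and ge >= best.end:
                    cls = ALT_EXTERNAL
                else:
                    cls = ALT_OVERLAPPING
                events.add((read.contig, gs, ge, cls, best.ies_id, read.read_id))
    return events


def _flatten(events):
    out = set()
    for ev in events:
        for rid in ev.supporting_read_ids:
            out.add(
                (ev.contig, ev.gap_start, ev.gap_end, ev.classification,
                 ev.matched_ies_id, rid)
            )
    return out


def test_classifier_matches_bruteforce_oracle_on_random_genomes():
    """On small random genomes with alternative and cryptic excision, the
    classifier and an exhaustive TA-pair/interval oracle produce identical
    event sets."""
    for seed in range(300, 306):
        cfg = SimConfig(seed=seed, n_contigs=1, contig_length=4_000, n_ies=8,
                        coverage=25.0)
        mac_plus, _, annotations = generate_genome(cfg)
        truth = TruthTable.constant(annotations, retention=0.4, alt=0.3,
                                    cryptic_rate=1.0)
        sim_reads, _ = simulate_dna_reads(mac_plus, annotations, truth, cfg)
        reads = to_aligned_reads(sim_reads)
        events, _, _, _ = call_events(reads, annotations, mac_plus)
        assert _flatten(events) == _oracle_events(reads, annotations, mac_plus)


def test_all_simulated_excisions_recovered_without_errors(mixed_dataset,
                                                          small_genome):
    """With error_rate=0 every simulated excision gap with adequate anchors
    is recovered with its true class."""
    mac_plus, _, annotations = small_genome
    reads, read_truth, _ = mixed_dataset
    events, per_ies, cryptic, rej = call_events(reads, annotations, mac_plus)
    found = _flatten(events)
    kind_map = {"correct": CORRECT, "cryptic": CRYPTIC}
    n_checked = 0
    read_by_id = {r.read_id: r for r in reads}
    for row in read_truth.itertuples():
        if not row.gaps:
            continue
        for g in str(row.gaps).split(","):
            if not g or g == "nan":
                continue
            span, kind = g.split(":")
            gs, ge = map(int, span.split("-"))
            read = read_by_id[row.read_id]
            gaps = extract_gaps(read)
            if not any((c.gap_start, c.gap_end) == (gs, ge) for c in gaps):
                continue  # anchors below threshold: legitimately not called
            n_checked += 1
            matches = [f for f in found if f[1] == gs and f[2] == ge
                       and f[5] == row.read_id]
            assert matches, (row.read_id, gs, ge)
            if kind in kind_map:
                assert matches[0][3] == kind_map[kind]
            else:  # alternative: any ALT_* class
                assert matches[0][3].startswith("ALT_")
    assert n_checked > 100
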