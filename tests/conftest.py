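import numpy as np
import pytest

from ieskit.genome import AssemblyFlavor, GenomeAssembly, IesAnnotation
from ieskit.simulate import SimConfig, TruthTable, generate_genome, simulate_dna_reads
from ieskit.simulate import to_aligned_reads


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=42, n_contigs=2, contig_length=12_000, n_ies=24,
                     coverage=60.0)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    """(MAC+IES assembly, MAC assembly, annotations) at toy scale."""
    return generate_genome(small_cfg)


@pytest.fixture(scope="session")
def mixed_dataset(small_cfg, small_genome):
    """Reads simulated with heterogeneous retention and some alternative
    and cryptic excision, plus the truth used."""
    mac_plus, _, annotations = small_genome
    rng = np.random.default_rng(7)
    truth = TruthTable(
        retention_prob={a.ies_id: float(r) for a, r in
                        zip(annotations, rng.uniform(0.1, 0.9, len(annotations)))},
        alt_prob={a.ies_id: 0.15 for a in annotations},
        density_multiplier={a.ies_id: 1.0 for a in annotations},
        cryptic_rate=0.3,
    )
    reads, read_truth = simulate_dna_reads(mac_plus, annotations, truth, small_cfg)
    return to_aligned_reads(reads), read_truth, truth


@pytest.fixture()
def toy_assembly():
    """Hand-built two-IES contig with known TA structure.

    Layout of contig "c" (0-based):
      positions 10-38  : IES ies_a (28 bp, starts TA, TA at 38)
      positions 60-105 : IES ies_b (45 bp, starts TA, TA at 105)
    """
    rng = np.random.default_rng(123)
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=160))

    def plant(p, s):
        for i, ch in enumerate(s):
            seq[p + i] = ch

    # scrub accidental TAs so the toy structure is exact
    for p in range(len(seq) - 1):
        if seq[p] == "T" and seq[p + 1] == "A":
            seq[p] = "C"
    plant(10, "TA")
    plant(38, "TA")
    plant(60, "TA")
    plant(105, "TA")
    genome = GenomeAssembly(
        contigs={"c": "".join(seq)}, flavor=AssemblyFlavor.MAC_PLUS_IES
    )
    annotations = [
        IesAnnotation(contig="c", start=10, end=38, ies_id="ies_a"),
        IesAnnotation(contig="c", start=60, end=105, ies_id="ies_b"),
    ]
    return genome, annotations
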