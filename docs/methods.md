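# Methods

This note documents the models, counting rules, numerical choices and
known limitations of `ieskit`. It describes what the code computes and
why the defaults are what they are; every empirical statement here is
one the test suite or `scripts/acceptance.py` computes.

## Coordinate and TA conventions

All intervals are 0-based half-open internally; GFF3 I/O converts to
and from 1-based inclusive at the boundary. An annotated IES interval
`[start, end)` begins with the dinucleotide `TA`, and the reference
carries a second `TA` at `[end, end+2)`. Excision removes
`[start, end)` exactly, so the downstream copy is the one retained at
the somatic junction and the gap length of a correctly excised read
equals the annotated IES length. Published *P. tetraurelia*
annotations do not state which flanking TA lies inside the feature;
this convention is internal and documented, and would need a one-line
adapter if an external annotation used the opposite choice. `N` bases
never match `TA` (conservative boundary calling). Everything is
recorded on the forward strand: excision is a double-stranded event,
so strand carries no information for these statistics.

## Event calling

Candidate excisions are CIGAR `D` or `N` operations — real spliced
mappers emit `N` for large gaps — of length ≥ `min_gap` (default 20)
flanked by ≥ `min_anchor` (default 10) aligned bases on each side of
the read. The shortest real IES length peak is 26–31 bp, so 20 bp
excludes small indel noise while keeping every genuine class. A gap is
accepted only if the excised segment is TA-bounded in the same two-TA
sense as a canonical IES; failures are counted and reported
(`no-TA-left` / `no-TA-right`), not raised.

Classification is interval arithmetic against the sorted annotation:
exact match → `CORRECT`; contained → `ALT_INTERNAL`; containing →
`ALT_EXTERNAL`; one-sided overlap → `ALT_OVERLAPPING`; no overlap →
`CRYPTIC`. If a gap overlaps several IESs, the IES with maximal
reciprocal overlap wins, ties broken by smaller absolute length
difference, then leftmost — deterministic and purely overlap-driven. A
read with two qualifying gaps contributes two independent events
(adjacent IESs can co-occur on one fragment). Correctness of the whole
path is checked against an exhaustive oracle that rescans every read
and every TA pair with shared no code.

## Retention scoring

A read supports retention at a boundary if one aligned (gap-free)
block covers `min_flank` (default 5) bases on both sides of it; 5 is
small enough to score 26-bp IESs with ordinary short reads. It
supports excision if it carries a `CORRECT` event for that IES. The
score is `IRS = (a+b) / (a+b+2c)`.

One deliberate asymmetry-removal choice: within retention scoring the
junction anchor requirement for the `c` count defaults to `min_flank`,
not the event caller's `min_anchor`. With reads of length R, a
boundary-crossing read is captured from `R − 2·min_flank + 1` start
positions but a junction read from `R − 2·min_anchor + 1`; unequal
thresholds (5 vs 10) would give retained molecules a ~12% larger
capture window and bias IRS upward by ~0.03 at intermediate retention.
With matched thresholds the estimator is unbiased: at 100× simulated
coverage, 99.5% of IESs score within three binomial standard
deviations of their true retention probability (the sampling unit for
that standard error is the number of distinct informative reads,
reported as `n_reads`, because one retained read spanning a short IES
contributes both boundary counts). Event calling proper keeps
`min_anchor = 10`.

IESs with no informative reads get a missing score, excluded pairwise
from correlations and never imputed. Sub-terminal base frequencies are
computed at the three positions after the terminal TA from both ends,
the right end read on the reverse complement (the junction TA is its
own reverse complement).

## Nucleosome density

Mononucleosome fragments are properly-paired reads with outer distance
in [100, 175] — the source protocol states "between 100 and 175 bp"
without inclusivity, declared inclusive here. Per-IES counting uses a
fixed ≥ 9 aligned-bp overlap rather than a read-length-dependent
fraction; gap-spanning reads contribute only aligned bases, so a read
documenting the IES's excision never counts toward its coverage.
Downsampling is Bernoulli per read name (a salted hash, so both mates
share the decision and reruns reproduce exactly); it is statistically,
not bit-for-bit, equivalent to `samtools view -s`. The density is
`r = (n/N)/(d/D)`, missing when the IES has no DNA coverage; no
parental-MAC correction is applied. The two-sample KS statistic is the
exact maximal ECDF difference; its p-value uses the asymptotic
Kolmogorov distribution with effective size `|x||y|/(|x|+|y|)` (the
exact small-sample distribution is not needed at the stratum sizes
this analysis works at).

**Boundary dilution.** Because fragments are ~147 bp and most
*Paramecium* IESs are much shorter, many fragments counted for an IES
have midpoints in flanking MAC-destined DNA. For an IES of length L
and fragment size F, the expected count scales as `λ·L + (F − 17)`
rather than `λ·L`, which attenuates the measured density ratio of
short IESs toward 1. This is a property of any overlap-based counting
at these sizes, not of the implementation; it is why the
parameter-recovery test uses long IESs (2.5 kb) embedded in a large,
mostly MAC-destined genome (16 Mb), where attenuation is below the 15%
recovery tolerance. Stratified comparisons of real-scale short IESs
are unaffected in rank terms, since attenuation is shared within a
length stratum — one reason the analysis stratifies by length at all.

## The synthetic-data generator

The generator emulates the features of the real system the pipeline
depends on: ~72% AT base composition (which sets the background TA
density and hence the supply of alternative boundaries), TA-bounded
IESs with the species' periodic length mixture (peaks centred 28, 35,
45 and 55 bp with weights 0.55, 0.02, 0.25, 0.18 — the 35-bp
"forbidden" class nearly absent, as in wild-type excision), per-IES
retention probabilities ρ, alternative-boundary probabilities α,
density multipliers λ, and a genome-wide cryptic rate κ (events per
read per kb of MAC-destined sequence). IESs are separated by at least
one read length so no read can span two IESs, which keeps per-read
truth unambiguous.

Each read is drawn from an independent molecule: per overlapped IES
the molecule is retained with probability ρ, otherwise excised at the
canonical TA pair with probability 1 − α or at an alternative TA pair.
Alternative boundaries are drawn from TA sites within ±20 bp of the
canonical ones, geometrically weighted by distance rank so the nearest
available site dominates; each IES is constructed with guaranteed
alternative TA sites 2–6 bp inside and outside both boundaries,
modelling excision slipping to the next closest site. Keeping the
guaranteed sites this close makes alternative lengths concentrate near
the reference length, so the mass of the alternative-length histogram
in the forbidden window responds cleanly (and, over the tested weight
settings, monotonically) to the weight of the 35-bp length class.
Excised spans are emitted as CIGAR deletions with true coordinates, so
the pipeline is testable without an external aligner; FASTQ is emitted
alongside for real-mapper workflows. Nucleosomal fragments draw
midpoints at rate 1 per MAC-destined bp and λ per IES bp, with sizes
from a normal (mean 147, sd 15) truncated to [80, 250] so the
[100, 175] filter is exercised on both sides.

What the generator does **not** model: sequencing errors beyond
uniform substitutions (no indel errors, no quality profiles), PCR
duplicates, mappability/repeat structure, parental-MAC contamination,
GC/AT coverage bias, or any mechanistic coupling between ρ and λ (the
coupling is a free parameter precisely because the strength of that
relationship is the scientific question). Passing tests therefore
demonstrate correctness of the measurement machinery under known
truth, not robustness to every artefact of real libraries.

## Problem sizes and determinism

All randomness flows from one mandatory seed through named
per-stage streams; identical configuration and seed give byte-identical
FASTA/GFF3/SAM/FASTQ/TSV/JSON outputs, verified end to end through the
CLI. Test and acceptance runs use toy scales chosen so each check's
statistical tolerance (three binomial or Poisson standard deviations,
or a stated recovery percentage) is comfortably resolvable: tens of
IESs at 40–100× for counting semantics, 200 IESs at 100× for retention
recovery, ~15,000 excision reads for the alternative-rate check, and
300 long IESs with ~50 fragments each for density recovery.

## Known limitations

- The exact counting variants of the reference implementations the
  field uses for retention scoring and event annotation are not
  published in detail; the rules here are declared precisely instead,
  and the defaults are exposed (`min_gap`, `min_anchor`, `min_flank`,
  `min_mapq`, `overlap_bp`, outer-distance bounds, IRS threshold,
  forbidden window).
- Real alternative excision may prefer boundaries matching the weak
  end-consensus sequence; the generator models distance only.
- Density r is a relative, library-normalized quantity; comparing its
  absolute level across experiments requires the same size-selection
  and downsampling conventions on both.
- No base-pair-resolution nucleosome positioning or dyad calling is
  attempted: with ≤ 9 bp overlap rules and IESs shorter than a
  nucleosome footprint, positioning would not be statistically
  meaningful.
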