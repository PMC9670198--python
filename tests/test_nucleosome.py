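"""Mononucleosome filtering, 9-bp overlap counting, downsampling,
density normalization, stratification, and the KS machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp, truncnorm

from ieskit.excision import AlignedRead
from ieskit.genome import IesAnnotation
from ieskit.nucleosome import (
    Fragment,
    count_ies_reads,
    downsample_reads,
    filter_nucleosomal_pairs,
    fragment_length_histogram,
    ks_two_sample,
    normalized_density,
    stratified_density_distributions,
)
from ieskit.simulate import (
    SimConfig,
    TruthTable,
    simulate_nucleosomal_fragments,
)


def _pair(rid, tlen, pos=0, proper=True):
    return AlignedRead(rid, "c", pos, ((0, 50),), is_proper_pair=proper,
                       template_length=tlen)


class TestMononucleosomeFilter:
    @pytest.mark.parametrize(
        "tlen,kept", [(99, False), (100, True), (147, True), (175, True), (176, False)]
    )
    def test_inclusive_bounds(self, tlen, kept):
        frags = filter_nucleosomal_pairs([_pair("r", tlen)])
        assert bool(frags) == kept

    def test_one_fragment_per_pair(self):
        reads = [_pair("r", 147, pos=10), _pair("r", -147, pos=107)]
        frags = filter_nucleosomal_pairs(reads)
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end) == (10, 157)

    def test_single_end_input_rejected(self):
        se = AlignedRead("r", "c", 0, ((0, 50),), is_proper_pair=False,
                         template_length=0)
        with pytest.raises(ValueError, match="paired-end"):
            filter_nucleosomal_pairs([se])

    def test_kept_fraction_matches_truncnorm_mass(self, small_cfg, small_genome):
        """The [100,175] filter keeps the truncated-normal CDF mass of that
        window, within 3 binomial SDs."""
        mac_plus, _, annotations = small_genome
        truth = TruthTable.constant(annotations)
        frags, _ = simulate_nucleosomal_fragments(
            mac_plus, annotations, truth, small_cfg, n_fragments=20_000
        )
        reads = [_pair(f.frag_id, f.size) for f in frags]
        kept = len(filter_nucleosomal_pairs(reads))
        a = (small_cfg.frag_size_min - small_cfg.frag_size_mean) / small_cfg.frag_size_sd
        b = (small_cfg.frag_size_max - small_cfg.frag_size_mean) / small_cfg.frag_size_sd
        # sizes are rounded to integers: use half-open continuity correction
        p = truncnorm.cdf(175.5, a, b, small_cfg.frag_size_mean,
                          small_cfg.frag_size_sd) - truncnorm.cdf(
            99.5, a, b, small_cfg.frag_size_mean, small_cfg.frag_size_sd)
        n = len(frags)
        assert abs(kept - n * p) <= 3 * math.sqrt(n * p * (1 - p))


class TestOverlapCounting:
    ANNS = [IesAnnotation("c", 100, 160, ies_id="i1")]

    @pytest.mark.parametrize("overlap,counted", [(8, False), (9, True)])
    def test_nine_bp_rule(self, overlap, counted):
        read = AlignedRead("r", "c", 100 + 60 - overlap, ((0, 50),))
        tab = count_ies_reads([read], self.ANNS)
        assert tab.loc[0, "count"] == int(counted)

    def test_gap_spanning_read_contributes_aligned_bases_only(self):
        # deletion covers the whole IES: zero aligned bases inside
        read = AlignedRead("r", "c", 80, ((0, 20), (2, 60), (0, 30)))
        tab = count_ies_reads([read], self.ANNS)
        assert tab.loc[0, "count"] == 0

    def test_fragment_interval_counts(self):
        frag = Fragment("f", "c", 95, 115)  # 15 bp inside
        tab = count_ies_reads([frag], self.ANNS)
        assert tab.loc[0, "count"] == 1


class TestDownsampling:
    def _reads(self, n):
        return [_pair(f"r{i}", 147) for i in range(n)]

    def test_identity_and_range_check(self):
        reads = self._reads(10)
        assert downsample_reads(reads, 1.0, seed=1) == reads
        with pytest.raises(ValueError):
            downsample_reads(reads, 0.0, seed=1)
        with pytest.raises(ValueError):
            downsample_reads(reads, 1.5, seed=1)

    def test_binomial_and_deterministic(self):
        reads = self._reads(20_000)
        kept = downsample_reads(reads, 0.5, seed=7)
        assert abs(len(kept) - 10_000) <= 3 * math.sqrt(20_000 * 0.25)
        again = downsample_reads(reads, 0.5, seed=7)
        assert [r.read_id for r in kept] == [r.read_id for r in again]

    def test_pair_coherent(self):
        mates1 = [_pair(f"r{i}", 147) for i in range(2_000)]
        mates2 = [_pair(f"r{i}", -147) for i in range(2_000)]
        k1 = {r.read_id for r in downsample_reads(mates1, 0.3, seed=3)}
        k2 = {r.read_id for r in downsample_reads(mates2, 0.3, seed=3)}
        assert k1 == k2


class TestNormalizedDensity:
    def test_direct_values(self):
        assert normalized_density(50, 1000, 25, 1000) == pytest.approx(2.0)
        assert normalized_density(10, 100, 10, 100) == pytest.approx(1.0)
        assert math.isnan(normalized_density(5, 100, 0, 100))
        with pytest.raises(ValueError):
            normalized_density(5, 0, 5, 100)

    def test_scale_invariance(self):
        r = normalized_density(50, 1000, 25, 2000)
        for k in (2, 10, 137):
            assert normalized_density(50 * k, 1000 * k, 25 * k, 2000 * k) == (
                pytest.approx(r)
            )


class TestStratification:
    def test_partition_and_bruteforce_agreement(self):
        anns = [
            IesAnnotation("c", i * 300, i * 300 + ln, ies_id=f"i{i}")
            for i, ln in enumerate([28, 30, 170, 45, 28], start=1)
        ]
        records = pd.DataFrame(
            {"ies_id": [a.ies_id for a in anns], "r": [1.0, 2.0, 3.0, np.nan, 0.5]}
        )
        irs = {"i1": 0.1, "i2": 0.5, "i3": 0.9, "i4": 0.0, "i5": np.nan}
        strata = stratified_density_distributions(records, irs, anns)
        # i4 (missing r) and i5 (missing IRS) drop out everywhere
        assert sorted(strata["weak_all"]) == [1.0]
        assert sorted(strata["strong_all"]) == [2.0, 3.0]
        assert list(strata["weak_peak1_26_31"]) == [1.0]
        assert list(strata["strong_peak1_26_31"]) == [2.0]
        assert list(strata["strong_long_150_200"]) == [3.0]
        assert len(strata["weak_long_150_200"]) == 0


class TestKsTwoSample:
    def test_identical_and_disjoint(self):
        x = [1.0, 2.0, 3.0]
        d, p = ks_two_sample(x, list(x))
        assert d == 0.0 and p == pytest.approx(1.0)
        d2, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d2 == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def _brute_force_d(self, x, y):
        xs, ys = np.asarray(x, float), np.asarray(y, float)
        best = 0.0
        for t in np.concatenate([xs, ys]):
            fx = (xs <= t).mean()
            fy = (ys <= t).mean()
            best = max(best, abs(fx - fy))
        return best

    def test_matches_bruteforce_ecdf_oracle(self):
        rng = np.random.default_rng(12)
        for n, m in [(3, 3), (10, 7), (50, 31), (50, 50)]:
            x = rng.normal(0, 1, n)
            y = rng.normal(0.4, 1.3, m)
            d, _ = ks_two_sample(x, y)
            assert d == pytest.approx(self._brute_force_d(x, y), abs=1e-12)

    def test_d_statistic_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.exponential(1, 80)
        y = rng.exponential(1.5, 60)
        d, p = ks_two_sample(x, y)
        ref = ks_2samp(x, y, method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)
        # asymptotic p-values: same order of magnitude, not identical formulae
        assert p == pytest.approx(ref.pvalue, rel=0.5) or (p < 1e-6 and
                                                           ref.pvalue < 1e-6)


class TestFragmentLengthHistogram:
    def test_spike_and_total(self):
        reads = [_pair(f"r{i}", 147) for i in range(10)]
        reads += [_pair("x", 600)]  # beyond max_len: excluded
        hist = fragment_length_histogram(reads, max_len=500)
        assert hist.loc[hist.outer_distance == 147, "count"].iloc[0] == 10
        assert hist["count"].sum() == 10
        dens = fragment_length_histogram(reads, max_len=500, density=True)
        assert dens["count"].sum() == pytest.approx(1.0)
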