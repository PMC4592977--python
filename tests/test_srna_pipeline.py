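"""Trimming, exact alignment, classification and profiling rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from masirna import (
    AnnotationIndex,
    ExactIndex,
    Genome,
    GenomicInterval,
    ProcessedRead,
    ReadHitSet,
    align_reads,
    classify_hitset,
    classify_library,
    length_filter,
    make_random_genome,
    profile_library,
    region_density,
    revcomp,
    trim_adapter,
)
from masirna.exceptions import ParameterError
from masirna.io_formats import AnnotatedFeature

ADAPTER = "AGATCGGAAGAG"


def naive_find_all(genome: Genome, query: str):
    """Definitional oracle: scan both strands of every chromosome."""
    hits = []
    if "N" in query:
        return hits
    for chrom, seq in genome.sequences.items():
        for oriented, strand in ((query, "+"), (revcomp(query), "-")):
            pos = seq.find(oriented)
            while pos != -1:
                hits.append(GenomicInterval(chrom, pos, pos + len(query), strand))
                pos = seq.find(oriented, pos + 1)
    return hits


class TestTrimAdapter:
    def test_adapter_prefix_suffix_removed(self):
        assert trim_adapter("ACGTACGTAGATCGG", ADAPTER, 6) == "ACGTACGT"

    def test_overlap_threshold(self):
        assert trim_adapter("ACGTACGTAGATCG", ADAPTER, 6) == "ACGTACGT"
        # 5-base suffix match is below min_overlap: read unchanged
        assert trim_adapter("ACGTACGTAGATC", ADAPTER, 6) == "ACGTACGTAGATC"

    def test_full_internal_adapter_cut(self):
        read = "ACGT" + ADAPTER + "TTTT"
        assert trim_adapter(read, ADAPTER, 6) == "ACGT"

    def test_read_equal_to_adapter_empties(self):
        assert trim_adapter(ADAPTER, ADAPTER, 6) == ""

    @given(st.text(alphabet="ACGT", min_size=5, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_trimmed_is_prefix_of_read(self, read):
        out = trim_adapter(read, ADAPTER, 6)
        assert read.startswith(out)


class TestLengthFilter:
    def test_bounds_inclusive(self):
        reads = [("a", "A" * 16), ("b", "A" * 18), ("c", "A" * 25),
                 ("d", "A" * 29), ("e", "A" * 30)]
        kept, stats = length_filter(reads, 18, 29)
        assert [r.id for r in kept] == ["b", "c", "d"]
        assert stats == {"input": 5, "kept": 3, "discarded_short": 1,
                         "discarded_long": 1}

    def test_empty_input(self):
        kept, stats = length_filter([], 18, 29)
        assert kept == [] and stats["input"] == 0

    def test_invalid_bounds(self):
        with pytest.raises(ParameterError):
            length_filter([], 20, 10)


class TestExactIndex:
    def test_forward_hits(self):
        g = Genome({"c": "ACGTACGT"})
        idx = ExactIndex(g, k=4)
        hits = idx.find_all("ACGT")
        fwd = sorted((h.start, h.strand) for h in hits if h.strand == "+")
        assert fwd == [(0, "+"), (4, "+")]

    def test_absent_query(self):
        g = Genome({"c": "ACGTACGT"})
        assert ExactIndex(g, k=4).find_all("AAAA") == []

    def test_palindrome_reported_on_both_strands(self):
        g = Genome({"c": "TTTGAATTCTTT"})
        hits = ExactIndex(g, k=4).find_all("GAATTC")
        assert sorted(h.strand for h in hits) == ["+", "-"]
        assert {(h.start, h.end) for h in hits} == {(3, 9)}

    def test_n_reads_never_align(self):
        g = Genome({"c": "ACGTNACGTACGTAAA"})
        assert ExactIndex(g, k=4).find_all("ACGTNACG") == []

    def test_query_shorter_than_k_rejected(self):
        g = Genome({"c": "ACGTACGT"})
        with pytest.raises(ParameterError):
            ExactIndex(g, k=6).find_all("ACGT")

    def test_matches_naive_scan_on_random_genome(self, rng):
        g = make_random_genome(21, {"c1": 4000, "c2": 1500}, 0.5)
        idx = ExactIndex(g, k=8)
        for _ in range(60):
            chrom = "c1" if rng.random() < 0.7 else "c2"
            s = int(rng.integers(0, len(g[chrom]) - 25))
            query = g[chrom][s:s + 20 + int(rng.integers(0, 5))]
            if rng.random() < 0.5:
                query = revcomp(query)
            assert sorted(map(str, idx.find_all(query))) == \
                sorted(map(str, naive_find_all(g, query)))


class TestAlignReads:
    def test_unique_two_copy_and_reverse_reads(self):
        core = "TTACGGATCACGGTTAAC"
        g = Genome({"c": "A" * 30 + core + "C" * 30 + core + "G" * 30 +
                         "ACCGTTAGCATGCAATCG" + "T" * 30})
        idx = ExactIndex(g, k=10)
        unique = ProcessedRead("u", "ACCGTTAGCATGCAATCG")
        double = ProcessedRead("d", core)
        rev = ProcessedRead("r", revcomp("ACCGTTAGCATGCAATCG"))
        none = ProcessedRead("n", "T" * 10 + "ACGTACGTAC")
        hitsets, unaligned = align_reads([unique, double, rev, none], idx)
        by_id = {hs.read.id: hs for hs in hitsets}
        assert len(by_id["u"].hits) == 1 and by_id["u"].weight == 1.0
        assert len(by_id["d"].hits) == 2 and by_id["d"].weight == 0.5
        assert [h.strand for h in by_id["r"].hits] == ["-"]
        assert [r.id for r in unaligned] == ["n"]


def _mk_hitset(read_id, seq, *hits):
    return ReadHitSet(ProcessedRead(read_id, seq),
                      [GenomicInterval(c, s, e, strand) for c, s, e, strand in hits])


class TestClassify:
    @pytest.fixture()
    def ann(self):
        return AnnotationIndex([
            AnnotatedFeature(GenomicInterval("c1", 100, 300, "+"), "rRNA", "r"),
            AnnotatedFeature(GenomicInterval("c1", 1000, 1100, "+"), "tRNA", "t"),
        ])

    def test_precedence_over_all_hits(self, ann):
        hs = _mk_hitset("x", "A" * 20, ("c1", 120, 140, "+"), ("c1", 5000, 5020, "+"))
        assert classify_hitset(hs, ann, mito_name=None) == "rRNA"

    def test_structural_beats_unpaired_region(self, ann):
        region = GenomicInterval("c1", 0, 2000)
        hs = _mk_hitset("x", "A" * 20, ("c1", 1010, 1030, "+"))
        assert classify_hitset(hs, ann, None, [region]) == "tRNA"

    def test_mito_and_other(self, ann):
        mito = _mk_hitset("m", "A" * 20, ("chrM", 10, 30, "+"))
        other = _mk_hitset("o", "A" * 20, ("c1", 5000, 5020, "+"))
        assert classify_hitset(mito, ann, "chrM") == "mito"
        assert classify_hitset(other, ann, "chrM") == "other"

    def test_half_overlap_rule(self, ann):
        # 20-nt read overlapping the rRNA feature by 5 bases: below 50%
        below = _mk_hitset("b", "A" * 20, ("c1", 85, 105, "+"))
        at = _mk_hitset("a", "A" * 20, ("c1", 90, 110, "+"))
        assert classify_hitset(below, ann, None) == "other"
        assert classify_hitset(at, ann, None) == "rRNA"

    def test_masirna_from_unpaired_region(self, ann):
        region = GenomicInterval("c1", 4000, 6000)
        hs = _mk_hitset("x", "A" * 20, ("c1", 5000, 5020, "+"))
        assert classify_hitset(hs, ann, None, [region]) == "masiRNA"


class TestProfileAndDensity:
    def test_uniform_library_profile(self):
        hitsets = [_mk_hitset(f"r{i}", "T" + "A" * 24, ("c", 10 * i, 10 * i + 25, "+"))
                   for i in range(50)]
        labels = ["other"] * 50
        prof = profile_library(hitsets, labels)
        assert prof.length_hist["other"] == {25: 50}
        assert prof.five_prime["other"] == {"T": 50}
        assert abs(sum(prof.fractions.values()) - 1.0) < 1e-12

    def test_density_arithmetic(self):
        region = GenomicInterval("c", 0, 1000)
        hitsets = [_mk_hitset(f"r{i}", "A" * 20, ("c", 100, 120, "+"))
                   for i in range(100)]
        d, rpkm = region_density(hitsets, region, library_size=1_000_000)
        assert d == pytest.approx(0.1)
        assert rpkm == pytest.approx(100.0)  # 100 reads / 1 kb / 1 M reads

    def test_multihit_weight_conservation(self):
        region = GenomicInterval("c", 0, 1000)
        hs = _mk_hitset("r", "A" * 20, ("c", 100, 120, "+"), ("c", 500, 520, "-"))
        d, _ = region_density([hs], region, 1000)
        assert d == pytest.approx(1.0 / 1000)

    def test_midpoint_matches_any_overlap_for_contained_reads(self, rng):
        region = GenomicInterval("c", 2000, 3000)
        hitsets = []
        for i in range(300):
            s = int(rng.integers(1985, 2995))  # some reads cross the edges
            hitsets.append(_mk_hitset(f"r{i}", "A" * 20, ("c", s, s + 20, "+")))
        d, _ = region_density(hitsets, region, 1000)
        midpoint_in = sum(1 for hs in hitsets
                          if 2000 <= hs.hits[0].midpoint < 3000)
        for hs in hitsets:  # any fully-contained read is counted by both rules
            h = hs.hits[0]
            if h.start >= 2000 and h.end <= 3000:
                assert 2000 <= h.midpoint < 3000
        assert d == pytest.approx(midpoint_in / 1000)

    def test_zero_length_region_rejected(self):
        with pytest.raises(ParameterError):
            GenomicInterval("c", 5, 5)


class TestConservation:
    def test_class_counts_conserve_reads(self, small_result):
        for tp, lib in small_result.libraries.items():
            total = lib.filter_stats["kept"]
            classified = sum(lib.profile.counts.values())
            assert classified + len(lib.unaligned) == total
            assert classified == len(lib.hitsets)

    def test_masirna_fraction_peaks_late(self, small_result):
        frac = {tp: lib.profile.fractions["masiRNA"]
                for tp, lib in small_result.libraries.items()}
        assert frac["4dPF"] > frac["PP"]
        assert frac["4dPF"] > frac["2dPF"]

    def test_recovered_five_prime_u_fraction(self, small_bundle, small_result):
        prof = small_result.libraries["4dPF"].profile
        fp = prof.five_prime["masiRNA"]
        n = sum(fp.values())
        f = small_bundle.config.srna.fraction_5pU_masirna
        assert abs(fp.get("T", 0) / n - f) <= 3 * np.sqrt(f * (1 - f) / n) + 0.01
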