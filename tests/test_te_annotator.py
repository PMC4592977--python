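"""TIR search, breakpoints, TSD calling, RIP indices and copy number."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from masirna import (
    ExactIndex,
    Genome,
    GenomicInterval,
    ProcessedRead,
    align_reads,
    apply_rip,
    call_tsd,
    copy_number,
    coverage_track,
    cri_track,
    cri_window,
    find_breakpoints,
    find_homologs,
    find_tirs,
    make_random_genome,
    plant_element,
    revcomp,
    ripcal_classify,
    simulate_wgs_reads,
)
from masirna.exceptions import FormatError, ParameterError
from masirna.synthetic_cross import ElementSpec, FUNGAL_DINUCLEOTIDE_ODDS, _random_sequence

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_tirs(seq, min_len, max_mismatch):
    """Definitional search over every (i, j, L) triple."""
    n = len(seq)
    best = None
    for i in range(n - 2 * min_len + 1):
        for j in range(i + min_len, n - min_len + 1):
            for L in range(min_len, min(j - i, n - j) + 1):
                mm = sum(seq[i + t] != _COMP[seq[j + L - 1 - t]] or seq[i + t] == "N"
                         for t in range(L))
                if mm <= max_mismatch:
                    key = (-L, mm, i, j)
                    if best is None or key < best:
                        best = key
    return best


def brute_force_tirs_exact(seq, min_len):
    """Substring-dictionary oracle for the zero-mismatch case on larger windows.

    A length-L inverted repeat implies one of length L-1, so the maximal
    length is found by bisection; the best pair at that length is then
    enumerated directly.
    """
    n = len(seq)

    def best_at(L):
        subs = {}
        for i in range(n - L + 1):
            subs.setdefault(seq[i:i + L], []).append(i)
        best = None
        for i in range(n - L + 1):
            for j in subs.get(revcomp(seq[i:i + L]), ()):
                if j >= i + L:
                    key = (-L, 0, i, j)
                    if best is None or key < best:
                        best = key
                    break  # positions ascending: first valid j is smallest
        return best

    lo, hi = min_len, n // 2  # invariant: solution at lo-1 known/irrelevant
    if best_at(lo) is None:
        return None
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if best_at(mid) is not None:
            lo = mid
        else:
            hi = mid - 1
    return best_at(lo)


def naive_cri(seq):
    counts = {d: 0 for d in ("TA", "AT", "CA", "TG", "AC", "GT")}
    for i in range(len(seq) - 1):
        d = seq[i:i + 2]
        if d in counts:
            counts[d] += 1
    if counts["AT"] == 0 or counts["AC"] + counts["GT"] == 0:
        return None
    return counts["TA"] / counts["AT"] - \
        (counts["CA"] + counts["TG"]) / (counts["AC"] + counts["GT"])


# ---------------------------------------------------------------------------
# TIRs
# ---------------------------------------------------------------------------


class TestFindTirs:
    def test_hand_checked_palindrome(self):
        pair = find_tirs("GAATTC", min_len=3)
        assert (pair.tir1_start, pair.tir2_start, pair.length) == (0, 3, 3)
        assert (pair.tir1_sequence, pair.tir2_sequence) == ("GAA", "TTC")

    def test_homopolymer_has_no_inverted_repeat(self):
        assert find_tirs("A" * 10, min_len=3) is None

    def test_window_too_short_rejected(self):
        with pytest.raises(ParameterError):
            find_tirs("ACGTA", min_len=3)

    def test_planted_perfect_tirs_recovered(self, rng):
        for trial in range(5):
            tir = _random_sequence(rng, 20, 0.5)
            insert = 300 + int(rng.integers(0, 200))
            left = _random_sequence(rng, insert, 0.5)
            body = _random_sequence(rng, 200, 0.5)
            right = _random_sequence(rng, 1000 - insert - 240, 0.5)
            window = left + tir + body + revcomp(tir) + right
            pair = find_tirs(window, min_len=12)
            # the planted pair is at least as good as anything coincidental
            assert pair.length >= 20
            if pair.length == 20:
                assert pair.tir1_start == insert
                assert pair.tir2_start == insert + 220

    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_matches_brute_force_on_random_windows(self, max_mismatch, rng):
        for trial in range(8):
            window = _random_sequence(rng, 60 + int(rng.integers(0, 25)), 0.5)
            pair = find_tirs(window, min_len=5, max_mismatch=max_mismatch)
            expected = brute_force_tirs(window, 5, max_mismatch)
            if expected is None:
                assert pair is None
            else:
                assert (-pair.length, pair.mismatches, pair.tir1_start,
                        pair.tir2_start) == expected

    def test_matches_brute_force_with_planted_pair(self, rng):
        for mm_planted in (0, 2):
            tir = _random_sequence(rng, 14, 0.5)
            tir2 = revcomp(tir)
            if mm_planted:
                idx = sorted(rng.choice(len(tir2), size=mm_planted, replace=False))
                tir2 = "".join("A" if t in idx and tir2[t] != "A" else
                               ("C" if t in idx else tir2[t]) for t in range(len(tir2)))
            window = (_random_sequence(rng, 20, 0.5) + tir +
                      _random_sequence(rng, 25, 0.5) + tir2 +
                      _random_sequence(rng, 20, 0.5))
            for budget in (0, 1, 2):
                pair = find_tirs(window, min_len=6, max_mismatch=budget)
                expected = brute_force_tirs(window, 6, budget)
                got = None if pair is None else (-pair.length, pair.mismatches,
                                                 pair.tir1_start, pair.tir2_start)
                assert got == expected

    def test_matches_exact_oracle_on_two_kb_window(self, rng):
        tir = _random_sequence(rng, 25, 0.5)
        window = (_random_sequence(rng, 700, 0.5) + tir +
                  _random_sequence(rng, 500, 0.5) + revcomp(tir) +
                  _random_sequence(rng, 750, 0.5))
        pair = find_tirs(window, min_len=10, max_mismatch=0)
        expected = brute_force_tirs_exact(window, 10)
        assert (-pair.length, pair.mismatches, pair.tir1_start, pair.tir2_start) == expected


# ---------------------------------------------------------------------------
# breakpoints and TSD
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def planted_locus():
    base = make_random_genome(41, {"c1": 40_000}, 0.5)
    spec = ElementSpec(body_length=900, tir_length=25, tsd_length=4,
                       insertion_site=("c1", 20_000))
    occupied, empty, truth = plant_element(base, spec, seed=41)
    reads = simulate_wgs_reads(empty, 25, 100, seed=41)
    index = ExactIndex(occupied, 12)
    hitsets, unaligned = align_reads([ProcessedRead(r[0], r[1]) for r in reads], index)
    track = coverage_track(hitsets, occupied, 100)
    return occupied, empty, truth, track, unaligned, index


class TestFindBreakpoints:
    def test_recovers_planted_boundaries_to_the_base(self, planted_locus):
        occupied, _empty, truth, track, unaligned, index = planted_locus
        locus = GenomicInterval("c1", truth.element_interval.start - 1500,
                                truth.element_interval.end + 1500)
        left, right = find_breakpoints(occupied, track, unaligned, locus, index=index)
        assert abs(left - truth.element_interval.start) <= 1
        assert abs(right - truth.element_interval.end) <= 1

    def test_no_gap_is_an_error(self, planted_locus):
        occupied, _empty, _truth, _track, _un, index = planted_locus
        reads = simulate_wgs_reads(occupied, 25, 100, seed=42)  # carrier's own reads
        hitsets, unaligned = align_reads(
            [ProcessedRead(r[0], r[1]) for r in reads], index)
        track = coverage_track(hitsets, occupied, 100)
        locus = GenomicInterval("c1", 18_000, 23_000)
        with pytest.raises(ParameterError):
            find_breakpoints(occupied, track, unaligned, locus, index=index)

    def test_stable_under_depth_doubling(self, planted_locus):
        occupied, empty, truth, track, unaligned, index = planted_locus
        locus = GenomicInterval("c1", truth.element_interval.start - 1500,
                                truth.element_interval.end + 1500)
        base_call = find_breakpoints(occupied, track, unaligned, locus, index=index)
        reads = simulate_wgs_reads(empty, 50, 100, seed=43)
        hitsets2, unaligned2 = align_reads(
            [ProcessedRead(r[0], r[1]) for r in reads], index)
        track2 = coverage_track(hitsets2, occupied, 100)
        deep_call = find_breakpoints(occupied, track2, unaligned2, locus, index=index)
        assert deep_call == base_call


class TestCallTsd:
    @pytest.mark.parametrize("tsd_len", [0, 1, 3, 7, 10])
    def test_planted_tsd_recovered_exactly(self, tsd_len):
        base = make_random_genome(50 + tsd_len, {"c1": 20_000}, 0.5)
        spec = ElementSpec(body_length=400, tir_length=20, tsd_length=tsd_len,
                           insertion_site=("c1", 10_000))
        occupied, empty, truth = plant_element(base, spec, seed=50 + tsd_len)
        call = call_tsd(occupied, empty["c1"], truth.element_interval)
        assert call.length == tsd_len
        assert call.left_tsd == truth.tsd_sequence
        assert call.rip_consistent_mismatches == ()

    def test_rip_mutated_right_copy(self):
        # keep planting until the target site contains a C (RIP-mutable)
        for seed in range(60, 80):
            base = make_random_genome(seed, {"c1": 20_000}, 0.5)
            spec = ElementSpec(body_length=400, tir_length=20, tsd_length=3,
                               insertion_site=("c1", 10_000), rip_tsd=True)
            occupied, empty, truth = plant_element(base, spec, seed=seed)
            if "C" in truth.tsd_sequence:
                break
        call = call_tsd(occupied, empty["c1"], truth.element_interval)
        assert call.length == 3
        assert call.left_tsd == truth.tsd_sequence
        assert call.right_tsd != call.left_tsd
        pos = call.rip_consistent_mismatches
        assert len(pos) == 1
        i = pos[0] - 1
        assert (call.left_tsd[i], call.right_tsd[i]) == ("C", "T")

    def test_reconstructed_partner_when_empty_missing(self, planted_locus):
        occupied, _empty, truth, _track, _un, _index = planted_locus
        call = call_tsd(occupied, None, truth.element_interval)
        assert call.length == len(truth.tsd_sequence)
        assert call.left_tsd == truth.tsd_sequence

    def test_inconsistent_junction_flagged(self):
        g = Genome({"c1": _random_sequence(np.random.default_rng(3), 2_000, 0.5)})
        call = call_tsd(g, "A" * 500, GenomicInterval("c1", 900, 1100))
        assert not call.consistent
        assert call.length == 0


# ---------------------------------------------------------------------------
# RIP index and RIPCAL-style counts
# ---------------------------------------------------------------------------


class TestCriWindow:
    def test_hand_enumeration(self):
        res = cri_window("ATTACATGAC")
        assert res.product_index == pytest.approx(0.5)   # TpA=1 / ApT=2
        assert res.substrate_index == pytest.approx(1.0)  # (1+1)/(2+0)
        assert res.cri == pytest.approx(-0.5)

    def test_degenerate_window_flagged(self):
        res = cri_window("ATATAT")
        assert not res.defined
        assert np.isnan(res.cri)

    def test_matches_naive_counter(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 60))
            seq = "".join(rng.choice(list("ACGT"), n))
            res = cri_window(seq)
            expected = naive_cri(seq)
            if expected is None:
                assert not res.defined
            else:
                assert res.cri == pytest.approx(expected)

    def test_rip_increases_cri(self, rng):
        seq = _random_sequence(rng, 10_000, 0.5)
        mutated, _ = apply_rip(seq, 0.5, 1)
        assert cri_window(mutated).cri > cri_window(seq).cri

    def test_rip_monotone_in_fraction(self):
        """Sign test over seeds: heavier RIP gives a larger CRI shift."""
        wins = 0
        for seed in range(10):
            seq = make_random_genome(seed + 100, {"c": 5_000}, 0.5)["c"]
            lo, _ = apply_rip(seq, 0.2, seed)
            hi, _ = apply_rip(seq, 0.6, seed)
            if cri_window(hi).cri > cri_window(lo).cri:
                wins += 1
        assert wins >= 9


class TestCriTrack:
    def test_single_window_consistency(self):
        g = make_random_genome(7, {"c": 2_000}, 0.5)
        track = cri_track(g, window=2_000, step=2_000)
        assert len(track.records) == 1
        assert track.records[0][5] == pytest.approx(cri_window(g["c"]).cri)

    def test_partial_window_rule(self):
        g = Genome({"c": "ACGT" * 300})  # 1200 bp
        track = cri_track(g, window=500, step=100)
        spans = [(rec[1], rec[2]) for rec in track.records]
        assert (700, 1200) in spans    # length 500
        assert (900, 1200) in spans    # length 300 >= window/2: retained
        assert (1000, 1200) not in spans  # length 200 < window/2: dropped

    def test_unmutated_biased_genome_mostly_negative(self):
        g = make_random_genome(8, {"c": 100_000}, 0.5,
                               dinucleotide_odds=FUNGAL_DINUCLEOTIDE_ODDS)
        vals = cri_track(g).values()
        assert (vals < 0).mean() > 0.95


class TestRipcal:
    def test_hand_counted_example(self):
        res = ripcal_classify(["CAACAA", "TAACAA"])
        assert res[0]["c2t_cpa"] == 1
        assert res[0]["c2t_other"] == 0
        assert res[0]["g2a_tpg"] == 0

    def test_identical_rows_all_zero(self):
        res = ripcal_classify(["ACGTACGT", "ACGTACGT"])
        assert all(res[0][k] == 0 for k in
                   ("c2t_cpa", "c2t_other", "g2a_tpg", "g2a_other", "other_differences"))

    def test_gap_columns_skipped_with_cross_gap_context(self):
        # reference C is followed (after a gap) by A: CpA context
        res = ripcal_classify(["C-A", "T-A"])
        assert res[0]["c2t_cpa"] == 1
        assert res[0]["compared_columns"] == 2

    def test_ragged_alignment_rejected(self):
        with pytest.raises(FormatError):
            ripcal_classify(["ACGT", "ACG"])

    def test_counts_match_applied_mutations(self, rng):
        seq = _random_sequence(rng, 3_000, 0.5, FUNGAL_DINUCLEOTIDE_ODDS)
        mutated, positions = apply_rip(seq, 0.4, 11)
        res = ripcal_classify([seq, mutated])[0]
        assert res["c2t_cpa"] + res["g2a_tpg"] == len(positions)
        assert res["c2t_other"] == 0 and res["g2a_other"] == 0
        assert res["other_differences"] == 0


class TestCopyNumberAndHomologs:
    def test_single_copy_ratio_near_one(self):
        g = make_random_genome(9, {"c": 50_000}, 0.5)
        reads = simulate_wgs_reads(g, 20, 100, seed=9)
        idx = ExactIndex(g, 12)
        hitsets, _ = align_reads([ProcessedRead(r[0], r[1]) for r in reads], idx)
        track = coverage_track(hitsets, g, 100)
        est = copy_number(track, GenomicInterval("c", 20_000, 23_000))
        assert est.ratio == pytest.approx(1.0, abs=0.2)
        assert est.estimate == 1

    def test_two_copies_double_depth(self, small_bundle, small_result):
        truth = small_bundle.truth
        est = copy_number(small_result.carrier_track, truth.element_interval)
        assert est.ratio == pytest.approx(truth.copy_number, rel=0.15)
        assert est.estimate == truth.copy_number

    def test_homologs_locate_riped_copies(self, small_bundle):
        truth = small_bundle.truth
        element_seq = small_bundle.occupied.fetch(truth.element_interval)
        hits = find_homologs(small_bundle.occupied, element_seq)
        starts = sorted(h.start for h in hits)
        expected = sorted([truth.element_interval.start] +
                          [iv.start for iv, _pos in truth.rip_copies])
        assert starts == expected
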