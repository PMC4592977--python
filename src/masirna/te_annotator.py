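"""Characterisation of a DNA transposon at a candidate unpaired locus.

Provides the individual measurements — terminal-inverted-repeat (TIR)
discovery by exhaustive self-alignment, insertion breakpoints from
split-read evidence in the partner's reads, target-site-duplication (TSD)
calling with RIP-aware mismatch tolerance, the composite RIP index (CRI) in
sliding windows, RIPCAL-style classification of mutations in homolog
copies, and a copy-number estimate from relative read depth — plus an
``annotate_element`` orchestrator that applies them to one locus.

The composite RIP index of a window is

    CRI = TpA/ApT - (CpA + TpG)/(ApC + GpT)

computed from overlapping dinucleotides on the given strand; positive
values indicate RIP-mutated DNA (RIP converts CpA to TpA on either strand,
inflating the product index and depleting the substrate index).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import FormatError, ParameterError
from .io_formats import Genome, GenomicInterval, revcomp, to_report_coords
from .srna_pipeline import ExactIndex, ProcessedRead, ReadHitSet
from .unpaired_detect import CoverageTrack

_COMP_TABLE = bytes.maketrans(b"ACGTN", b"TGCAN")


# ---------------------------------------------------------------------------
# TIR discovery
# ---------------------------------------------------------------------------


@dataclass
class TIRPair:
    """An inverted-repeat pair inside a searched window (window coordinates)."""

    tir1_start: int
    tir2_start: int
    length: int
    mismatches: int
    tir1_sequence: str
    tir2_sequence: str

    @property
    def tir1_end(self) -> int:
        return self.tir1_start + self.length

    @property
    def tir2_end(self) -> int:
        return self.tir2_start + self.length


def find_tirs(window_sequence: str, min_len: int = 10,
              max_mismatch: int = 0) -> Optional[TIRPair]:
    """Exhaustive search for the best inverted-repeat pair in a window.

    Considers every pair ``(i, j, L)`` with ``sequence[i:i+L]`` reverse-
    complementing ``sequence[j:j+L]`` at up to ``max_mismatch`` positions,
    ``L >= min_len`` and non-overlapping arms (``i+L <= j``).  The winner is
    the longest pair, ties broken by fewer mismatches, then leftmost ``i``,
    then smallest ``j``.  Positions pairing an N never match.

    The search enumerates anti-diagonals: a pair ``(i, j, L)`` occupies the
    anti-diagonal ``D = i + j + L - 1`` where position ``x`` of arm 1 pairs
    with ``D - x`` of arm 2, so each anti-diagonal reduces to finding the
    longest run with at most ``max_mismatch`` failures — which makes the
    enumeration exhaustive without cubic cost.
    """
    n = len(window_sequence)
    if min_len < 1:
        raise ParameterError("min_len must be >= 1")
    if n < 2 * min_len:
        raise ParameterError(f"window of {n} bp shorter than 2*min_len={2 * min_len}")
    raw = window_sequence.encode()
    S = np.frombuffer(raw, dtype=np.uint8)
    C = np.frombuffer(raw.translate(_COMP_TABLE), dtype=np.uint8)
    not_n = S != ord("N")

    best_key = None
    best = None
    for D in range(2 * min_len - 1, 2 * n - 2):
        x_lo = max(0, D - n + 1)
        x_hi = (D - 1) // 2
        if x_hi - x_lo + 1 < min_len:
            continue
        match = (S[x_lo:x_hi + 1] == C[D - x_hi:D - x_lo + 1][::-1])
        match &= not_n[x_lo:x_hi + 1]
        fails = np.flatnonzero(~match)
        m = len(match)
        nf = len(fails)
        # only windows at least as long as the best so far can win or tie
        threshold = min_len if best_key is None else max(min_len, -best_key[0])
        windows = []  # (left, right) inclusive, with <= max_mismatch fails
        if nf <= max_mismatch:
            if m >= threshold:
                windows.append((0, int(m) - 1, int(nf)))
        else:
            blockers = np.concatenate(([-1], fails, [m]))
            lengths = blockers[max_mismatch + 1:] - blockers[:-(max_mismatch + 1)] - 1
            for gi in np.flatnonzero(lengths >= threshold):
                gi = int(gi)
                left = int(blockers[gi]) + 1
                right = int(blockers[gi + max_mismatch + 1]) - 1
                n_mm = min(gi + max_mismatch, nf) - gi  # fails strictly inside
                windows.append((left, right, n_mm))
        for left, right, n_mm in windows:
            L = right - left + 1
            i = x_lo + left
            j = D - i - L + 1
            key = (-L, n_mm, i, j)
            if best_key is None or key < best_key:
                best_key = key
                best = (i, j, L, n_mm)
    if best is None:
        return None
    i, j, L, mm = best
    return TIRPair(
        tir1_start=i, tir2_start=j, length=L, mismatches=mm,
        tir1_sequence=window_sequence[i:i + L],
        tir2_sequence=window_sequence[j:j + L],
    )


# ---------------------------------------------------------------------------
# breakpoints and TSD
# ---------------------------------------------------------------------------


def _mode(counter: Counter) -> Optional[int]:
    if not counter:
        return None
    return min(counter, key=lambda p: (-counter[p], p))


def find_breakpoints(genome: Genome, track: CoverageTrack,
                     unaligned: Sequence[ProcessedRead], locus: GenomicInterval,
                     index: Optional[ExactIndex] = None, k: int = 12,
                     min_gap: int = 100, absence_fraction: float = 0.05,
                     merge_island: int = 250) -> Tuple[int, int]:
    """Insertion breakpoints of an element absent from the partner.

    The locus must contain exactly one coverage gap of at least ``min_gap``
    bp in the partner's depth track (otherwise the element is present in
    the partner and an error is raised).  The gap tolerates residual depth
    up to ``absence_fraction`` of the genome-wide median — spurious
    multi-mapped placements from diverged paralogs can drip weight into an
    absent element, and sub-``merge_island`` covered islands (bounded by the
    read length and the length of conserved paralog stretches) are absorbed
    into the surrounding gap.  The gap edges are then refined at base
    resolution with
    split-read evidence: partner reads that failed to align whole are
    anchored by their terminal k-mers and extended; the modal maximal-prefix
    end position gives the left breakpoint and the modal maximal-suffix
    start position the right breakpoint.  Returns ``(left, right)`` as a
    0-based half-open span.
    """
    depth = track.per_base[locus.chrom][locus.start:locus.end]
    zero = depth <= absence_fraction * track.median_depth
    raw_runs = []
    pos = 0
    while pos < len(zero):
        if zero[pos]:
            end = pos
            while end < len(zero) and zero[end]:
                end += 1
            raw_runs.append((locus.start + pos, locus.start + end))
            pos = end
        else:
            pos += 1
    merged = []
    for run in raw_runs:
        if merged and run[0] - merged[-1][1] < merge_island:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    runs = [r for r in merged if r[1] - r[0] >= min_gap]
    if not runs:
        raise ParameterError("element present in partner: no zero-coverage gap in locus")
    if len(runs) > 1:
        raise ParameterError(f"locus contains {len(runs)} zero-coverage gaps, expected 1")
    gap_start, gap_end = runs[0]

    if index is None:
        index = ExactIndex(genome, k)
    k = index.k
    seq = genome[locus.chrom]
    left_votes: Counter = Counter()
    right_votes: Counter = Counter()
    for read in unaligned:
        rlen = len(read.sequence)
        for oriented in (read.sequence, revcomp(read.sequence)):
            if "N" in oriented:
                continue
            # maximal prefix alignment ending near the gap's left edge
            for chrom, pos0 in index.lookup(oriented[:k]):
                if chrom != locus.chrom or pos0 >= gap_start:
                    continue
                ext = k
                while ext < rlen and pos0 + ext < len(seq) and oriented[ext] == seq[pos0 + ext]:
                    ext += 1
                end = pos0 + ext
                if ext < rlen and abs(end - gap_start) <= 2 * rlen:
                    left_votes[end] += 1
            # maximal suffix alignment starting near the gap's right edge
            for chrom, pos0 in index.lookup(oriented[-k:]):
                anchor_end = pos0 + k
                if chrom != locus.chrom or anchor_end <= gap_end:
                    continue
                ext = k
                while ext < rlen and anchor_end - ext - 1 >= 0 and \
                        oriented[rlen - ext - 1] == seq[anchor_end - ext - 1]:
                    ext += 1
                start = anchor_end - ext
                if ext < rlen and abs(start - gap_end) <= 2 * rlen:
                    right_votes[start] += 1
    left = _mode(left_votes)
    right = _mode(right_votes)
    return (left if left is not None else gap_start,
            right if right is not None else gap_end)


_RIP_PAIRS = {("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")}


@dataclass
class TSDCall:
    """A target-site duplication call at an element's flanks."""

    left_tsd: str
    right_tsd: str
    length: int
    rip_consistent_mismatches: Tuple[int, ...]  # 1-based positions within the TSD
    consistent: bool = True
    note: str = ""


def call_tsd(occupied_genome: Genome, empty_sequence: Optional[str],
             element_interval: GenomicInterval, max_tsd_len: int = 10,
             anchor: int = 20) -> TSDCall:
    """Call the TSD flanking an element by occupied/empty haplotype comparison.

    Finds the longest ``k <= max_tsd_len`` such that the k bases immediately
    left of the element equal the k bases immediately right of it, allowing
    only RIP-type one-sided substitutions (C->T or G->A in either copy), and
    such that the empty haplotype carries the corresponding junction
    sequence exactly once.  When ``empty_sequence`` is None the partner
    haplotype is reconstructed from the occupied reference by excising the
    element plus one TSD copy, and the junction test reduces to a
    uniqueness check.
    """
    if max_tsd_len < 0:
        raise ParameterError("max_tsd_len must be >= 0")
    seq = occupied_genome[element_interval.chrom]
    start, end = element_interval.start, element_interval.end
    if start < max_tsd_len + anchor or end + max_tsd_len + anchor > len(seq):
        raise ParameterError("element flanks shorter than max_tsd_len + anchor")

    for k in range(max_tsd_len, -1, -1):
        left = seq[start - k:start]
        right = seq[end:end + k]
        mismatches = []
        ok = True
        for t, (a, b) in enumerate(zip(left, right), start=1):
            if a != b:
                if (a, b) in _RIP_PAIRS:
                    mismatches.append(t)
                else:
                    ok = False
                    break
        if not ok:
            continue
        empty = empty_sequence
        if empty is None:
            empty = seq[:start] + seq[end + k:]
        junction_variants = (
            seq[start - k - anchor:start] + seq[end + k:end + k + anchor],   # left copy kept
            seq[start - k - anchor:start - k] + seq[end:end + k + anchor],   # right copy kept
        )
        if any(empty.count(j) == 1 for j in junction_variants):
            return TSDCall(left_tsd=left, right_tsd=right, length=k,
                           rip_consistent_mismatches=tuple(mismatches))
    return TSDCall(left_tsd="", right_tsd="", length=0,
                   rip_consistent_mismatches=(), consistent=False,
                   note="no junction-consistent TSD found in the partner haplotype")


# ---------------------------------------------------------------------------
# RIP index and RIPCAL-style classification
# ---------------------------------------------------------------------------


@dataclass
class CriResult:
    product_index: float   # TpA / ApT
    substrate_index: float  # (CpA + TpG) / (ApC + GpT)
    cri: float
    defined: bool


def cri_window(sequence: str) -> CriResult:
    """Composite RIP index of one window (single-strand dinucleotide counts).

    Counts overlapping dinucleotides on the given strand only; reverse-
    strand RIP events are captured by the TpG/GpT terms.  A zero denominator
    (ApT or ApC+GpT) makes the window undefined.
    """
    if len(sequence) < 2:
        raise ParameterError("sequence shorter than one dinucleotide")
    counts = Counter(sequence[i:i + 2] for i in range(len(sequence) - 1))
    tpa, apt = counts["TA"], counts["AT"]
    cpa, tpg = counts["CA"], counts["TG"]
    apc, gpt = counts["AC"], counts["GT"]
    if apt == 0 or apc + gpt == 0:
        return CriResult(float("nan"), float("nan"), float("nan"), defined=False)
    product = tpa / apt
    substrate = (cpa + tpg) / (apc + gpt)
    return CriResult(product, substrate, product - substrate, defined=True)


@dataclass
class RIPTrack:
    """Sliding-window CRI values over a genome."""

    window: int
    step: int
    records: List[tuple]  # (chrom, start, end, product, substrate, cri, defined)

    def values(self, chrom: Optional[str] = None, defined_only: bool = True):
        out = []
        for rec in self.records:
            if chrom is not None and rec[0] != chrom:
                continue
            if defined_only and not rec[6]:
                continue
            out.append(rec[5])
        return np.array(out)

    def windows_overlapping(self, interval: GenomicInterval) -> List[tuple]:
        return [rec for rec in self.records
                if rec[0] == interval.chrom
                and min(rec[2], interval.end) - max(rec[1], interval.start) > 0]


def cri_track(genome: Genome, window: int = 500, step: int = 100) -> RIPTrack:
    """CRI in sliding windows across all chromosomes.

    Windows start at 0, step, 2*step, ...; a trailing partial window is
    retained when at least half the window size, else dropped.
    """
    if not window >= step >= 1:
        raise ParameterError("need window >= step >= 1")
    records = []
    for chrom, seq in genome.sequences.items():
        for start in range(0, len(seq), step):
            end = min(start + window, len(seq))
            if end - start < window and end - start < window / 2:
                continue
            res = cri_window(seq[start:end])
            records.append((chrom, start, end, res.product_index,
                            res.substrate_index, res.cri, res.defined))
    return RIPTrack(window=window, step=step, records=records)


def ripcal_classify(aligned_homologs: Sequence[str], reference_index: int = 0,
                    ids: Optional[Sequence[str]] = None) -> List[dict]:
    """Count RIP-type differences of each aligned homolog against a reference row.

    Rows are equal-length aligned sequences (gaps as '-').  For every
    non-reference row, positions where the reference has C and the row T
    (or reference G, row A) are counted, partitioned by the reference-strand
    dinucleotide context: CpA for C->T (next reference base A), TpG for
    G->A (previous reference base T), everything else as 'other'.  Columns
    where either the reference or the row has a gap are skipped; context
    bases are the adjacent non-gap reference bases.
    """
    rows = [r.upper() for r in aligned_homologs]
    if len(rows) < 2:
        raise ParameterError("need a reference and at least one homolog row")
    width = len(rows[reference_index])
    if any(len(r) != width for r in rows):
        raise FormatError("ragged alignment: rows differ in length")
    ref = rows[reference_index]

    # adjacent non-gap reference base, for dinucleotide context across gaps
    next_base = [""] * width
    nxt = ""
    for i in range(width - 1, -1, -1):
        next_base[i] = nxt
        if ref[i] != "-":
            nxt = ref[i]
    prev_base = [""] * width
    prv = ""
    for i in range(width):
        prev_base[i] = prv
        if ref[i] != "-":
            prv = ref[i]

    results = []
    for r_idx, row in enumerate(rows):
        if r_idx == reference_index:
            continue
        counts = {"c2t_cpa": 0, "c2t_other": 0, "g2a_tpg": 0, "g2a_other": 0,
                  "other_differences": 0, "compared_columns": 0}
        for i in range(width):
            a, b = ref[i], row[i]
            if a == "-" or b == "-":
                continue
            counts["compared_columns"] += 1
            if a == b:
                continue
            if a == "C" and b == "T":
                counts["c2t_cpa" if next_base[i] == "A" else "c2t_other"] += 1
            elif a == "G" and b == "A":
                counts["g2a_tpg" if prev_base[i] == "T" else "g2a_other"] += 1
            else:
                counts["other_differences"] += 1
        counts["id"] = ids[r_idx] if ids is not None else f"row_{r_idx}"
        results.append(counts)
    return results


def find_homologs(genome: Genome, query: str, k: int = 16,
                  min_anchor_frac: float = 0.05) -> List[GenomicInterval]:
    """Locate (possibly RIP-diverged) same-orientation copies of ``query``.

    Exact k-mers of the query vote for genome diagonals; diagonals
    collecting at least ``min_anchor_frac`` of the query's k-mers become
    gapless copy calls of the query's length.  Suited to RIP-diverged
    paralogs, which differ by substitutions only.
    """
    if len(query) < k:
        raise ParameterError("query shorter than k")
    anchors: Dict[str, List[Tuple[str, int]]] = {}
    for t in range(len(query) - k + 1):
        anchors.setdefault(query[t:t + k], []).append(t)
    votes: Counter = Counter()
    for chrom, seq in genome.sequences.items():
        for i in range(len(seq) - k + 1):
            offsets = anchors.get(seq[i:i + k])
            if offsets:
                for t in offsets:
                    votes[(chrom, i - t)] += 1
    min_votes = max(3, int(min_anchor_frac * (len(query) - k + 1)))
    hits = []
    for (chrom, diag), n in votes.items():
        if n >= min_votes and 0 <= diag and diag + len(query) <= len(genome[chrom]):
            hits.append(GenomicInterval(chrom, diag, diag + len(query), "+"))
    hits.sort(key=lambda iv: (iv.chrom, iv.start))
    # merge near-identical diagonals (substitution-only copies give one diagonal)
    merged: List[GenomicInterval] = []
    for iv in hits:
        if merged and iv.chrom == merged[-1].chrom and iv.start - merged[-1].start < k:
            continue
        merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------


@dataclass
class CopyNumberEstimate:
    ratio: float
    estimate: int
    element_depth: float
    flank_depth: float


def copy_number(track: CoverageTrack, element_interval: GenomicInterval,
                flank_size: int = 2000, edge_trim: int = 100) -> CopyNumberEstimate:
    """Depth ratio of an element to its flanks in the carrier's own reads.

    With multi-mapping alignment, reads from unassembled extra copies pile
    onto the single reference copy, so the ratio estimates copy number.
    Because exact alignment cannot soft-clip, reads spanning an extra
    copy's junctions are lost and depth ramps down within one read length
    of the element boundaries; ``edge_trim`` bases are excluded at each
    end (when the element is long enough) to keep the estimate unbiased.
    """
    if flank_size < 1:
        raise ParameterError("flank_size must be >= 1")
    depth = track.per_base[element_interval.chrom]
    lo = element_interval.start - flank_size
    hi = element_interval.end + flank_size
    if lo < 0 or hi > len(depth):
        raise ParameterError("flanks extend beyond the chromosome")
    trim = edge_trim if element_interval.length > 4 * edge_trim else 0
    inside = float(depth[element_interval.start + trim:element_interval.end - trim].mean())
    flank = float(np.concatenate([
        depth[lo:element_interval.start], depth[element_interval.end:hi]]).mean())
    if flank == 0:
        raise ParameterError("zero flank depth; cannot normalise")
    ratio = inside / flank
    return CopyNumberEstimate(ratio=ratio, estimate=int(round(ratio)),
                              element_depth=inside, flank_depth=flank)


# ---------------------------------------------------------------------------
# per-locus orchestration
# ---------------------------------------------------------------------------


@dataclass
class TECall:
    """Full annotation of one element locus."""

    element: GenomicInterval
    tir_pair: Optional[TIRPair]
    tir1: Optional[GenomicInterval]
    tir2: Optional[GenomicInterval]
    tsd: TSDCall
    copy_number_estimate: Optional[CopyNumberEstimate]
    homologs: List[GenomicInterval] = field(default_factory=list)
    ripcal: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        def report(iv):
            if iv is None:
                return None
            s1, e1, length = to_report_coords(iv)
            return {"chrom": iv.chrom, "start": s1, "end": e1, "length": length}

        return {
            "element": report(self.element),
            "tir": None if self.tir_pair is None else {
                "tir1": report(self.tir1), "tir2": report(self.tir2),
                "length": self.tir_pair.length,
                "mismatches": self.tir_pair.mismatches,
                "tir1_sequence": self.tir_pair.tir1_sequence,
                "tir2_sequence": self.tir_pair.tir2_sequence,
            },
            "tsd": {
                "left": self.tsd.left_tsd, "right": self.tsd.right_tsd,
                "length": self.tsd.length,
                "rip_consistent_mismatches": list(self.tsd.rip_consistent_mismatches),
                "consistent": self.tsd.consistent, "note": self.tsd.note,
            },
            "copy_number": None if self.copy_number_estimate is None else {
                "ratio": self.copy_number_estimate.ratio,
                "estimate": self.copy_number_estimate.estimate,
            },
            "homologs": [report(h) for h in self.homologs],
            "ripcal": self.ripcal,
        }


def annotate_element(genome: Genome, partner_track: CoverageTrack,
                     partner_unaligned: Sequence[ProcessedRead],
                     locus: GenomicInterval,
                     carrier_track: Optional[CoverageTrack] = None,
                     empty_sequence: Optional[str] = None,
                     index: Optional[ExactIndex] = None,
                     tir_min_len: int = 10, tir_max_mismatch: int = 0,
                     tir_flank: int = 3000, max_tsd_len: int = 10,
                     copy_flank: int = 2000) -> TECall:
    """Annotate one candidate locus end to end.

    Breakpoints are refined from partner split reads, the TIR pair searched
    in the element plus ``tir_flank`` of flanking DNA on each side, the TSD
    called at the refined boundaries, homolog copies located genome-wide
    and RIP-classified against the element as reference, and copy number
    estimated from the carrier depth track when provided.
    """
    left, right = find_breakpoints(genome, partner_track, partner_unaligned,
                                   locus, index=index)
    element = GenomicInterval(locus.chrom, left, right)
    seq = genome[locus.chrom]
    w_lo = max(0, left - tir_flank)
    w_hi = min(len(seq), right + tir_flank)
    pair = find_tirs(seq[w_lo:w_hi], min_len=tir_min_len, max_mismatch=tir_max_mismatch)
    tir1 = tir2 = None
    if pair is not None:
        tir1 = GenomicInterval(locus.chrom, w_lo + pair.tir1_start, w_lo + pair.tir1_end, "+")
        tir2 = GenomicInterval(locus.chrom, w_lo + pair.tir2_start, w_lo + pair.tir2_end, "+")
    tsd = call_tsd(genome, empty_sequence, element, max_tsd_len=max_tsd_len)
    cn = None
    if carrier_track is not None:
        cn = copy_number(carrier_track, element, flank_size=copy_flank)
    element_seq = seq[left:right]
    homologs = [h for h in find_homologs(genome, element_seq)
                if not (h.chrom == element.chrom and h.start == element.start)]
    ripcal = []
    if homologs:
        rows = [element_seq] + [genome.fetch(h) for h in homologs]
        ids = ["element"] + [str(h) for h in homologs]
        ripcal = ripcal_classify(rows, reference_index=0, ids=ids)
    return TECall(element=element, tir_pair=pair, tir1=tir1, tir2=tir2, tsd=tsd,
                  copy_number_estimate=cn, homologs=homologs, ripcal=ripcal)


def write_te_call_json(call: TECall, path) -> None:
    Path(path).write_text(json.dumps(call.to_dict(), indent=1, sort_keys=True) + "\n")


def write_cri_track_tsv(track: RIPTrack, handle) -> None:
    handle.write("chrom\twindow_start_1based\twindow_end_1based\tproduct_index\t"
                 "substrate_index\tcri\tdefined\n")
    for chrom, start, end, product, substrate, cri, defined in track.records:
        handle.write(f"{chrom}\t{start + 1}\t{end}\t{product:.6g}\t{substrate:.6g}\t"
                     f"{cri:.6g}\t{int(defined)}\n")


def write_ripcal_tsv(results: Sequence[dict], handle) -> None:
    cols = ["id", "c2t_cpa", "c2t_other", "g2a_tpg", "g2a_other",
            "other_differences", "compared_columns"]
    handle.write("\t".join(cols) + "\n")
    for res in results:
        handle.write("\t".join(str(res[c]) for c in cols) + "\n")
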