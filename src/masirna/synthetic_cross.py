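"""Synthetic sexual-cross generator with a machine-readable truth record.

The generator emulates the data underlying a meiotic-silencing small-RNA
study: a *carrier* parent genome containing a planted DNA transposon
(terminal inverted repeats + target-site duplication) that is absent from
the *non-carrier* partner, additional RIP-mutated paralog copies present in
both parents, decoy insertions unique to the carrier that produce no small
RNAs, whole-genome shotgun reads for both parents, and three developmental
time-point small-RNA libraries (PP, 2dPF, 4dPF) in which the unpaired
element emits 24-26-nt, 25-nt-mode, 5'-U-biased small RNAs from both
strands predominantly at the late time point.

Background sequence is drawn from a first-order Markov model with
fungal-like dinucleotide odds (TpA suppressed, CpA/TpG enriched) so that
the composite RIP index of unmutated DNA is negative, as in real fungal
genomes; see ``FUNGAL_DINUCLEOTIDE_ODDS``.  Reads are error-free: with the
pipeline's zero-mismatch alignment rule, sequencing errors are pure dropout
and would test nothing.

Uracil is represented as T throughout; the "5' uridine" bias is realised by
biased sampling of read start positions whose genomic 5' base is T, so that
every read still matches the genome exactly.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ParameterError
from .io_formats import (
    AnnotatedFeature,
    FEATURE_CLASSES,
    Genome,
    GenomicInterval,
    revcomp,
    write_annotations_bed,
    write_fasta,
    write_fastq,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

TIMEPOINTS = ("PP", "2dPF", "4dPF")

#: Relative dinucleotide odds emulating fungal genome composition: TpA is
#: universally under-represented and CpA/TpG (the RIP substrate) somewhat
#: over-represented.  With these odds an unmutated genome shows a clearly
#: negative composite RIP index almost everywhere, which is the empirical
#: baseline the RIP index presupposes.
FUNGAL_DINUCLEOTIDE_ODDS = {("T", "A"): 0.75, ("C", "A"): 1.45, ("T", "G"): 1.45}


# ---------------------------------------------------------------------------
# random sequence
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _transition_matrix(gc_fraction: float, odds: Optional[dict]) -> np.ndarray:
    """4x4 next-base transition matrix whose stationary GC equals ``gc_fraction``.

    Base weights are calibrated by fixed-point iteration on the stationary
    distribution of the chain (deterministic, a handful of 4x4 eigen solves).
    """
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    w = np.ones((4, 4))
    idx = {b: i for i, b in enumerate(_BASES)}
    for (a, b), o in (odds or {}).items():
        w[idx[a], idx[b]] = o
    trans = w * p[None, :]
    trans /= trans.sum(axis=1, keepdims=True)
    for _ in range(60):
        evals, evecs = np.linalg.eig(trans.T)
        stat = np.real(evecs[:, np.argmax(np.real(evals))])
        stat = np.abs(stat) / np.abs(stat).sum()
        cur_gc = stat[1] + stat[2]
        if abs(cur_gc - gc_fraction) < 1e-9:
            break
        p[1] *= gc_fraction / cur_gc
        p[2] *= gc_fraction / cur_gc
        p[0] *= (1 - gc_fraction) / (1 - cur_gc)
        p[3] *= (1 - gc_fraction) / (1 - cur_gc)
        p /= p.sum()
        trans = w * p[None, :]
        trans /= trans.sum(axis=1, keepdims=True)
    return trans


def _random_sequence(rng: np.random.Generator, n: int, gc_fraction: float,
                     odds: Optional[dict] = None) -> str:
    if n <= 0:
        raise ParameterError("sequence length must be positive")
    if odds is None:
        bases = rng.choice(
            np.frombuffer(_BASES.encode(), dtype=np.uint8), size=n,
            p=[(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2],
        )
        return bases.tobytes().decode()
    trans = _transition_matrix(gc_fraction, odds)
    cum = [row.cumsum().tolist() for row in trans]
    u = rng.random(n)
    out = bytearray(n)
    state = int(rng.choice(4))
    basebytes = _BASES.encode()
    for i in range(n):
        row = cum[state]
        x = u[i]
        state = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out[i] = basebytes[state]
    return out.decode()


def make_random_genome(seed: int, chrom_lengths: Dict[str, int], gc_fraction: float,
                       dinucleotide_odds: Optional[dict] = None,
                       mito_name: Optional[str] = None) -> Genome:
    """Deterministic random genome with the requested GC fraction.

    With ``dinucleotide_odds=None`` bases are iid; otherwise a first-order
    Markov chain with the given relative dinucleotide odds is used, with its
    stationary GC calibrated to ``gc_fraction``.
    """
    if not 0 < gc_fraction < 1:
        raise ParameterError("gc_fraction must be in (0, 1)")
    for name, length in chrom_lengths.items():
        if length < 1000:
            raise ParameterError(f"chromosome {name!r} shorter than 1 kb")
    rng = np.random.default_rng(seed)
    sequences = {
        name: _random_sequence(rng, length, gc_fraction, dinucleotide_odds)
        for name, length in chrom_lengths.items()
    }
    return Genome(sequences=sequences, mito_name=mito_name)


# ---------------------------------------------------------------------------
# element planting and RIP
# ---------------------------------------------------------------------------


@dataclass
class ElementSpec:
    """Geometry of the planted DNA transposon.

    The element is ``TIR1 + body + TIR2`` with ``TIR2 = revcomp(TIR1)``;
    on insertion the ``tsd_length`` target-site bases are duplicated so the
    occupied haplotype reads ``... T TIR1 body TIR2 T ...``.
    """

    body_length: int = 2500
    tir_length: int = 30
    tsd_length: int = 3
    tir_sequence: Optional[str] = None
    insertion_site: Optional[Tuple[str, int]] = None  # (chrom, 0-based position)
    rip_tsd: bool = False  # mutate one C->T in the right-hand TSD copy

    @property
    def element_length(self) -> int:
        return self.body_length + 2 * self.tir_length


@dataclass
class TruthRecord:
    """Ground truth of a synthetic cross, for parameter-recovery tests."""

    seed: int
    element_interval: GenomicInterval
    tir1: GenomicInterval
    tir1_sequence: str
    tir2: GenomicInterval
    tir2_sequence: str
    tsd_sequence: str
    tsd_left: Optional[GenomicInterval]
    tsd_right: Optional[GenomicInterval]
    masirna_source_regions: List[GenomicInterval]
    rip_copies: List[Tuple[GenomicInterval, Tuple[int, ...]]] = field(default_factory=list)
    decoy_intervals: List[GenomicInterval] = field(default_factory=list)
    copy_number: int = 1
    srna_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def iv(x):
            return None if x is None else [x.chrom, x.start, x.end, x.strand]

        return {
            "seed": self.seed,
            "element_interval": iv(self.element_interval),
            "tir1": iv(self.tir1), "tir1_sequence": self.tir1_sequence,
            "tir2": iv(self.tir2), "tir2_sequence": self.tir2_sequence,
            "tsd_sequence": self.tsd_sequence,
            "tsd_left": iv(self.tsd_left), "tsd_right": iv(self.tsd_right),
            "masirna_source_regions": [iv(r) for r in self.masirna_source_regions],
            "rip_copies": [[iv(r), list(pos)] for r, pos in self.rip_copies],
            "decoy_intervals": [iv(r) for r in self.decoy_intervals],
            "copy_number": self.copy_number,
            "srna_counts": self.srna_counts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        def iv(x):
            return None if x is None else GenomicInterval(x[0], x[1], x[2], x[3])

        return cls(
            seed=d["seed"],
            element_interval=iv(d["element_interval"]),
            tir1=iv(d["tir1"]), tir1_sequence=d["tir1_sequence"],
            tir2=iv(d["tir2"]), tir2_sequence=d["tir2_sequence"],
            tsd_sequence=d["tsd_sequence"],
            tsd_left=iv(d["tsd_left"]), tsd_right=iv(d["tsd_right"]),
            masirna_source_regions=[iv(r) for r in d["masirna_source_regions"]],
            rip_copies=[(iv(r), tuple(pos)) for r, pos in d["rip_copies"]],
            decoy_intervals=[iv(r) for r in d["decoy_intervals"]],
            copy_number=d["copy_number"],
            srna_counts=d["srna_counts"],
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "TruthRecord":
        return cls.from_dict(json.loads(Path(path).read_text()))


def apply_rip(sequence: str, mutation_fraction: float, seed) -> Tuple[str, Tuple[int, ...]]:
    """Apply repeat-induced point mutation to a sequence.

    Each C followed by A mutates to T with probability ``mutation_fraction``,
    and each G preceded by T mutates to A with the same probability (the
    CpA->TpA event seen from the opposite strand).  Contexts are evaluated on
    the original sequence, so mutations do not create new eligible sites
    within a single application.  Returns the mutated sequence and the
    0-based positions mutated.
    """
    if not 0 <= mutation_fraction <= 1:
        raise ParameterError("mutation_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = list(sequence)
    positions = []
    for i in range(len(sequence) - 1):
        if sequence[i] == "C" and sequence[i + 1] == "A":
            if rng.random() < mutation_fraction:
                out[i] = "T"
                positions.append(i)
        if sequence[i] == "T" and sequence[i + 1] == "G":
            if rng.random() < mutation_fraction:
                out[i + 1] = "A"
                positions.append(i + 1)
    return "".join(out), tuple(sorted(set(positions)))


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in _BASES if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


def _fix_insertion_site(seq: str, pos: int, tsd_len: int, tir: str,
                        rng: np.random.Generator) -> str:
    """Adjust up to three bases around an insertion site so the planted
    element's annotation is unambiguous.

    Real insertions can sit in micro-homology that makes the breakpoint /
    TSD decomposition non-unique; the generator avoids this so the truth
    record is exact.  Constraints enforced:

    * the base right of the target site differs from the element's first
      base, and the base left of it from the complement of that base
      (otherwise the insertion point could be rotated by one);
    * the target site's terminal bases are not complementary (otherwise the
      TIR pair could be extended outward by one).
    """
    left = seq[pos - 1]
    right_of_tsd = seq[pos + tsd_len]
    if right_of_tsd == tir[0]:
        right_of_tsd = _other_base(rng, tir[0])
        seq = seq[:pos + tsd_len] + right_of_tsd + seq[pos + tsd_len + 1:]
    if left == _COMP[tir[0]] or (tsd_len == 0 and left == _COMP[right_of_tsd]):
        avoid = [_COMP[tir[0]]] + ([_COMP[right_of_tsd]] if tsd_len == 0 else [])
        seq = seq[:pos - 1] + _other_base(rng, *avoid) + seq[pos:]
    if tsd_len > 0:
        tsd = seq[pos:pos + tsd_len]
        if tsd[-1] == _COMP[tsd[0]]:
            fixed = _other_base(rng, tsd[-1], _COMP[tsd[0]])
            seq = seq[:pos + tsd_len - 1] + fixed + seq[pos + tsd_len:]
    return seq


def _build_element(rng: np.random.Generator, spec: ElementSpec, gc: float,
                   odds: Optional[dict]) -> Tuple[str, str]:
    """Return (tir1, body).  The body's terminal bases are chosen so the
    planted TIR pair cannot be extended inward by a coincidental match,
    keeping the truth annotation unambiguous."""
    if spec.tir_length < 1:
        raise ParameterError("tir_length must be >= 1")
    if spec.body_length < 2:
        raise ParameterError("body_length must be >= 2")
    tir = spec.tir_sequence.upper() if spec.tir_sequence else _random_sequence(
        rng, spec.tir_length, gc, odds)
    if len(tir) != spec.tir_length:
        raise ParameterError("tir_sequence length disagrees with tir_length")
    body = _random_sequence(rng, spec.body_length, gc, odds)
    if body[0] == _COMP[body[-1]]:
        body = _other_base(rng, body[0]) + body[1:]
    return tir, body


def plant_element(genome: Genome, spec: ElementSpec, seed: int,
                  gc_fraction: float = 0.5,
                  dinucleotide_odds: Optional[dict] = FUNGAL_DINUCLEOTIDE_ODDS,
                  ) -> Tuple[Genome, Genome, TruthRecord]:
    """Insert a transposon into ``genome``, duplicating the target site.

    Returns ``(occupied, empty, truth)`` where *empty* is the input genome
    (up to at most two single-base adjustments that keep the planted TIR
    pair the unique maximal inverted repeat at the locus) and *occupied*
    carries ``TSD + TIR1 + body + TIR2 + TSD`` at the insertion site.
    """
    rng = np.random.default_rng(seed)
    if spec.insertion_site is None:
        raise ParameterError("ElementSpec.insertion_site is required")
    chrom, pos = spec.insertion_site
    if chrom not in genome:
        raise ParameterError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom]
    if pos < 3000 or pos + spec.tsd_length + 3000 > len(seq):
        raise ParameterError("insertion site must be >= 3 kb from chromosome ends")
    if spec.tsd_length < 0:
        raise ParameterError("tsd_length must be >= 0")

    tir, body = _build_element(rng, spec, gc_fraction, dinucleotide_odds)
    element = tir + body + revcomp(tir)
    seq = _fix_insertion_site(seq, pos, spec.tsd_length, tir, rng)
    tsd = seq[pos:pos + spec.tsd_length]

    empty_sequences = dict(genome.sequences)
    empty_sequences[chrom] = seq
    empty = Genome(sequences=empty_sequences, mito_name=genome.mito_name)

    right_tsd = tsd
    if spec.rip_tsd and "C" in tsd:
        i = tsd.index("C")
        right_tsd = tsd[:i] + "T" + tsd[i + 1:]

    occ_seq = seq[:pos + spec.tsd_length] + element + right_tsd + seq[pos + spec.tsd_length:]
    occ_sequences = dict(empty_sequences)
    occ_sequences[chrom] = occ_seq
    occupied = Genome(sequences=occ_sequences, mito_name=genome.mito_name)

    el_start = pos + spec.tsd_length
    el_end = el_start + len(element)
    truth = TruthRecord(
        seed=seed,
        element_interval=GenomicInterval(chrom, el_start, el_end),
        tir1=GenomicInterval(chrom, el_start, el_start + spec.tir_length, "+"),
        tir1_sequence=tir,
        tir2=GenomicInterval(chrom, el_end - spec.tir_length, el_end, "+"),
        tir2_sequence=revcomp(tir),
        tsd_sequence=tsd,
        tsd_left=GenomicInterval(chrom, pos, el_start) if spec.tsd_length else None,
        tsd_right=GenomicInterval(chrom, el_end, el_end + spec.tsd_length) if spec.tsd_length else None,
        masirna_source_regions=[GenomicInterval(chrom, el_start, el_end)],
    )
    return occupied, empty, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_wgs_reads(genome: Genome, mean_depth: float, read_length: int,
                       seed: int, id_prefix: str = "wgs") -> List[Tuple[str, str, str]]:
    """Error-free uniform shotgun reads; about half are reverse-complemented.

    The read count per chromosome is Poisson with mean
    ``mean_depth * chrom_length / read_length``.
    """
    if mean_depth < 0:
        raise ParameterError("mean_depth must be >= 0")
    if read_length > min(genome.chrom_lengths.values()):
        raise ParameterError("read_length exceeds the shortest chromosome")
    rng = np.random.default_rng(seed)
    reads = []
    qual = "I" * read_length
    i = 0
    for chrom, seq in genome.sequences.items():
        n = int(rng.poisson(mean_depth * len(seq) / read_length)) if mean_depth > 0 else 0
        if n == 0:
            continue
        starts = rng.integers(0, len(seq) - read_length + 1, size=n)
        flips = rng.random(n) < 0.5
        for s, flip in zip(starts, flips):
            sub = seq[s:s + read_length]
            reads.append((f"{id_prefix}_{i:07d}", revcomp(sub) if flip else sub, qual))
            i += 1
    return reads


@dataclass
class SrnaProfile:
    """Per-class read counts and read-feature distributions for one cross.

    Background classes are emitted at every time point; masiRNA counts are
    per time point, with early time points defaulting to 5% of the late
    count (small RNAs from unpaired regions are observed at low frequency
    before the late stage, not zero).
    """

    background_counts: Dict[str, int] = field(default_factory=lambda: {
        "rRNA": 20000, "tRNA": 8000, "snoRNA": 3000, "milRNA": 3000,
        "disiRNA": 3000, "mito": 3000, "other": 5000,
    })
    masirna_counts: Dict[str, int] = field(default_factory=lambda: {
        "PP": 400, "2dPF": 400, "4dPF": 8000,
    })
    background_lengths: Dict[int, float] = field(default_factory=lambda: {
        18: 0.05, 19: 0.15, 20: 0.45, 21: 0.20, 22: 0.10, 23: 0.05,
    })
    masirna_lengths: Dict[int, float] = field(default_factory=lambda: {
        24: 0.25, 25: 0.50, 26: 0.25,
    })
    fraction_5pU_background: float = 0.75
    fraction_5pU_masirna: float = 0.80

    def library_size(self, timepoint: str) -> int:
        return sum(self.background_counts.values()) + self.masirna_counts[timepoint]


class _RegionSampler:
    """Samples exact-match read coordinates from one region with a 5'-T bias.

    With probability ``fraction_5pU`` the start is drawn uniformly from
    positions whose 5' base (in the read's orientation) is T, otherwise from
    the complementary positions, so the realised 5'-U fraction matches the
    configured one exactly in expectation while every read still matches the
    genome with zero mismatches.
    """

    def __init__(self, seq: str, start: int, end: int):
        self.start, self.end = start, end
        sub = seq[start:end]
        self.t_pos = [start + i for i, b in enumerate(sub) if b == "T"]
        self.nt_pos = [start + i for i, b in enumerate(sub) if b != "T"]
        self.a_end = [start + i for i, b in enumerate(sub) if b == "A"]
        self.na_end = [start + i for i, b in enumerate(sub) if b != "A"]

    @staticmethod
    def _pick(rng, positions, lo, hi):
        i0 = bisect_left(positions, lo)
        i1 = bisect_right(positions, hi)
        if i1 <= i0:
            return None
        return positions[int(rng.integers(i0, i1))]

    def sample(self, rng: np.random.Generator, length: int, strand: str,
               biased: bool) -> Optional[int]:
        """Return a read start, or None if the region is too short."""
        if self.end - self.start < length:
            return None
        lo, hi = self.start, self.end - length
        if strand == "+":
            pools = (self.t_pos, self.nt_pos) if biased else (self.nt_pos, self.t_pos)
            s = self._pick(rng, pools[0], lo, hi)
            if s is None:
                s = self._pick(rng, pools[1], lo, hi)
            return s
        # '-' strand: the read's 5' base is the complement of the genomic
        # base at the segment's right end, so a 5'-T read needs genomic A.
        lo_e, hi_e = self.start + length - 1, self.end - 1
        pools = (self.a_end, self.na_end) if biased else (self.na_end, self.a_end)
        e = self._pick(rng, pools[0], lo_e, hi_e)
        if e is None:
            e = self._pick(rng, pools[1], lo_e, hi_e)
        return None if e is None else e - length + 1


def _draw_length(rng: np.random.Generator, dist: Dict[int, float]) -> int:
    lengths = sorted(dist)
    probs = np.array([dist[l] for l in lengths], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(lengths, p=probs))


def simulate_srna_library(occupied_genome: Genome, annotations: Sequence[AnnotatedFeature],
                          truth: TruthRecord, timepoint: str, profile: SrnaProfile,
                          seed: int) -> List[Tuple[str, str, str]]:
    """One time-point small-RNA library as error-free FASTQ records.

    Background classes (length peak 20 nt) are drawn from the annotated
    features at all time points; masiRNA reads (24-26 nt, mode 25 nt, both
    strands, 5'-U biased) are drawn from ``truth.masirna_source_regions``
    at the per-time-point count in ``profile``.
    """
    if timepoint not in TIMEPOINTS:
        raise ParameterError(f"unknown timepoint {timepoint!r}")
    rng = np.random.default_rng(seed)
    genome = occupied_genome
    for region in truth.masirna_source_regions:
        if region.chrom not in genome or region.end > len(genome[region.chrom]):
            raise ParameterError(f"masiRNA source region {region} outside genome")

    samplers: Dict[Tuple[str, int, int], _RegionSampler] = {}

    def sampler_for(chrom: str, start: int, end: int) -> _RegionSampler:
        key = (chrom, start, end)
        if key not in samplers:
            samplers[key] = _RegionSampler(genome[chrom], start, end)
        return samplers[key]

    by_class: Dict[str, List[GenomicInterval]] = {c: [] for c in FEATURE_CLASSES}
    for feat in annotations:
        by_class[feat.feature_class].append(feat.interval)

    main_chrom = next(c for c in genome.sequences if c != genome.mito_name)
    blocked = sorted(
        [(f.interval.start, f.interval.end) for f in annotations if f.interval.chrom == main_chrom]
        + [(r.start, r.end) for r in truth.masirna_source_regions if r.chrom == main_chrom]
        + [(r.start, r.end) for r in truth.decoy_intervals if r.chrom == main_chrom]
        # RIP paralogs share unmutated stretches with the element; keep the
        # unannotated background clear of them so masiRNA regions receive
        # exactly the configured read counts
        + [(r.start, r.end) for r, _pos in truth.rip_copies if r.chrom == main_chrom]
    )
    gaps, prev = [], 0
    for s, e in blocked + [(len(genome[main_chrom]), len(genome[main_chrom]))]:
        if s - prev >= 100:
            gaps.append(GenomicInterval(main_chrom, prev, s))
        prev = max(prev, e)
    gap_weights = np.array([g.length for g in gaps], dtype=float)
    gap_weights /= gap_weights.sum()

    reads: List[Tuple[str, str, str]] = []

    def emit(regions: List[GenomicInterval], count: int, lengths: Dict[int, float],
             frac_5pu: float, tag: str) -> None:
        if not regions or count <= 0:
            return
        for _ in range(count):
            region = regions[int(rng.integers(len(regions)))]
            length = _draw_length(rng, lengths)
            strand = "+" if rng.random() < 0.5 else "-"
            biased = rng.random() < frac_5pu
            smp = sampler_for(region.chrom, region.start, region.end)
            start = smp.sample(rng, length, strand, biased)
            if start is None:
                continue
            sub = genome[region.chrom][start:start + length]
            seq = revcomp(sub) if strand == "-" else sub
            reads.append((f"{tag}{len(reads):07d}", seq, "I" * length))

    bg = profile.background_counts
    for cls in FEATURE_CLASSES:
        emit(by_class[cls], bg.get(cls, 0), profile.background_lengths,
             profile.fraction_5pU_background, f"{timepoint}_")
    if genome.mito_name is not None and bg.get("mito", 0):
        mito_len = len(genome[genome.mito_name])
        emit([GenomicInterval(genome.mito_name, 0, mito_len)], bg["mito"],
             profile.background_lengths, profile.fraction_5pU_background, f"{timepoint}_")
    if bg.get("other", 0):
        for _ in range(bg["other"]):
            gap = gaps[int(rng.choice(len(gaps), p=gap_weights))]
            length = _draw_length(rng, profile.background_lengths)
            strand = "+" if rng.random() < 0.5 else "-"
            biased = rng.random() < profile.fraction_5pU_background
            smp = sampler_for(gap.chrom, gap.start, gap.end)
            start = smp.sample(rng, length, strand, biased)
            if start is None:
                continue
            sub = genome[gap.chrom][start:start + length]
            seq = revcomp(sub) if strand == "-" else sub
            reads.append((f"{timepoint}_{len(reads):07d}", seq, "I" * length))
    emit(truth.masirna_source_regions, profile.masirna_counts.get(timepoint, 0),
         profile.masirna_lengths, profile.fraction_5pU_masirna, f"{timepoint}_")
    return reads


# ---------------------------------------------------------------------------
# full cross
# ---------------------------------------------------------------------------


@dataclass
class CrossConfig:
    """Study conditions for one synthetic cross.

    Sites default to fixed fractions of the main chromosome so the layout
    scales with genome size; all special loci keep >= 3 kb clear of the
    chromosome ends and of each other.
    """

    chrom_length: int = 100_000
    main_chrom: str = "chrI"
    mito_name: str = "chrM"
    mito_length: int = 8_000
    gc: float = 0.5
    dinucleotide_odds: Optional[dict] = field(
        default_factory=lambda: dict(FUNGAL_DINUCLEOTIDE_ODDS))
    element: ElementSpec = field(default_factory=ElementSpec)
    rip_copies: int = 2
    rip_fraction: float = 0.5
    decoy_lengths: Tuple[int, ...] = (600, 2000)
    extra_element_copies: int = 1
    wgs_depth: float = 20.0
    wgs_read_length: int = 100
    srna: SrnaProfile = field(default_factory=SrnaProfile)

    # site fractions along the main chromosome
    element_site_frac: float = 0.40
    rip_site_fracs: Tuple[float, ...] = (0.15, 0.25)
    decoy_site_fracs: Tuple[float, ...] = (0.60, 0.70)
    extra_copy_site_frac: float = 0.85

    def validate(self) -> None:
        if self.rip_copies > len(self.rip_site_fracs):
            raise ParameterError("more rip_copies than rip_site_fracs")
        if len(self.decoy_lengths) > len(self.decoy_site_fracs):
            raise ParameterError("more decoy_lengths than decoy_site_fracs")
        if not 0 <= self.rip_fraction <= 1:
            raise ParameterError("rip_fraction must be in [0, 1]")
        if self.wgs_read_length > self.mito_length or self.wgs_read_length > self.chrom_length:
            raise ParameterError("wgs_read_length exceeds a chromosome length")


@dataclass
class CrossBundle:
    """Everything one synthetic cross produces, in memory."""

    config: CrossConfig
    seed: int
    occupied: Genome
    empty: Genome
    carrier: Genome  # physical carrier genome (occupied + extra element copies)
    annotations: List[AnnotatedFeature]
    truth: TruthRecord
    wgs_reads: List[Tuple[str, str, str]]  # non-carrier partner
    carrier_wgs_reads: List[Tuple[str, str, str]]
    srna: Dict[str, List[Tuple[str, str, str]]]


_FEATURE_PLAN = (
    ("rRNA", 2, 2000),
    ("tRNA", 8, 80),
    ("snoRNA", 5, 150),
    ("milRNA", 4, 250),
    ("disiRNA", 4, 400),
)


def _place_features(rng: np.random.Generator, chrom: str, length: int,
                    blocked: List[Tuple[int, int]]) -> List[AnnotatedFeature]:
    taken = list(blocked)
    features = []
    idx = 0
    for cls, count, flen in _FEATURE_PLAN:
        for j in range(count):
            for _ in range(2000):
                start = int(rng.integers(3000, length - 3000 - flen))
                if all(start + flen + 100 <= s or start >= e + 100 for s, e in taken):
                    break
            else:
                raise ParameterError("could not place annotation features; genome too small")
            taken.append((start, start + flen))
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(AnnotatedFeature(
                GenomicInterval(chrom, start, start + flen, strand), cls, f"{cls}_{j}"))
            idx += 1
    return features


def simulate_cross(config: CrossConfig, seed: int) -> CrossBundle:
    """Generate a complete synthetic cross, deterministically for a seed."""
    config.validate()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(12)]
    rng = np.random.default_rng(seeds[0])

    L = config.chrom_length
    chrom = config.main_chrom
    base = make_random_genome(seeds[1], {chrom: L, config.mito_name: config.mito_length},
                              config.gc, config.dinucleotide_odds,
                              mito_name=config.mito_name)
    base_seq = base[chrom]

    spec = config.element
    el_site = spec.insertion_site[1] if spec.insertion_site else int(L * config.element_site_frac)
    tir, body = _build_element(rng, spec, config.gc, config.dinucleotide_odds)
    element = tir + body + revcomp(tir)

    # --- TSD and ambiguity-breaking adjustments on the base sequence
    tsd_len = spec.tsd_length
    base_seq = _fix_insertion_site(base_seq, el_site, tsd_len, tir, rng)
    tsd = base_seq[el_site:el_site + tsd_len]

    # --- RIP paralogs, overwritten in place in BOTH haplotypes
    rip_records = []  # (base_start, mutated_seq, positions)
    for i in range(config.rip_copies):
        site = int(L * config.rip_site_fracs[i])
        mutated, positions = apply_rip(element, config.rip_fraction, seeds[2] + i)
        base_seq = base_seq[:site] + mutated + base_seq[site + len(element):]
        rip_records.append((site, mutated, positions))

    empty = Genome(sequences={chrom: base_seq, config.mito_name: base[config.mito_name]},
                   mito_name=config.mito_name)

    # --- insertions unique to the carrier (element + decoys), base coords
    right_tsd = tsd
    if spec.rip_tsd and "C" in tsd:
        i = tsd.index("C")
        right_tsd = tsd[:i] + "T" + tsd[i + 1:]
    events = [(el_site + tsd_len, element + right_tsd, "element")]
    decoy_seqs = []
    for i, dlen in enumerate(config.decoy_lengths):
        site = int(L * config.decoy_site_fracs[i])
        dseq = _random_sequence(rng, dlen, config.gc, config.dinucleotide_odds)
        events.append((site, dseq, f"decoy_{i}"))
        decoy_seqs.append(dseq)
    events.sort()

    occ_parts, prev, block_starts = [], 0, {}
    offset = 0
    for pos, ins, kind in events:
        occ_parts.append(base_seq[prev:pos])
        block_starts[kind] = pos + offset
        occ_parts.append(ins)
        offset += len(ins)
        prev = pos
    occ_parts.append(base_seq[prev:])
    occ_seq = "".join(occ_parts)

    def shift(x: int) -> int:
        return x + sum(len(ins) for pos, ins, _ in events if x >= pos)

    occupied = Genome(sequences={chrom: occ_seq, config.mito_name: base[config.mito_name]},
                      mito_name=config.mito_name)

    el_start = block_starts["element"]
    el_end = el_start + len(element)
    decoy_intervals = []
    for i in range(len(config.decoy_lengths)):
        s = block_starts[f"decoy_{i}"]
        decoy_intervals.append(GenomicInterval(chrom, s, s + len(decoy_seqs[i])))

    truth = TruthRecord(
        seed=seed,
        element_interval=GenomicInterval(chrom, el_start, el_end),
        tir1=GenomicInterval(chrom, el_start, el_start + len(tir), "+"),
        tir1_sequence=tir,
        tir2=GenomicInterval(chrom, el_end - len(tir), el_end, "+"),
        tir2_sequence=revcomp(tir),
        tsd_sequence=tsd,
        tsd_left=GenomicInterval(chrom, el_start - tsd_len, el_start) if tsd_len else None,
        tsd_right=GenomicInterval(chrom, el_end, el_end + tsd_len) if tsd_len else None,
        masirna_source_regions=[GenomicInterval(chrom, el_start, el_end)],
        rip_copies=[
            (GenomicInterval(chrom, shift(s), shift(s) + len(element)), pos)
            for s, _seq, pos in rip_records
        ],
        decoy_intervals=decoy_intervals,
        copy_number=1 + config.extra_element_copies,
        srna_counts={
            tp: {**config.srna.background_counts,
                 "masiRNA": config.srna.masirna_counts.get(tp, 0)}
            for tp in TIMEPOINTS
        },
    )

    # --- annotations placed in base coords away from all special sites,
    #     then shifted into occupied (reference) coordinates
    blocked = [(0, 3000), (L - 3000, L)]
    blocked += [(el_site - 200, el_site + tsd_len + 200)]
    blocked += [(s - 200, s + len(element) + 200) for s, _m, _p in rip_records]
    for i, dlen in enumerate(config.decoy_lengths):
        site = int(L * config.decoy_site_fracs[i])
        blocked.append((site - 200, site + 200))
    extra_site = int(L * config.extra_copy_site_frac)
    blocked.append((extra_site - 200, extra_site + 200))
    base_features = _place_features(np.random.default_rng(seeds[3]), chrom, L, blocked)
    annotations = [
        AnnotatedFeature(f.interval.shifted(shift(f.interval.start) - f.interval.start),
                         f.feature_class, f.id)
        for f in base_features
    ]

    # --- physical carrier genome: occupied + identical extra element copies
    carrier_seq = occ_seq
    for i in range(config.extra_element_copies):
        at = shift(extra_site) + i * len(element)
        carrier_seq = carrier_seq[:at] + element + carrier_seq[at:]
    carrier = Genome(sequences={chrom: carrier_seq, config.mito_name: base[config.mito_name]},
                     mito_name=config.mito_name)

    wgs_reads = simulate_wgs_reads(empty, config.wgs_depth, config.wgs_read_length,
                                   seeds[4], id_prefix="partner")
    carrier_wgs_reads = simulate_wgs_reads(carrier, config.wgs_depth, config.wgs_read_length,
                                           seeds[5], id_prefix="carrier")
    srna = {
        tp: simulate_srna_library(occupied, annotations, truth, tp, config.srna, seeds[6 + i])
        for i, tp in enumerate(TIMEPOINTS)
    }
    return CrossBundle(config=config, seed=seed, occupied=occupied, empty=empty,
                       carrier=carrier, annotations=annotations, truth=truth,
                       wgs_reads=wgs_reads, carrier_wgs_reads=carrier_wgs_reads, srna=srna)


def write_bundle(bundle: CrossBundle, outdir) -> Dict[str, Path]:
    """Write a cross to disk as plain-text FASTA/FASTQ/BED/JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name, writer):
        path = outdir / name
        with open(path, "w") as fh:
            writer(fh)
        paths[name] = path

    _write("occupied.fasta", lambda fh: write_fasta(bundle.occupied, fh))
    _write("empty.fasta", lambda fh: write_fasta(bundle.empty, fh))
    _write("wgs.fastq", lambda fh: write_fastq(bundle.wgs_reads, fh))
    _write("carrier_wgs.fastq", lambda fh: write_fastq(bundle.carrier_wgs_reads, fh))
    for tp in TIMEPOINTS:
        _write(f"srna_{tp}.fastq", lambda fh, tp=tp: write_fastq(bundle.srna[tp], fh))
    _write("annotations.bed", lambda fh: write_annotations_bed(
        bundle.annotations, fh, header=f"seed={bundle.seed}"))
    bundle.truth.save(outdir / "truth.json")
    paths["truth.json"] = outdir / "truth.json"
    return paths
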