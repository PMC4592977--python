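"""Small-RNA read processing: trimming, zero-mismatch alignment, classification.

The pipeline mirrors a strict short-read workflow: adapter trimming, an
inclusive length filter (default 18-29 nt), exhaustive exact (zero-mismatch)
alignment of every read to both genome strands with all placements kept, an
eight-class partition of reads (rRNA, tRNA, snoRNA, milRNA, disiRNA,
masiRNA, mitochondrial, other), and per-library length/5'-base/strand/
density profiles.

Multi-mapped reads are classified once per read (highest-precedence class
over all placements) and counted fractionally (1/n per placement) in
densities, so totals are conserved exactly.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .exceptions import ParameterError
from .io_formats import AnnotatedFeature, Genome, GenomicInterval, revcomp

#: Fixed classification precedence: abundant structural RNAs first, so they
#: are never absorbed by broad unpaired regions; masiRNA before the
#: mitochondrial and catch-all classes.
CLASS_PRECEDENCE = ("rRNA", "tRNA", "snoRNA", "milRNA", "disiRNA", "masiRNA", "mito", "other")
_RANK = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}


@dataclass(frozen=True)
class ProcessedRead:
    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReadHitSet:
    """One read plus every zero-mismatch placement on either strand."""

    read: ProcessedRead
    hits: List[GenomicInterval]

    @property
    def weight(self) -> float:
        """Per-hit multi-mapping weight, 1/|hits|."""
        return 1.0 / len(self.hits)


def trim_adapter(read_sequence: str, adapter_sequence: str, min_overlap: int = 6) -> str:
    """Remove a 3' adapter.

    If the full adapter occurs anywhere in the read, everything from its
    first occurrence is removed; otherwise the longest read suffix that is a
    prefix of the adapter (length >= ``min_overlap``) is removed.  A read
    with no detectable adapter is returned unchanged.
    """
    if not adapter_sequence:
        raise ParameterError("adapter sequence must be non-empty")
    if min_overlap < 1:
        raise ParameterError("min_overlap must be >= 1")
    pos = read_sequence.find(adapter_sequence)
    if pos != -1:
        return read_sequence[:pos]
    max_k = min(len(read_sequence), len(adapter_sequence) - 1)
    for k in range(max_k, min_overlap - 1, -1):
        if read_sequence.endswith(adapter_sequence[:k]):
            return read_sequence[:-k]
    return read_sequence


def length_filter(reads: Iterable[Tuple[str, str]], min_len: int = 18,
                  max_len: int = 29) -> Tuple[List[ProcessedRead], Dict[str, int]]:
    """Keep reads with ``min_len <= length <= max_len`` (inclusive bounds).

    ``reads`` yields ``(id, sequence)`` pairs (extra tuple elements such as
    qualities are ignored).  Returns the retained reads and a tally of
    discarded-short / discarded-long counts.
    """
    if min_len > max_len:
        raise ParameterError("min_len must be <= max_len")
    kept: List[ProcessedRead] = []
    stats = {"input": 0, "kept": 0, "discarded_short": 0, "discarded_long": 0}
    for rec in reads:
        read_id, seq = rec[0], rec[1]
        stats["input"] += 1
        if len(seq) < min_len:
            stats["discarded_short"] += 1
        elif len(seq) > max_len:
            stats["discarded_long"] += 1
        else:
            stats["kept"] += 1
            kept.append(ProcessedRead(read_id, seq))
    return kept, stats


class ExactIndex:
    """All-positions exact lookup over both strands of a genome.

    A k-mer hash anchors the first k bases of a (forward or
    reverse-complemented) query; each anchor hit is verified by direct
    string comparison, so results are exact for any query of length >= k.
    """

    def __init__(self, genome: Genome, k: int = 12):
        if k < 1:
            raise ParameterError("k must be >= 1")
        self.genome = genome
        self.k = k
        index: Dict[str, list] = defaultdict(list)
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                index[seq[i:i + k]].append((chrom, i))
        self._index = dict(index)

    def lookup(self, kmer: str) -> list:
        """Positions of an exact k-mer on the forward strand."""
        return self._index.get(kmer, [])

    def find_all(self, query: str) -> List[GenomicInterval]:
        """Every zero-mismatch placement of ``query`` on either strand.

        Queries containing N never align (zero-mismatch rule); queries
        shorter than k raise :class:`ParameterError`.
        """
        n = len(query)
        if n < self.k:
            raise ParameterError(f"query length {n} < index k={self.k}")
        if "N" in query:
            return []
        hits: List[GenomicInterval] = []
        sequences = self.genome.sequences
        for oriented, strand in ((query, "+"), (revcomp(query), "-")):
            prefix = oriented[:self.k]
            for chrom, pos in self._index.get(prefix, ()):
                if sequences[chrom].startswith(oriented, pos):
                    hits.append(GenomicInterval(chrom, pos, pos + n, strand))
        return hits


def align_reads(reads: Sequence[ProcessedRead], index: ExactIndex,
                ) -> Tuple[List[ReadHitSet], List[ProcessedRead]]:
    """Align length-filtered reads; returns (hitsets, unaligned reads).

    Placements are memoised per distinct sequence, so duplicate reads cost a
    single lookup.
    """
    cache: Dict[str, List[GenomicInterval]] = {}
    hitsets: List[ReadHitSet] = []
    unaligned: List[ProcessedRead] = []
    for read in reads:
        hits = cache.get(read.sequence)
        if hits is None:
            hits = index.find_all(read.sequence)
            cache[read.sequence] = hits
        if hits:
            hitsets.append(ReadHitSet(read, hits))
        else:
            unaligned.append(read)
    return hitsets, unaligned


class AnnotationIndex:
    """Interval lookup of annotated features, per chromosome."""

    def __init__(self, features: Sequence[AnnotatedFeature]):
        self._trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
        for feat in features:
            iv = feat.interval
            self._trees[iv.chrom].addi(iv.start, iv.end, feat.feature_class)

    def classes_overlapping(self, interval: GenomicInterval, min_bases: int) -> set:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return set()
        out = set()
        for hit in tree.overlap(interval.start, interval.end):
            if min(hit.end, interval.end) - max(hit.begin, interval.start) >= min_bases:
                out.add(hit.data)
        return out


def _region_trees(regions: Sequence[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for region in regions:
        trees[region.chrom].addi(region.start, region.end)
    return dict(trees)


def classify_hitset(hitset: ReadHitSet, annotations: AnnotationIndex,
                    mito_name: Optional[str],
                    unpaired_regions: Sequence[GenomicInterval] = (),
                    min_overlap_frac: float = 0.5,
                    _unpaired_trees: Optional[dict] = None) -> str:
    """Class label for one read: highest-precedence class over ALL hits.

    A hit counts toward a feature class (or an unpaired region, giving
    masiRNA) when the overlap covers at least ``min_overlap_frac`` of the
    read's aligned length; a hit on the mitochondrial chromosome gives
    'mito'; anything else is 'other'.
    """
    trees = _unpaired_trees if _unpaired_trees is not None else _region_trees(unpaired_regions)
    min_bases = int(np.ceil(min_overlap_frac * hitset.read.length))
    best = _RANK["other"]
    for hit in hitset.hits:
        for cls in annotations.classes_overlapping(hit, min_bases):
            best = min(best, _RANK[cls])
        tree = trees.get(hit.chrom)
        if tree is not None:
            for node in tree.overlap(hit.start, hit.end):
                if min(node.end, hit.end) - max(node.begin, hit.start) >= min_bases:
                    best = min(best, _RANK["masiRNA"])
        if mito_name is not None and hit.chrom == mito_name:
            best = min(best, _RANK["mito"])
    return CLASS_PRECEDENCE[best]


def classify_library(hitsets: Sequence[ReadHitSet], annotations: AnnotationIndex,
                     mito_name: Optional[str],
                     unpaired_regions: Sequence[GenomicInterval] = (),
                     min_overlap_frac: float = 0.5) -> List[str]:
    trees = _region_trees(unpaired_regions)
    return [
        classify_hitset(hs, annotations, mito_name, min_overlap_frac=min_overlap_frac,
                        _unpaired_trees=trees)
        for hs in hitsets
    ]


@dataclass
class ClassProfile:
    """Per-class counts and read-feature profiles for one library."""

    counts: Dict[str, int]
    n_total: int          # filtered reads (aligned + unaligned)
    n_aligned: int
    n_unaligned: int
    length_hist: Dict[str, Counter]       # class -> Counter(length)
    five_prime: Dict[str, Counter]        # class -> Counter(5' base, sequenced orientation)
    region_plus_fraction: Dict[str, float] = field(default_factory=dict)

    @property
    def fractions(self) -> Dict[str, float]:
        """Class fractions over classified (aligned) reads."""
        total = sum(self.counts.values())
        if total == 0:
            return {c: 0.0 for c in self.counts}
        return {c: n / total for c, n in self.counts.items()}

    @property
    def fractions_of_total(self) -> Dict[str, float]:
        """Class fractions over all filtered reads (alternate denominator)."""
        if self.n_total == 0:
            return {c: 0.0 for c in self.counts}
        return {c: n / self.n_total for c, n in self.counts.items()}


def profile_library(hitsets: Sequence[ReadHitSet], labels: Sequence[str],
                    unaligned: Sequence[ProcessedRead] = (),
                    regions: Sequence[GenomicInterval] = ()) -> ClassProfile:
    """Aggregate class counts, length histograms, 5'-base frequencies and,
    for each requested region, the multi-map-weighted plus-strand fraction.
    """
    if len(hitsets) != len(labels):
        raise ParameterError("hitsets and labels differ in length")
    counts: Dict[str, int] = {c: 0 for c in CLASS_PRECEDENCE}
    length_hist: Dict[str, Counter] = defaultdict(Counter)
    five_prime: Dict[str, Counter] = defaultdict(Counter)
    for hs, label in zip(hitsets, labels):
        counts[label] += 1
        length_hist[label][hs.read.length] += 1
        five_prime[label][hs.read.sequence[0]] += 1

    region_plus: Dict[str, float] = {}
    for region in regions:
        plus = total = 0.0
        for hs in hitsets:
            w = hs.weight
            for hit in hs.hits:
                if hit.chrom == region.chrom and region.start <= hit.midpoint < region.end:
                    total += w
                    if hit.strand == "+":
                        plus += w
        region_plus[str(region)] = plus / total if total > 0 else float("nan")

    return ClassProfile(
        counts=counts,
        n_total=len(hitsets) + len(unaligned),
        n_aligned=len(hitsets),
        n_unaligned=len(unaligned),
        length_hist=dict(length_hist),
        five_prime=dict(five_prime),
        region_plus_fraction=region_plus,
    )


def region_density(hitsets: Sequence[ReadHitSet], region: GenomicInterval,
                   library_size: int) -> Tuple[float, float]:
    """Weighted small-RNA density of a region.

    A hit contributes its multi-mapping weight when its midpoint lies inside
    the region.  Returns ``(reads_per_bp, rpkm)`` where rpkm is reads per kb
    of region per million library reads, for cross-library comparison.
    """
    if region.length <= 0:
        raise ParameterError("zero-length region")
    weight = 0.0
    for hs in hitsets:
        w = hs.weight
        for hit in hs.hits:
            if hit.chrom == region.chrom and region.start <= hit.midpoint < region.end:
                weight += w
    reads_per_bp = weight / region.length
    rpkm = (weight / (region.length / 1000.0)) / (library_size / 1e6) if library_size else float("nan")
    return reads_per_bp, rpkm
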