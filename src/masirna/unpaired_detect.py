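"""Presence/absence variant detection from partner read coverage.

Reads of the non-carrier parent are aligned to the carrier reference; a
region present only in the carrier receives (nearly) no partner coverage
and is called as a candidate unpaired loop.  Seeding works on fixed windows
of mean depth relative to the genome-wide median; boundaries are then
refined to the outermost zero-depth base, since downstream TIR/TSD calling
needs near-base precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .exceptions import ParameterError
from .io_formats import Genome, GenomicInterval
from .srna_pipeline import ReadHitSet


@dataclass
class CoverageTrack:
    """Per-base and per-window weighted read depth over a genome."""

    window_size: int
    per_base: Dict[str, np.ndarray]       # chrom -> float depth per base
    windows: Dict[str, np.ndarray]        # chrom -> mean depth per window
    median_depth: float                   # genome-wide median of window depths

    def window_starts(self, chrom: str) -> np.ndarray:
        return np.arange(len(self.windows[chrom])) * self.window_size


@dataclass
class UnpairedRegion:
    """An interval absent from the partner genome."""

    interval: GenomicInterval
    mean_depth_inside: float
    flank_mean_depth: float

    @property
    def length(self) -> int:
        return self.interval.length


def coverage_track(hitsets: Sequence[ReadHitSet], genome: Genome,
                   window_size: int = 100) -> CoverageTrack:
    """Accumulate multi-map-weighted depth; deterministic given its inputs.

    Each placement of a read adds the read's weight to every base it
    covers; window depth is the mean per-base depth of the window (the last
    window of a chromosome may be shorter).
    """
    if window_size < 1:
        raise ParameterError("window_size must be >= 1")
    per_base = {chrom: np.zeros(length, dtype=np.float64)
                for chrom, length in genome.chrom_lengths.items()}
    for hs in hitsets:
        w = hs.weight
        for hit in hs.hits:
            per_base[hit.chrom][hit.start:hit.end] += w
    windows = {}
    all_windows = []
    for chrom, depth in per_base.items():
        n_win = int(np.ceil(len(depth) / window_size))
        sums = np.add.reduceat(depth, np.arange(0, len(depth), window_size))
        lengths = np.full(n_win, window_size, dtype=np.float64)
        if len(depth) % window_size:
            lengths[-1] = len(depth) % window_size
        windows[chrom] = sums / lengths
        all_windows.append(windows[chrom])
    median = float(np.median(np.concatenate(all_windows)))
    return CoverageTrack(window_size=window_size, per_base=per_base,
                         windows=windows, median_depth=median)


def call_absent_regions(track: CoverageTrack, absence_fraction: float = 0.05,
                        min_len: int = 200, merge_gap: int = 200) -> List[UnpairedRegion]:
    """Call regions with (near-)zero partner depth.

    Windows with depth <= ``absence_fraction`` x genome-wide median seed a
    region; seeds within ``merge_gap`` bp are merged; boundaries are refined
    to the outermost zero-depth base inside the (window-padded) seed span.
    Merged spans without any zero-depth base, or shorter than ``min_len``
    after refinement, are dropped.
    """
    if track.median_depth <= 0:
        raise ParameterError("no partner coverage (genome-wide median depth is zero)")
    threshold = absence_fraction * track.median_depth
    regions: List[UnpairedRegion] = []
    for chrom, win_depth in track.windows.items():
        depth = track.per_base[chrom]
        seeds = np.flatnonzero(win_depth <= threshold)
        if seeds.size == 0:
            continue
        # merge seed windows whose gap is <= merge_gap bp
        ws = track.window_size
        spans = []
        run_start = prev = seeds[0]
        for s in seeds[1:]:
            if (s - prev - 1) * ws <= merge_gap:
                prev = s
            else:
                spans.append((run_start, prev))
                run_start = prev = s
        spans.append((run_start, prev))
        for w0, w1 in spans:
            lo = max(0, w0 * ws - ws)
            hi = min(len(depth), (w1 + 1) * ws + ws)
            zero = np.flatnonzero(depth[lo:hi] == 0)
            if zero.size == 0:
                continue
            start = int(lo) + int(zero[0])
            end = int(lo) + int(zero[-1]) + 1
            if end - start < min_len:
                continue
            inside = float(depth[start:end].mean())
            flank_lo = depth[max(0, start - 1000):start]
            flank_hi = depth[end:end + 1000]
            flank = np.concatenate([flank_lo, flank_hi])
            regions.append(UnpairedRegion(
                interval=GenomicInterval(chrom, start, end),
                mean_depth_inside=inside,
                flank_mean_depth=float(flank.mean()) if flank.size else float("nan"),
            ))
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return regions
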