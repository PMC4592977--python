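"""Four-criterion filter calling masiRNA-producing loci.

A candidate locus must be (1) unique to the carrier parent (inherited from
unpaired-region detection), (2) longer than 700 bp — the minimum size
reported to trigger meiotic silencing efficiently, (3) small-RNA enriched
only at the late time point, and (4) produce more small-RNA reads than its
length in bp (weighted reads/bp > 1).

Criteria 3 and 4 are stated qualitatively in the source workflow; here they
are operationalised as a fold-change test with a pseudocount and as a
strict weighted reads-per-bp threshold, both configurable.  All four
verdicts are reported per region so near-misses can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .exceptions import ParameterError
from .io_formats import GenomicInterval, to_report_coords
from .srna_pipeline import ReadHitSet, region_density
from .unpaired_detect import UnpairedRegion

TIMEPOINTS = ("PP", "2dPF", "4dPF")


@dataclass
class CandidateParams:
    min_size: int = 700            # bp, strict
    fold: float = 5.0              # late/early enrichment fold
    pseudo: float = 1e-4           # reads/bp pseudocount (0.1 reads per kb)
    min_ratio: float = 1.0         # reads/bp, strict

    def validate(self) -> None:
        if self.fold <= 1:
            raise ParameterError("fold must be > 1")
        if self.min_size < 0 or self.pseudo < 0:
            raise ParameterError("min_size and pseudo must be >= 0")


@dataclass
class CandidateVerdict:
    region: UnpairedRegion
    density_PP: float
    density_2d: float
    density_4d: float
    rpkm_4d: float
    c1_unique: bool
    c2_size: bool
    c3_late_only: bool
    c4_ratio: bool

    @property
    def pass_all(self) -> bool:
        return self.c1_unique and self.c2_size and self.c3_late_only and self.c4_ratio


def criterion_size(region: UnpairedRegion, min_size: int = 700) -> bool:
    """Strictly larger than ``min_size`` bp."""
    return region.length > min_size


def criterion_late_enrichment(d_pp: float, d_2d: float, d_4d: float,
                              fold: float = 5.0, pseudo: float = 1e-4) -> bool:
    """True when the late density exceeds ``fold`` x the larger early density
    (pseudocount added on both sides)."""
    if fold <= 1:
        raise ParameterError("fold must be > 1")
    if min(d_pp, d_2d, d_4d) < 0:
        raise ParameterError("densities must be >= 0")
    return (d_4d + pseudo) >= fold * (max(d_pp, d_2d) + pseudo)


def criterion_ratio(masirna_read_count_4d: float, region_length: int,
                    min_ratio: float = 1.0) -> bool:
    """Strictly more than ``min_ratio`` weighted reads per bp of region."""
    if region_length <= 0:
        raise ParameterError("region_length must be > 0")
    return masirna_read_count_4d / region_length > min_ratio


def call_candidates(unpaired_regions: Sequence[UnpairedRegion],
                    hitsets_by_timepoint: Dict[str, Sequence[ReadHitSet]],
                    library_sizes: Dict[str, int],
                    params: CandidateParams = CandidateParams(),
                    ) -> Tuple[List[CandidateVerdict], dict]:
    """Evaluate all four criteria for every unpaired region.

    ``hitsets_by_timepoint`` must provide all three time points, processed
    with identical settings.  Returns one verdict per region plus a summary
    with per-criterion pass counts and the size-class tally of passing
    regions (<5 kb, 5-10 kb, >10 kb).
    """
    params.validate()
    for tp in TIMEPOINTS:
        if tp not in hitsets_by_timepoint:
            raise ParameterError(f"missing time point {tp!r}")
        if tp not in library_sizes:
            raise ParameterError(f"missing library size for {tp!r}")

    verdicts: List[CandidateVerdict] = []
    for region in unpaired_regions:
        dens = {}
        rpkm = {}
        for tp in TIMEPOINTS:
            d, r = region_density(hitsets_by_timepoint[tp], region.interval,
                                  library_sizes[tp])
            dens[tp], rpkm[tp] = d, r
        verdicts.append(CandidateVerdict(
            region=region,
            density_PP=dens["PP"], density_2d=dens["2dPF"], density_4d=dens["4dPF"],
            rpkm_4d=rpkm["4dPF"],
            c1_unique=True,  # inherited: every input region is partner-absent
            c2_size=criterion_size(region, params.min_size),
            c3_late_only=criterion_late_enrichment(
                dens["PP"], dens["2dPF"], dens["4dPF"], params.fold, params.pseudo),
            c4_ratio=criterion_ratio(dens["4dPF"] * region.length, region.length,
                                     params.min_ratio),
        ))

    passing = [v for v in verdicts if v.pass_all]
    size_classes = {
        "lt_5kb": sum(1 for v in passing if v.region.length < 5000),
        "5_to_10kb": sum(1 for v in passing if 5000 <= v.region.length <= 10000),
        "gt_10kb": sum(1 for v in passing if v.region.length > 10000),
    }
    summary = {
        "n_regions": len(verdicts),
        "n_pass_c1": int(sum(bool(v.c1_unique) for v in verdicts)),
        "n_pass_c2": int(sum(bool(v.c2_size) for v in verdicts)),
        "n_pass_c3": int(sum(bool(v.c3_late_only) for v in verdicts)),
        "n_pass_c4": int(sum(bool(v.c4_ratio) for v in verdicts)),
        "n_pass_all": len(passing),
        "size_classes_passing": size_classes,
        "params": {"min_size": params.min_size, "fold": params.fold,
                   "pseudo": params.pseudo, "min_ratio": params.min_ratio},
    }
    return verdicts, summary


def write_candidates_tsv(verdicts: Sequence[CandidateVerdict], handle) -> None:
    handle.write("chrom\tstart_1based\tend_1based\tlength\tdensity_PP\tdensity_2dPF\t"
                 "density_4dPF\trpkm_4dPF\tc1_unique\tc2_size\tc3_late_only\tc4_ratio\tpass_all\n")
    for v in verdicts:
        s1, e1, length = to_report_coords(v.region.interval)
        handle.write(
            f"{v.region.interval.chrom}\t{s1}\t{e1}\t{length}\t"
            f"{v.density_PP:.6g}\t{v.density_2d:.6g}\t{v.density_4d:.6g}\t{v.rpkm_4d:.6g}\t"
            f"{int(v.c1_unique)}\t{int(v.c2_size)}\t{int(v.c3_late_only)}\t"
            f"{int(v.c4_ratio)}\t{int(v.pass_all)}\n"
        )


def write_summary_json(summary: dict, handle) -> None:
    json.dump(summary, handle, indent=1, sort_keys=True)
    handle.write("\n")
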