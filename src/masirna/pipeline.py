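"""End-to-end orchestration: align/classify -> detect -> filter -> annotate.

``run_pipeline`` does the whole analysis in memory on parsed inputs and
returns a :class:`RunResult`; the ``stage_*`` helpers are thin file-based
wrappers used by the command-line interface so that every stage can be
re-run independently from its intermediate files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import __version__ as _version
from .exceptions import ParameterError, StageError
from .io_formats import (
    AnnotatedFeature,
    Genome,
    GenomicInterval,
    parse_fasta,
    parse_fastq,
    read_annotations_bed,
    read_annotations_gff3,
    read_bed,
    to_report_coords,
    write_bed,
)
from .masirna_candidates import (
    CandidateParams,
    CandidateVerdict,
    call_candidates,
    write_candidates_tsv,
    write_summary_json,
)
from .srna_pipeline import (
    AnnotationIndex,
    ExactIndex,
    ProcessedRead,
    ReadHitSet,
    align_reads,
    classify_library,
    length_filter,
    profile_library,
    region_density,
    trim_adapter,
)
from .te_annotator import (
    TECall,
    annotate_element,
    cri_track,
    write_cri_track_tsv,
    write_ripcal_tsv,
)
from .unpaired_detect import CoverageTrack, UnpairedRegion, call_absent_regions, coverage_track

TIMEPOINTS = ("PP", "2dPF", "4dPF")


@dataclass
class PipelineParams:
    """All tunable stage parameters with their declared defaults."""

    # small-RNA processing
    adapter: Optional[str] = None      # adapter trimming disabled unless set
    adapter_min_overlap: int = 6
    min_len: int = 18                  # inclusive length bounds
    max_len: int = 29
    index_k: int = 12
    min_overlap_frac: float = 0.5      # feature-overlap rule for classification
    # unpaired-region detection
    window_size: int = 100
    absence_fraction: float = 0.05
    min_region_len: int = 200
    merge_gap: int = 200
    # candidate filtering
    candidate: CandidateParams = field(default_factory=CandidateParams)
    # element annotation
    tir_min_len: int = 10
    tir_max_mismatch: int = 0
    tir_flank: int = 3000
    max_tsd_len: int = 10
    copy_flank: int = 2000
    cri_window: int = 500
    cri_step: int = 100

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ParameterError("min_len > max_len")
        if self.index_k > self.min_len:
            raise ParameterError("index_k larger than min read length")
        if self.min_len < 1 or self.window_size < 1:
            raise ParameterError("min_len and window_size must be >= 1")
        if not self.cri_window >= self.cri_step >= 1:
            raise ParameterError("need cri_window >= cri_step >= 1")
        if not 0 <= self.absence_fraction < 1:
            raise ParameterError("absence_fraction must be in [0, 1)")
        self.candidate.validate()


@dataclass
class LibraryResult:
    """Processed state of one small-RNA library."""

    timepoint: str
    filter_stats: Dict[str, int]
    hitsets: List[ReadHitSet]
    unaligned: List[ProcessedRead]
    labels: List[str]
    profile: object  # ClassProfile

    @property
    def library_size(self) -> int:
        return self.filter_stats["kept"]


@dataclass
class RunResult:
    regions: List[UnpairedRegion]
    verdicts: List[CandidateVerdict]
    summary: dict
    libraries: Dict[str, LibraryResult]
    te_calls: List[TECall]
    partner_track: CoverageTrack
    carrier_track: Optional[CoverageTrack]
    rip_track: object
    accounting: Dict[str, dict]


def _align_wgs(reads, index: ExactIndex):
    processed = [ProcessedRead(r[0], r[1]) for r in reads]
    return align_reads(processed, index)


def process_srna_library(records, index: ExactIndex, annotations: AnnotationIndex,
                         mito_name: Optional[str],
                         regions: Sequence[GenomicInterval],
                         params: PipelineParams, timepoint: str) -> LibraryResult:
    """Trim, length-filter, align, classify and profile one library."""
    if params.adapter:
        records = [(r[0], trim_adapter(r[1], params.adapter, params.adapter_min_overlap))
                   for r in records]
    reads, stats = length_filter(records, params.min_len, params.max_len)
    hitsets, unaligned = align_reads(reads, index)
    labels = classify_library(hitsets, annotations, mito_name, regions,
                              params.min_overlap_frac)
    profile = profile_library(hitsets, labels, unaligned, regions)
    return LibraryResult(timepoint=timepoint, filter_stats=stats, hitsets=hitsets,
                         unaligned=unaligned, labels=labels, profile=profile)


def run_pipeline(reference: Genome, annotations: Sequence[AnnotatedFeature],
                 srna_records: Dict[str, list], wgs_records: list,
                 params: Optional[PipelineParams] = None,
                 carrier_wgs_records: Optional[list] = None,
                 empty_genome: Optional[Genome] = None) -> RunResult:
    """Run detection, classification, filtering and annotation in memory.

    ``srna_records`` maps each of the three time points to FASTQ records of
    that library; ``wgs_records`` are the non-carrier partner's genomic
    reads.  ``carrier_wgs_records`` (optional) enable the copy-number
    estimate; ``empty_genome`` (optional) sharpens the TSD junction test.
    """
    params = params or PipelineParams()
    params.validate()
    for tp in TIMEPOINTS:
        if tp not in srna_records:
            raise ParameterError(f"missing small-RNA library for time point {tp!r}")

    index = ExactIndex(reference, params.index_k)
    accounting: Dict[str, dict] = {}

    # --- partner coverage and unpaired regions
    wgs_hitsets, wgs_unaligned = _align_wgs(wgs_records, index)
    partner_track = coverage_track(wgs_hitsets, reference, params.window_size)
    regions = call_absent_regions(partner_track, params.absence_fraction,
                                  params.min_region_len, params.merge_gap)
    accounting["wgs"] = {"input": len(wgs_records), "aligned": len(wgs_hitsets),
                         "unaligned": len(wgs_unaligned)}

    # --- small-RNA libraries
    ann_index = AnnotationIndex(annotations)
    region_intervals = [r.interval for r in regions]
    libraries: Dict[str, LibraryResult] = {}
    for tp in TIMEPOINTS:
        lib = process_srna_library(srna_records[tp], index, ann_index,
                                   reference.mito_name, region_intervals, params, tp)
        libraries[tp] = lib
        accounting[f"srna_{tp}"] = {
            **lib.filter_stats,
            "aligned": len(lib.hitsets),
            "unaligned": len(lib.unaligned),
            "classified": sum(lib.profile.counts.values()),
        }

    # --- four-criterion candidate filter
    verdicts, summary = call_candidates(
        regions,
        {tp: libraries[tp].hitsets for tp in TIMEPOINTS},
        {tp: libraries[tp].library_size for tp in TIMEPOINTS},
        params.candidate,
    )

    # --- per-locus element annotation for passing candidates
    carrier_track = None
    if carrier_wgs_records is not None:
        carrier_hitsets, _carrier_unaligned = _align_wgs(carrier_wgs_records, index)
        carrier_track = coverage_track(carrier_hitsets, reference, params.window_size)
    te_calls: List[TECall] = []
    for verdict in verdicts:
        if not verdict.pass_all:
            continue
        iv = verdict.region.interval
        empty_seq = empty_genome[iv.chrom] if empty_genome and iv.chrom in empty_genome else None
        te_calls.append(annotate_element(
            reference, partner_track, wgs_unaligned, iv,
            carrier_track=carrier_track, empty_sequence=empty_seq, index=index,
            tir_min_len=params.tir_min_len, tir_max_mismatch=params.tir_max_mismatch,
            tir_flank=params.tir_flank, max_tsd_len=params.max_tsd_len,
            copy_flank=params.copy_flank))

    rip = cri_track(reference, params.cri_window, params.cri_step)
    return RunResult(regions=regions, verdicts=verdicts, summary=summary,
                     libraries=libraries, te_calls=te_calls,
                     partner_track=partner_track, carrier_track=carrier_track,
                     rip_track=rip, accounting=accounting)


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------


def write_coverage_tsv(track: CoverageTrack, handle) -> None:
    handle.write("chrom\twindow_start_1based\tdepth\n")
    for chrom in sorted(track.windows):
        for start, depth in zip(track.window_starts(chrom), track.windows[chrom]):
            handle.write(f"{chrom}\t{start + 1}\t{depth:.4f}\n")


def write_regions_bed(regions: Sequence[UnpairedRegion], handle) -> None:
    write_bed(
        ((r.interval, f"unpaired_{i}", f"{r.mean_depth_inside:.3f}")
         for i, r in enumerate(regions)),
        handle,
    )


def write_class_profile_tsv(libraries: Dict[str, LibraryResult], handle) -> None:
    handle.write("timepoint\tclass\tcount\tfraction_of_classified\tfraction_of_filtered\n")
    for tp in TIMEPOINTS:
        prof = libraries[tp].profile
        fr, frt = prof.fractions, prof.fractions_of_total
        for cls, count in prof.counts.items():
            handle.write(f"{tp}\t{cls}\t{count}\t{fr[cls]:.6g}\t{frt[cls]:.6g}\n")


def write_length_hist_tsv(libraries: Dict[str, LibraryResult], handle) -> None:
    handle.write("timepoint\tclass\tlength\tcount\n")
    for tp in TIMEPOINTS:
        for cls, hist in sorted(libraries[tp].profile.length_hist.items()):
            for length in sorted(hist):
                handle.write(f"{tp}\t{cls}\t{length}\t{hist[length]}\n")


def write_five_prime_tsv(libraries: Dict[str, LibraryResult], handle) -> None:
    handle.write("timepoint\tclass\tbase\tcount\n")
    for tp in TIMEPOINTS:
        for cls, bases in sorted(libraries[tp].profile.five_prime.items()):
            for base in sorted(bases):
                handle.write(f"{tp}\t{cls}\t{base}\t{bases[base]}\n")


def write_classified_reads_tsv(lib: LibraryResult, handle) -> None:
    handle.write("read_id\tclass\tn_hits\n")
    for hs, label in zip(lib.hitsets, lib.labels):
        handle.write(f"{hs.read.id}\t{label}\t{len(hs.hits)}\n")
    for read in lib.unaligned:
        handle.write(f"{read.id}\tunaligned\t0\n")


def write_density_bed(regions: Sequence[UnpairedRegion],
                      libraries: Dict[str, LibraryResult], handle) -> None:
    entries = []
    for i, region in enumerate(regions):
        for tp in TIMEPOINTS:
            d, _ = region_density(libraries[tp].hitsets, region.interval,
                                  max(libraries[tp].library_size, 1))
            entries.append((region.interval, f"unpaired_{i}:{tp}", f"{d:.6g}"))
    write_bed(entries, handle)


def write_reports(result: RunResult, outdir, seed: Optional[int] = None,
                  params: Optional[PipelineParams] = None) -> Dict[str, Path]:
    """Write the full report bundle for a pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name, writer):
        path = outdir / name
        with open(path, "w") as fh:
            writer(fh)
        paths[name] = path

    _write("coverage.tsv", lambda fh: write_coverage_tsv(result.partner_track, fh))
    _write("unpaired_regions.bed", lambda fh: write_regions_bed(result.regions, fh))
    _write("class_profile.tsv", lambda fh: write_class_profile_tsv(result.libraries, fh))
    _write("length_hist.tsv", lambda fh: write_length_hist_tsv(result.libraries, fh))
    _write("five_prime.tsv", lambda fh: write_five_prime_tsv(result.libraries, fh))
    for tp in TIMEPOINTS:
        _write(f"classified_reads_{tp}.tsv",
               lambda fh, tp=tp: write_classified_reads_tsv(result.libraries[tp], fh))
    _write("density.bed", lambda fh: write_density_bed(result.regions, result.libraries, fh))
    _write("candidates.tsv", lambda fh: write_candidates_tsv(result.verdicts, fh))
    _write("summary.json", lambda fh: write_summary_json(result.summary, fh))
    _write("te_call.json", lambda fh: fh.write(
        json.dumps([c.to_dict() for c in result.te_calls], indent=1, sort_keys=True) + "\n"))
    _write("cri_track.tsv", lambda fh: write_cri_track_tsv(result.rip_track, fh))
    ripcal_rows = [row for call in result.te_calls for row in call.ripcal]
    _write("ripcal.tsv", lambda fh: write_ripcal_tsv(ripcal_rows, fh))
    log = {
        "package": "masirna",
        "version": _version,
        "seed": seed,
        "parameters": asdict(params) if params is not None else None,
        "accounting": result.accounting,
        "n_unpaired_regions": len(result.regions),
        "n_pass_all": result.summary["n_pass_all"],
    }
    _write("run_log.json", lambda fh: fh.write(json.dumps(log, indent=1, sort_keys=True) + "\n"))
    return paths


# ---------------------------------------------------------------------------
# file-based stage helpers (used by the CLI)
# ---------------------------------------------------------------------------


def load_annotations(path) -> list:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".gff", ".gff3"):
            return read_annotations_gff3(fh)
        return read_annotations_bed(fh)


def load_reference(path, mito_name: Optional[str] = None) -> Genome:
    with open(path) as fh:
        return parse_fasta(fh, mito_name=mito_name)


def load_fastq(path) -> list:
    with open(path) as fh:
        return parse_fastq(fh)


def load_regions_bed(path) -> List[UnpairedRegion]:
    with open(path) as fh:
        entries = read_bed(fh)
    return [UnpairedRegion(interval=iv, mean_depth_inside=float("nan"),
                           flank_mean_depth=float("nan"))
            for iv, _name in entries]
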