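# Methods

This note documents the models and procedures implemented in `masirna`,
the defaults that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
show about real data.

## Coordinates and formats

Internally every interval is 0-based half-open; every report emits 1-based
inclusive coordinates (`to_report_coords`), the convention of genome
browsers and of published locus descriptions, where an interval printed as
`s–e` has length `e − s + 1`.  BED (0-based half-open) is the interchange
format for regions; GFF3 is accepted read-only for annotations.  Genomes
are uppercase DNA over `{A,C,G,T,N}`; uracil is represented as T
throughout, so the "5′ uridine" bias of small RNAs is assessed as 5′ T in
DNA space.

## Small-RNA processing

Adapter trimming removes everything from the first occurrence of the full
adapter, or else the longest read suffix that is a prefix of the adapter
(≥ `min_overlap`, default 6).  The length filter keeps reads of 18–29 nt
inclusive — the bounds are configurable because "longer than 17 and
smaller than 30" is read literally.

Alignment is exact (zero mismatches) against both strands, reporting
*every* placement.  A k-mer hash (k = 12 by default; k must not exceed the
minimum read length) anchors the query's first k bases and each candidate
is verified by direct string comparison, so results are provably complete
for any query; a read containing N can never align.  This deliberately
reproduces a "no mismatches, multiple matches allowed" short-read
configuration; there is no seed-and-extend approximation to document.

Classification assigns each read one label by a fixed precedence over all
of its placements: rRNA > tRNA > snoRNA > milRNA > disiRNA > masiRNA
(placement covering ≥ 50% of the read inside an unpaired region) >
mitochondrial (placement on the designated mitochondrial chromosome) >
other.  Structural RNAs take precedence so that their enormous read mass
is never absorbed by a broad unpaired region that happens to overlap them.
The 50% overlap rule is a declared default (a majority-overlap rule;
configurable), not an inherited constant.  Class fractions are reported
over classified reads and, as an alternative denominator, over all
filtered reads.  Densities weight each placement by 1/(number of
placements) and count a placement when its midpoint lies in the region;
weights sum to one per aligned read, so class counts + unaligned reads
equal the filtered total exactly — an invariant the tests assert.

## Unpaired-region detection

Partner reads aligned to the carrier reference produce a per-base,
multi-map-weighted depth track.  Windows (100 bp) with mean depth at or
below `absence_fraction` (0.05) of the genome-wide median seed a region —
not strict zero, because diverged paralogs can drip spurious multi-mapped
weight into a truly absent element.  Seeds within 200 bp merge; boundaries
are then refined to the outermost zero-depth base, and regions shorter
than 200 bp, or without any zero-depth base, are dropped.  Detection
thresholds are deliberately separate from the biological 700-bp rule,
which is applied downstream by the candidate filter, so the two concerns
can be audited independently.

## The four-criterion filter

For each partner-absent region and the three time-point libraries
(PP, 2dPF, 4dPF):

1. **unique** — inherited from detection: every input region is
   partner-absent by construction;
2. **size** — length strictly greater than 700 bp, the minimum unpaired
   size reported to trigger meiotic silencing efficiently;
3. **late-only enrichment** — `(d_4d + ε) ≥ fold · (max(d_PP, d_2d) + ε)`
   with fold = 5 and pseudocount ε = 0.1 reads/kb.  "Enriched only at the
   late time point" is qualitative in the source workflow; a fold-change
   with pseudocount is the simplest monotone operationalisation, and 5 is
   permissive given that observed class fractions rise about tenfold;
4. **production/size ratio** — weighted reads per bp of region strictly
   greater than 1.  The source ratio's units are not stated anywhere;
   reads/bp is dimensionally coherent and reproduces its intent (high
   small-RNA output per unit length).  It is a declared interpretation,
   configurable, and must not be read as the original definition.

All four booleans are evaluated independently and reported for every
region so near-misses can be audited; the summary tallies per-criterion
passes and the <5 kb / 5–10 kb / >10 kb size classes of passing regions.

## Element annotation

**Breakpoints.** The locus must contain exactly one partner-coverage gap
(≥ 100 bp below the absence threshold; covered islands shorter than 250 bp
— bounded by the read length and by the length of conserved stretches in
RIP-diverged paralogs — are absorbed).  Gap edges are then refined with
split-read evidence: unaligned partner reads are anchored by their
terminal k-mers and extended; the modal maximal-prefix end is the left
breakpoint, the modal maximal-suffix start the right one.  Because the
junction sequence is the same for every spanning read, the mode is sharp
and recovery is exact at 20X in the validation; split reads are how
breakpoints are called at base resolution when alignment is exact and
cannot soft-clip.

**TIRs.** `find_tirs` is an exhaustive search for the best inverted-repeat
pair `(i, j, L)`: `seq[i:i+L]` reverse-complements `seq[j:j+L]` with at
most `max_mismatch` positions differing, arms non-overlapping, scored by
length, then fewer mismatches, then leftmost `i`, then smallest `j` (a
deterministic tie-break).  A pair occupies the anti-diagonal
`D = i + j + L − 1`, on which position `x` pairs with `D − x`; each
anti-diagonal therefore reduces to the longest run with a bounded number
of failures, making the enumeration exhaustive without cubic cost.  The
tests pin it against a definitional triple-loop oracle and, on 2-kb
windows, against a substring-dictionary oracle.  The search window is the
element ± 3 kb of flanking DNA.  Note that with a nonzero mismatch budget
the longest-first scoring always spends the budget extending a perfect
repeat outward, so the default budget is 0; budgets > 0 are for genuinely
degenerate TIRs.

**TSD.** The longest k ≤ 10 such that the k bases left of the element
equal the k bases right of it, allowing only RIP-type one-sided
substitutions (C→T or G→A in either copy — the mutation class that
explains a TSD pair differing at a cytosine), *and* such that the partner
haplotype carries the corresponding junction exactly once.  When no
partner assembly is available the junction is reconstructed by excising
the element from the reference, and the test reduces to a uniqueness
check (stated in the call's diagnostics).

**Composite RIP index.** Per window,
`CRI = TpA/ApT − (CpA+TpG)/(ApC+GpT)` from overlapping dinucleotides on
the given strand only (reverse-strand RIP events appear in the TpG/GpT
terms); a window with ApT = 0 or ApC+GpT = 0 is flagged undefined.
Positive CRI indicates RIP-mutated DNA.  Sliding windows default to
500/100 bp (window/step; a declared default), with a trailing partial
window kept when at least half a window long.

**RIPCAL-style homolog classification.** Homolog copies are located by
exact k-mer diagonal voting (suited to RIP-diverged, substitution-only
copies; it will not find indel-containing homologs), then compared
gaplessly against the element as the reference row: C→T and G→A
differences are counted by reference-strand dinucleotide context (CpA for
C→T, TpG for G→A, otherwise "other").  Reference-row mode is implemented
and labelled as such.  On the generator's gapless paralogs these counts
equal the applied mutation counts exactly.

**Copy number.** Mean depth of the element over mean flank depth
(2 kb per flank) in the carrier's own reads, with `edge_trim` = 100 bp
excluded at each element end: exact alignment cannot soft-clip, so reads
spanning an unassembled extra copy's junctions are lost and depth ramps
down within one read length of the boundaries; trimming removes that bias.
The rounded ratio is the copy-number estimate.  At 20X the ratio has an
intrinsic sampling spread of roughly ±0.1 for a 2.5-kb element, which is
why the validation checks the rounded estimate per cross and the ratio
averaged across crosses.

## The synthetic cross

The generator *defines* the validation conditions; defaults:

| parameter | default | why |
|---|---|---|
| carrier chromosome | 100 kb + 8 kb mitochondrial contig | large enough for a realistic layout, small enough for desk-scale runs |
| background model | first-order Markov, GC 0.5, TpA odds 0.75, CpA/TpG odds 1.45 | fungal-like dinucleotide composition (TpA suppression is universal; CpA/TpG is the RIP substrate).  Under iid sequence the composite RIP index is symmetric around zero and its sign is uninformative; the negative baseline that RIP scans rely on is a property of real genome composition, which the generator must reproduce for the index to mean anything |
| element | 2,500-bp body + 30-bp TIRs, 3-bp TSD | mid-sized DNA transposon geometry |
| RIP paralogs | 2 copies, mutation fraction 0.5 at CpA/TpG sites | heavily RIP-mutated duplicates, present in both parents; 0.5 places their windows unambiguously on the positive side of the index, as real RIPed repeats are |
| decoy insertions | 600 bp and 2,000 bp, carrier-only, no small RNAs | exercise the size and late-enrichment criteria with true negatives |
| genomic reads | 20X, 100 bp, error-free, both parents | error-free because with zero-mismatch alignment sequencing errors are pure dropout — they would add noise without testing any computation |
| small-RNA libraries | ~45k background reads (length peak 20 nt, 5′-U 0.75) per time point; masiRNA 8,000 at 4dPF and 5% of that at PP/2dPF; masiRNA lengths 24/25/26 at 0.25/0.5/0.25, 5′-U 0.8, both strands | the study conditions: late-stage burst of 25-nt-mode, 5′-U-biased RNAs from the unpaired region, with small but nonzero early leakage so the late-only criterion is tested non-degenerately |

The 5′-U bias is realised by biased *sampling* of start positions whose
genomic 5′ base is T (with probability `fraction_5pU`, else a non-T
start), so the realised fraction matches the configured one exactly in
expectation while every read still aligns with zero mismatches.  masiRNA
per-locus abundance is uniform within the region — a modelling choice,
not an inherited claim.  The carrier's *physical* genome carries one extra
identical element copy absent from the reference, so carrier reads pile
onto the single reference copy and the depth ratio estimates copy number,
mirroring how an unassembled second copy manifests.

Planting adjusts up to three bases around the insertion site (and the
body's terminal bases) so that the planted TIR pair is the unique maximal
inverted repeat and the breakpoint/TSD decomposition is unambiguous.
Real insertions can sit in micro-homology that makes these annotations
genuinely non-unique; the generator avoids that so the truth record is
exact.  Seeds flow through `numpy` `SeedSequence` spawning: every output
is byte-identical for a fixed seed.

**What passing the validation does not show.**  Reads are error-free and
unpaired; there are no quality artefacts, PCR duplicates or insert-size
structure.  The background has no repeat families beyond the planted
paralogs, so the multi-mapping load is far below that of a real genome.
Real unpaired regions need not be transposons, and real TSDs/TIRs can be
ambiguous under micro-homology.  Recovery being exact here validates the
computations, not the difficulty of real data.

## Validation problem sizes

Oracle-equivalence suites run the exact aligner against a both-strand
scan on a 50-kb genome with 1,000 reads, the RIP-index window against a
naive dinucleotide counter on 1,000 sequences, and the TIR search against
brute force on windows up to 2 kb.  Parameter recovery runs 20 synthetic
crosses at the default conditions above (TSD length cycling 0–10) and
requires: exactly one passing locus per cross with reciprocal overlap
≥ 0.95 of the planted element (recall 1.0, zero false positives),
breakpoints within ±1 bp, TSD sequence and length exact, TIR coordinates
exact, per-cross rounded copy-number estimate exact and the mean depth
ratio within 15% of truth.  The acceptance script reruns the same
pipeline on a few seeds derived from its `--seed` argument; these problem
sizes are the package's chosen validation scale.

## Known limitations

* Exact alignment only; no quality-aware processing or inexact mapping.
* Homolog discovery is substitution-only (diagonal voting); indel-bearing
  homologs require an external aligner.
* Insertions present in the partner but absent from the reference are out
  of scope for detection, as are SNP/indel calling and assembly-assembly
  comparison.
* With a nonzero TIR mismatch budget, "longest first" scoring makes the
  search always consume the budget; treat budgets > 0 as exploratory.
* `run-all` operates on a simulated cross; real data flows through the
  individual stages, whose inputs are ordinary FASTA/FASTQ/BED/GFF3.
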