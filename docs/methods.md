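# Methods

This note documents the models, rules and numerical choices implemented in
`svtriage`, the assumptions behind the synthetic evidence generator, and the
design decisions taken where the design was genuinely open.

## Coordinates and containers

All coordinates are 0-based half-open internally; every user-facing writer
(variant TSV, VCF, IGV session) emits 1-based inclusive positions. Coverage
and mapping-quality signals are held as per-contig numpy arrays binned at
100 bp (`CoverageTrack`), readable from fixed-step wiggle or BigWig;
evidence records (`DiscordantPair`, `SplitRead`) are plain dataclasses
serialized to TSV, optionally bgzip-compressed and tabix-indexed through
pysam.

## Evidence extraction

**Insert-size cutoffs.** The discordant mapping-distance cutoffs are
estimated from normally oriented pairs in a configurable sample region
(default contig 1, positions 1,000,001–5,000,000, 1-based; at least 1000
pairs required). Iterating the sorted distances in descending order and
accumulating counts, the upper cutoff is the distance at which the
cumulative count per Mb of region first reaches 100 pairs; the lower cutoff
is obtained symmetrically in ascending order. When many pairs tie at one
distance the whole block is accumulated before the comparison, which
resolves ties toward the wider (more permissive) cutoff.

**Discordant pairs** are read pairs that are inter-chromosomal, mis-oriented,
or whose distance falls outside the cutoffs. Orientation labels follow
position order on the contig: `+-` inward (deletion signature — discordant
only by distance), `-+` everted (duplication), `++`/`--` same-strand
(inversion), `inter`. Duplicate-flagged reads are dropped, as are pairs
touching excluded regions (maximal intervals with depth > 300×, rebuilt from
the coverage track per sample). Whether extraction should also drop low-MQ
pairs is not settled; it is exposed as a configurable MQ floor defaulting
to 0 (no filtering).

**Split reads** come from primary alignments with an SA tag. A read is
discarded if it maps to a decoy contig (default NC_007605, hs37d5 —
configurable), has more than one clipped part, has alignment parts that
overlap on the same contig, or has more than one SA entry. The surviving
read contributes one record with primary and clipped intervals, clip side,
and an orientation label assigned with the same scheme as pairs.

Evidence may equally be loaded from pre-extracted TSV tables, so the
pipeline runs without an aligner; both paths produce identical record types.

## Depth-of-coverage model

The genome-average coverage is the median of per-autosome window means
(GRCh37 layout: the 10-Mb window 20,000,001–30,000,000 of each autosome,
clear of centromeres and telomeres; toy layouts define their own windows).
X uses the whole chromosome and Y its two large unique regions
(GRCh37: 6,641,419–10,079,253 and 13,800,704–23,668,908); both
sex-chromosome coverages are rounded in fractions of 0.5 of the autosomal
value (half away from zero at exact quarters), making the estimate robust to
large CNVs and giving a haploid X a DRA near 1 because the rounded baseline
enters the DRA denominator. A copy-number point estimate round(DRA ×
ploidy) is reported alongside the genotype for aneuploidy reporting.

DOC within a variant is the base-weighted mean over bins with mean mapping
quality ≥ 50, unless bins covering less than one third of the variant length
qualify, in which case all bins are used and the restriction is recorded as
not applied. DRA divides DOC by the chromosome-appropriate baseline; DRF
divides by the mean of the two flanks of the same length as the variant. At
contig edges the single available flank is used; with no flank DRF is
undefined and the CNV flag falls back to DRA alone.

Thresholds: CNV = 1 iff DRA or DRF < 0.8 or > 1.2; genotype 0/1 for DRA in
[0.2, 0.8) or (1.2, 1.75], 1/1 for DRA < 0.2 or > 1.75, ./. in the neutral
band. Genotyping is DRA-only by design: SR/DP fractions are poor genotype
indicators near repeats, and DRF-based genotyping is deliberately not
implemented. The per-interval control coverage SD track uses the population
SD (ddof = 0) across samples on a 1-kb grid anchored at position 1 — the
cohort is the full reference set, so the track is descriptive, not
inferential.

## Integration

DOC-caller candidates are split at N-masked reference regions, excluding the
masked part (split happens before cross-sample merging; the ordering when
calls disagree is not externally pinned). Each DOC candidate is then
annotated with SR/DP showing the orientation its type predicts within
breakpoint windows: outer limit 1% of CNV length clamped to [1 kb, 5 kb],
inner limit half the CNV length capped at 5 kb, mirrored at the 3'
breakpoint.

Two calls are mergeable when they share a gain/loss class (DEL with losses,
DUP with gains, INV only with INV; BND passes through un-merged) and either
reciprocally overlap by ≥ 70% or each leaves at most 200 bp outside the
overlap. The residue clause is implemented literally, so two disjoint
sub-200-bp calls of one class technically merge; candidate calls that short
do not arise from the generator, and depth-based callers emit window-sized
calls well above this. Cross-sample merging collapses single-linkage
connected components to one call at the average start and end; per-sample
evidence is retained with per-sample maxima of SR and DP (merged calls may
share reads, so sums would double-count). Caller fusion pairs DOC with
SR/DP candidates greedily by highest reciprocal overlap (ties broken by
smaller start), keeps the SR/DP caller's breakpoint-precise coordinates,
and passes unmatched calls through.

In joint batches (at most 15 samples) every batch sample is genotyped over
each merged interval. If some samples show a DOC change and others carry
only SR/DP support, the variant is emitted twice: once as CNV = 1 with the
DOC-supported samples, once as a copy-neutral CNV = 0 variant with the rest.

## Confidence tranches and quality attributes

Calibrated for 30–40× Illumina WGS:

| class | HIGH | PASS |
|---|---|---|
| CNV | > 100 kb, or > 10 kb with average MQ > 55 across the variant | > 10 kb, or ≤ 10 kb with SU ≥ 2 |
| copy-neutral SV | SU ≥ 10 with ≥ 1 SR and ≥ 1 DP | SU ≥ 6 |

Everything else is LOW. "Spanning read" support is read as discordant pairs
— SR and DP are the two read-evidence sources. The thresholds live in a
`TrancheRules` dataclass for recalibration at other depths. Whether small
PASS CNVs should additionally require a DOC change is open; the
evidence-count-only reading is implemented. Variant-level support for
classification is the per-sample maximum.

Quality attributes per variant: average MQ across the variant and in
±500 bp windows around each breakpoint (the window size is this package's
choice; nothing external pins it), GC% over unambiguous bases, the sequence
compression ratio (zlib/DEFLATE at level 6, pinned so ratios are
reproducible; tandem repeats compress harder, so low CR marks repetitive
sequence), and the best segmental-duplication match — the overlapping record
with the highest sum of overlap percent of variant length and percent
sequence similarity.

## Population allele frequencies

* **PAFSU = SUC / SU / NCS.** SUC sums control SR/DP within 1000 bp of each
  breakpoint with the orientation matching the SV type; the two breakpoint
  windows are summed without deduplication (evidence shared between windows
  may count twice — accepted, since PAFSU is an abundance estimate, not a
  genotype). PAFSU is unbounded above; values > 1 flag mapping-artifact
  regions. Undefined when SU = 0.
* **PAFDRA** counts control samples whose 1-kb DRA intervals show the same
  change direction (loss < 0.8, gain > 1.2) over ≥ 90% of the CNV's
  overlapped intervals; a CNV inside one interval uses that interval alone.
* **PAFV** counts control carriers of matching Pass/High control variants.
  Matching requires equal type and CNV state; copy-neutral SVs match within
  1000 bp per breakpoint; CNVs require overlap ≥ 20% of the reference
  length and ≥ 90% of the query length, relaxed to ≥ 70% of the query for
  queries under 1 kb (the 20% reference clause is retained for short
  queries — the composition of the short-CNV rule is ambiguous, and
  retaining both clauses is the stricter reading).
* External sets (1000-Genomes-style, gnomAD-style) contribute the AF of the
  best-matching record by overlap. DGV-style annotation reuses the same
  matcher.

RARE ⇔ none of PAFV, PAFSU, PAFDRA, PAF1KG exceeds 0.01 (strict; a PAF of
exactly 1% is still rare). PAFG (gnomAD) is annotation-only and excluded
from the rule.

## Annotation and prioritization

Genes are matched by any overlap with the gene body (configurable padding,
default 0); pseudogenes are expected to be pre-filtered from the gene
models; disease terms join from a prepared TSV mapping. Candidate-gene hits
(CANDG) are the intersection of overlapped genes with a user list. With a
PED file, IA and IUA count called carriers among affected and unaffected
individuals (unknown status excluded; carriers are samples with a call, not
any-evidence samples). The rare-gene-affecting filter keeps variants that
are rare, overlap ≥ 1 gene, and are PASS or HIGH; it is idempotent.

## Concordance

A truth variant is a true positive when a same-type query has both
breakpoints within 1000 bp or a reciprocal overlap ≥ 80% — or, in multipart
mode, when several HIGH/PASS query parts overlap it and their interval
union itself satisfies the reciprocal criterion against the truth variant.
Query records matching nothing are false positives; sensitivity is
TP / (TP + FN), optionally stratified into the size bins 0–500, 500–1 k,
1 k–5 k, 5 k–10 k, 10 k–50 k, 50 k–100 k, 100 k–500 k, 500 k–5 M.
Microarray-style comparison uses 50% reciprocal overlap with no breakpoint
clause and greedy one-to-one matching (best overlap, coordinate
tie-break).

## QC report and outputs

Per-sample scalar metrics (mean coverage, DP/SR totals, variant counts by
class and tranche, rare counts — the metric list is config-driven) are
compared to control-cohort distributions supplied as a (metric, mean, sd)
TSV; the deviation is reported as z = (x − mean)/sd, metrics with |z| > 2
are flagged, and a metric with control SD 0 gets an undefined z and a
review flag without failing the sample. The sample passes when no
computable metric exceeds the limit.

Writers emit an annotated per-variant-per-sample TSV with a stable column
order, a VCF 4.2 with symbolic ALTs and breakend notation for
inter-chromosomal records, an IGV session XML wiring up the 11 review data
tracks (control DOC, sample DOC, DOC MQ20, MQ, control DOC SD, segmental
duplications, calls, DP, SR, control-cohort calls, DGV) plus the gene
annotation as a feature-panel resource, and the QC report as TSV/HTML. All
writers are deterministic given identical input.

## Synthetic evidence generator

The generator emulates evidence at the DP/SR/coverage level rather than
simulating reads: this exercises every downstream formula without an
aligner and keeps the full test bed under a minute. Defaults are the study
conditions the pipeline targets: 30× depth (clinical WGS at 30–40×), 150-bp
reads and 400 ± 80 bp fragments (HiSeq-X-class paired-end), 100-bp coverage
bins (the depth-caller window size), planted variants non-overlapping with
5-kb flanking spacing. Per-bin depth is Poisson in read starts scaled by
the copy factor (het DEL 0.5, hom DEL 0, het DUP 1.5, hom DUP 2, INV 1);
breakpoint DP counts are Poisson with mean depth × allele fraction and SR
counts at 0.6 of that (split reads are clipped below usable length more
often than pairs are lost); both carry the orientation the type predicts
and are suppressed inside configurable low-MQ patches. A background of 2
artifact DP records per Mb is scattered uniformly. Control cohorts draw
carriers binomially from each variant's allele frequency; control 1-kb DRA
summaries use Gaussian noise with SD 0.08 around the copy state —
representative of the well-behaved majority of the genome, where the
per-interval control SD sits below 0.15. Randomness derives from
SHA-256 of (seed, stream label), so per-sample streams are independent and
byte-reproducible.

Caller-shaped candidates come either from the truth table (`srdp` style:
exact breakpoints with the sample's simulated support counts; `doc` style:
CNV types only, boundaries quantized to the 100-bp window with optional
jitter and dropout) or from a deliberately naive fixed-bin segmenter that
thresholds smoothed DRA runs (box smoothing over 5 bins normalized at
contig edges, gaps up to 2 bins closed, minimum run 5 bins). The segmenter
exists only to turn simulated tracks into depth-caller-shaped input; it is
not a reimplementation of any published caller, and its spurious short
segments are expected — they exercise the LOW tranche.

What the generator does **not** emulate: GC-coverage bias, read-error
profiles, fragment-length mixtures, repeat-mediated evidence loss beyond
the low-MQ patches, and multi-allelic CNV. Passing tests therefore
demonstrate the correctness of the integration, genotyping, frequency and
prioritization logic under clean evidence — not calling performance on
real, repeat-rich genomes.

## Problem sizes in the test bed

The end-to-end harness plants 200 non-overlapping DEL/DUP of 0.5–500 kb
(log-uniform) on a 50-Mb single-contig genome at 30× and requires ≥ 95% of
unique-region variants > 1 kb back as PASS/HIGH; cohort recovery uses 200
variants against 500 simulated controls; merge and matching oracles run
1,000 and 500 random instances. These sizes were chosen as the smallest
that make the binomial/Poisson tolerances tight; the full suite runs in a
few seconds on one CPU.

## Known limitations

* The tranche table implements the published prose rules; a fuller
  recalibration table would need matched validation data.
* Breakend (BND) records pass through integration un-merged and un-scored
  beyond read counts.
* Mask-splitting is applied to depth-caller candidates only, before
  cross-sample merging; SR/DP candidates keep their precise coordinates.
* The IGV session references track paths without validating file contents.
* PAFSU's window sums may double-count evidence shared between the two
  breakpoint windows of very short variants.
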