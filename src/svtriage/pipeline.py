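"""End-to-end orchestration: candidate calls + evidence in, fully
annotated integrated variants out.

Single samples and joint batches (up to 15 samples) run through the same
path: mask-splitting, cross-annotation of DOC calls with read evidence,
within- and cross-caller merging, per-sample DOC genotyping, mixed-support
splitting, tranche classification, population allele frequencies, and
gene/pedigree annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotate import (
    GeneIndex,
    PedigreeInfo,
    annotate_genes,
    pedigree_counts,
)
from .coverage import CoverageTrack, GenomeCoverageEstimate, compute_doc_metrics
from .evidence import DiscordantPair, SplitRead
from .genome import EstimationError
from .integrate import (
    CandidateCall,
    EvidenceCounts,
    IntegratedVariant,
    annotate_doc_call_with_read_evidence,
    genotype_variant,
    merge_doc_calls_across_samples,
    merge_doc_with_srdp,
    split_at_masked_regions,
    split_mixed_support,
)
from .popfreq import (
    ControlCohortDB,
    PafSet,
    compute_external_paf,
    compute_pafdra,
    compute_pafsu,
    compute_pafv,
    flag_rare,
)
from .quality import (
    DEFAULT_RULES,
    QualityAttributes,
    SegDupRecord,
    TrancheRules,
    best_segdup_match,
    classify_confidence,
    compute_compression_ratio,
    compute_gc,
)

MAX_BATCH = 15
BREAKPOINT_MQ_WINDOW = 500


@dataclass
class SampleInput:
    """Everything the pipeline needs for one sample of a batch."""

    sample_id: str
    track: CoverageTrack
    genome_est: GenomeCoverageEstimate
    doc_calls: list[CandidateCall] = field(default_factory=list)
    srdp_calls: list[CandidateCall] = field(default_factory=list)
    dps: list[DiscordantPair] = field(default_factory=list)
    srs: list[SplitRead] = field(default_factory=list)


def _avg_mq(tracks: Sequence[CoverageTrack], chrom: str, start: int, end: int):
    vals = []
    for t in tracks:
        if t.mq is None or chrom not in t.mq:
            continue
        idx, w = t._bin_weights(chrom, start, end)
        if len(idx):
            vals.append(float(np.average(t.mq[chrom][idx], weights=w)))
    return float(np.mean(vals)) if vals else None


def _quality_attributes(
    variant: IntegratedVariant,
    tracks: Sequence[CoverageTrack],
    reference: dict[str, str] | None,
    segdups: Sequence[SegDupRecord],
) -> QualityAttributes:
    q = QualityAttributes()
    q.avg_mq_variant = _avg_mq(tracks, variant.chrom, variant.start, variant.end)
    bp_vals = []
    for pos in (variant.start, variant.end):
        v = _avg_mq(
            tracks,
            variant.chrom,
            pos - BREAKPOINT_MQ_WINDOW,
            pos + BREAKPOINT_MQ_WINDOW,
        )
        if v is not None:
            bp_vals.append(v)
    q.avg_mq_breakpoints = float(np.mean(bp_vals)) if bp_vals else None
    if reference is not None and variant.chrom in reference:
        seq = reference[variant.chrom][variant.start : variant.end]
        if seq:
            q.gc_percent = compute_gc(seq)
            if len(seq) >= 50:
                q.compression_ratio = compute_compression_ratio(seq)
    hit = best_segdup_match(
        variant.chrom, variant.start, variant.end, segdups
    )
    if hit is not None:
        q.segdup_match = (hit[1], hit[2])
    return q


def run_integration(
    samples: Sequence[SampleInput],
    mask: dict[str, list[tuple[int, int]]] | None = None,
    db: ControlCohortDB | None = None,
    gene_index: GeneIndex | None = None,
    candidate_genes: Sequence[str] = (),
    ped: PedigreeInfo | None = None,
    external_1kg: Sequence = (),
    external_gnomad: Sequence = (),
    reference: dict[str, str] | None = None,
    segdups: Sequence[SegDupRecord] = (),
    rules: TrancheRules = DEFAULT_RULES,
) -> list[IntegratedVariant]:
    """Run the full integration and annotation pipeline on a batch."""
    if not samples:
        return []
    if len(samples) > MAX_BATCH:
        raise EstimationError(
            f"joint batches are limited to {MAX_BATCH} samples, got {len(samples)}"
        )
    mask = mask or {}
    all_dps = [d for s in samples for d in s.dps]
    all_srs = [r for s in samples for r in s.srs]

    doc_calls: list[CandidateCall] = []
    for s in samples:
        for call in s.doc_calls:
            for part in split_at_masked_regions(call, mask.get(call.chrom, [])):
                counts = annotate_doc_call_with_read_evidence(
                    part, all_dps, all_srs
                )
                merged_counts = dict(part.samples)
                for sid, c in counts.items():
                    cur = merged_counts.setdefault(sid, EvidenceCounts())
                    cur.sr = max(cur.sr, c.sr)
                    cur.dp = max(cur.dp, c.dp)
                part.samples = merged_counts
                doc_calls.append(part)
    srdp_calls = [c for s in samples for c in s.srdp_calls]

    doc_merged = merge_doc_calls_across_samples(doc_calls)
    srdp_merged = (
        merge_doc_calls_across_samples(srdp_calls)
        if len(samples) > 1
        else srdp_calls
    )
    variants = merge_doc_with_srdp(doc_merged, srdp_merged)

    by_id = {s.sample_id: s for s in samples}
    tracks = [s.track for s in samples]
    out: list[IntegratedVariant] = []
    for v in variants:
        # per-sample DOC metrics over the final interval
        for s in samples:
            sc = v.samples.get(s.sample_id)
            try:
                doc = compute_doc_metrics(
                    v.chrom, v.start, v.end, s.track, s.genome_est
                )
            except EstimationError:
                doc = None
            if sc is not None:
                sc.doc = doc
            elif doc is not None:
                from .integrate import SampleCall

                v.samples[s.sample_id] = SampleCall(doc=doc)
        genotype_variant(v)
        # keep carrier samples: read support or a DOC copy-number change
        carriers = {
            k: sc
            for k, sc in v.samples.items()
            if sc.counts.su > 0 or sc.cnv
        }
        if carriers:
            v.samples = carriers
        for part in split_mixed_support(v):
            part.quality = _quality_attributes(part, tracks, reference, segdups)
            part.tranche = classify_confidence(part, rules)
            pafs = PafSet()
            if db is not None:
                counts = part.max_counts()
                pafs.pafsu = compute_pafsu(
                    part.chrom, part.start, part.end, part.svtype,
                    counts.su, db,
                )
                if part.is_cnv:
                    pafs.pafdra = compute_pafdra(
                        part.chrom, part.start, part.end, part.svtype, db
                    )
                pafs.pafv = compute_pafv(part, db)
            if external_1kg:
                pafs.paf1kg = compute_external_paf(part, external_1kg)
            if external_gnomad:
                pafs.pafg = compute_external_paf(part, external_gnomad)
            pafs.rare = flag_rare(pafs)
            part.pafs = pafs
            if gene_index is not None:
                ann = annotate_genes(part, gene_index, candidate_genes)
                if ped is not None:
                    ann.ia, ann.iua = pedigree_counts(part.samples, ped)
            out.append(part)
    out.sort(key=lambda v: (v.chrom, v.start, v.end, v.svtype, not v.is_cnv))
    return out


def collect_qc_metrics(
    sample: SampleInput, variants: Sequence[IntegratedVariant]
) -> dict[str, float]:
    """Per-sample scalar QC metrics compared against the control cohort."""
    track = sample.track
    cov = float(
        np.mean([a.mean() for a in track.depth.values()])
    )
    mine = [v for v in variants if sample.sample_id in v.samples]
    n_cnv = sum(1 for v in mine if v.is_cnv)
    n_sv = len(mine) - n_cnv
    n_pass_high = sum(1 for v in mine if v.tranche in ("HIGH", "PASS"))
    n_rare = sum(1 for v in mine if v.pafs is not None and v.pafs.rare)
    return {
        "mean_coverage": cov,
        "dp_total": float(len(sample.dps)),
        "sr_total": float(len(sample.srs)),
        "n_cnv": float(n_cnv),
        "n_sv": float(n_sv),
        "n_pass_high": float(n_pass_high),
        "n_rare": float(n_rare),
    }
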