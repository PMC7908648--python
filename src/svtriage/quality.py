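"""Confidence tranches and per-variant quality attributes.

Tranche rules (calibrated for 30-40x Illumina WGS):

* CNVs: HIGH if > 100 kb, or > 10 kb with confidently mapped reads
  (average MQ > 55 across the variant); PASS if > 10 kb, or <= 10 kb with
  at least two supporting split reads or discordant pairs.
* Copy-number-neutral SVs: HIGH with at least 10 supporting reads and at
  least one from each source (SR and DP); PASS with at least 6.
* Everything else is LOW.

The rule thresholds live in :class:`TrancheRules` so they can be
recalibrated for other depths or chemistries.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

from .integrate import IntegratedVariant

HIGH, PASS, LOW = "HIGH", "PASS", "LOW"


@dataclass
class QualityAttributes:
    avg_mq_variant: float | None = None
    avg_mq_breakpoints: float | None = None
    gc_percent: float | None = None
    compression_ratio: float | None = None
    segdup_match: tuple[float, float] | None = None  # (overlap %, similarity %)


@dataclass(frozen=True)
class TrancheRules:
    cnv_high_length: int = 100_000
    cnv_mq_length: int = 10_000
    cnv_mq_min: float = 55.0
    cnv_pass_length: int = 10_000
    cnv_pass_su: int = 2
    sv_high_su: int = 10
    sv_pass_su: int = 6


DEFAULT_RULES = TrancheRules()


def classify_confidence(
    variant: IntegratedVariant, rules: TrancheRules = DEFAULT_RULES
) -> str:
    """Assign exactly one of HIGH / PASS / LOW (a total function)."""
    counts = variant.max_counts()
    su, sr, dp = counts.su, counts.sr, counts.dp
    if variant.is_cnv:
        length = variant.length
        mq = variant.quality.avg_mq_variant if variant.quality else None
        if length > rules.cnv_high_length:
            return HIGH
        if length > rules.cnv_mq_length and mq is not None and mq > rules.cnv_mq_min:
            return HIGH
        if length > rules.cnv_pass_length:
            return PASS
        if su >= rules.cnv_pass_su:
            return PASS
        return LOW
    if su >= rules.sv_high_su and sr >= 1 and dp >= 1:
        return HIGH
    if su >= rules.sv_pass_su:
        return PASS
    return LOW


def compute_gc(sequence: str) -> float | None:
    """GC percent over unambiguous bases; None for an all-ambiguous
    (e.g. all-N) interval."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        return None
    return 100.0 * gc / acgt


#: DEFLATE level pinned so compression ratios are reproducible across runs
COMPRESSION_LEVEL = 6


def compute_compression_ratio(sequence: str, level: int = COMPRESSION_LEVEL) -> float:
    """Compressed byte length divided by sequence length.

    Low ratios indicate repetitive (tandem-repeat) sequence; such variants
    typically have reduced SR/DP support from short reads.
    """
    if len(sequence) < 50:
        raise ValueError("sequence must be at least 50 bases for a stable ratio")
    data = sequence.upper().encode("ascii")
    return len(zlib.compress(data, level)) / len(data)


@dataclass(frozen=True)
class SegDupRecord:
    chrom: str
    start: int
    end: int
    similarity: float  # percent identity of the duplicated pair


def best_segdup_match(
    variant_chrom: str,
    variant_start: int,
    variant_end: int,
    segdups: Sequence[SegDupRecord],
) -> tuple[SegDupRecord, float, float] | None:
    """Among overlapping segmental duplications, the record with the
    highest sum of overlap (% of variant length) and sequence similarity
    (%).  Returns (record, overlap %, similarity %), or None if nothing
    overlaps."""
    length = variant_end - variant_start
    if length <= 0:
        return None
    best: tuple[float, SegDupRecord, float] | None = None
    for rec in segdups:
        if rec.chrom != variant_chrom:
            continue
        ov = max(0, min(variant_end, rec.end) - max(variant_start, rec.start))
        if ov == 0:
            continue
        ov_pct = 100.0 * ov / length
        score = ov_pct + rec.similarity
        if best is None or score > best[0]:
            best = (score, rec, ov_pct)
    if best is None:
        return None
    return best[1], best[2], best[1].similarity
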