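"""Integration of depth-of-coverage CNV calls with split-read /
discordant-pair SV calls.

DOC-caller candidates (imprecise, read-depth driven) and SR/DP-caller
candidates (breakpoint precise) are split at reference N-masked regions,
cross-annotated with each other's evidence type, merged within and across
samples, and fused into :class:`IntegratedVariant` records.  When both
callers contribute, the SR/DP caller's more precise coordinates are
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .coverage import DocMetrics, assign_genotype, flag_cnv
from .evidence import EXPECTED_ORIENTATION, DiscordantPair, SplitRead
from .genome import overlap_length, subtract_intervals

SVTYPES = ("DEL", "DUP", "INV", "BND")

#: gain/loss merge classes: DEL merges only with losses, DUP with gains,
#: INV only with INV; BND records pass through un-merged.
MERGE_CLASS = {"DEL": "loss", "DUP": "gain", "INV": "inv", "BND": "bnd"}


@dataclass
class EvidenceCounts:
    sr: int = 0
    dp: int = 0

    @property
    def su(self) -> int:
        return self.sr + self.dp

    def __post_init__(self):
        if self.sr < 0 or self.dp < 0:
            raise ValueError("evidence counts must be non-negative")


@dataclass
class CandidateCall:
    """One caller's candidate with per-sample support counts."""

    chrom: str
    start: int
    end: int
    svtype: str
    caller: str  # "doc" or "srdp"
    samples: dict[str, EvidenceCounts] = field(default_factory=dict)
    doc: dict[str, DocMetrics] = field(default_factory=dict)  # per sample
    precise: bool = False
    mate_chrom: str | None = None  # BND only
    mate_pos: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SampleCall:
    """Per-sample state of an integrated variant."""

    counts: EvidenceCounts = field(default_factory=EvidenceCounts)
    doc: DocMetrics | None = None
    genotype: str = "./."
    cnv: bool = False


@dataclass
class IntegratedVariant:
    chrom: str
    start: int
    end: int
    svtype: str
    callers: frozenset[str]
    samples: dict[str, SampleCall] = field(default_factory=dict)
    is_cnv: bool = False
    tranche: str | None = None
    quality: object | None = None  # QualityAttributes
    pafs: object | None = None  # PafSet
    annotations: object | None = None  # Annotations
    mate_chrom: str | None = None
    mate_pos: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def max_counts(self) -> EvidenceCounts:
        """Variant-level evidence: max SR and DP over carrier samples."""
        sr = max((s.counts.sr for s in self.samples.values()), default=0)
        dp = max((s.counts.dp for s in self.samples.values()), default=0)
        return EvidenceCounts(sr=sr, dp=dp)


# ---- masked-region splitting ------------------------------------------


def split_at_masked_regions(
    call: CandidateCall, mask: Sequence[tuple[int, int]]
) -> list[CandidateCall]:
    """Split a call spanning N-masked reference regions, excluding the
    masked part.  ``mask`` is sorted, non-overlapping (same contig)."""
    parts = subtract_intervals(call.start, call.end, mask)
    if parts == [(call.start, call.end)]:
        return [call]
    return [replace(call, start=s, end=e) for s, e in parts]


# ---- DOC-call read-evidence annotation --------------------------------


def breakpoint_evidence_window(length: int) -> tuple[int, int]:
    """(outer, inner) limits around each breakpoint of a CNV of ``length``:
    outer = 1% of length clamped to [1 kb, 5 kb]; inner = min(length/2, 5 kb)."""
    if length <= 0:
        raise ValueError("length must be positive")
    outer = int(min(max(0.01 * length, 1000), 5000))
    inner = int(min(length / 2, 5000))
    return outer, inner


def annotate_doc_call_with_read_evidence(
    call: CandidateCall,
    dps: Iterable[DiscordantPair],
    srs: Iterable[SplitRead],
) -> dict[str, EvidenceCounts]:
    """Count DP/SR with the expected orientation whose mapped ends fall
    within [breakpoint - outer, breakpoint + inner] at the 5' breakpoint
    (mirrored at the 3' breakpoint)."""
    outer, inner = breakpoint_evidence_window(call.length)
    lo5, hi5 = call.start - outer, call.start + inner
    lo3, hi3 = call.end - inner, call.end + outer
    allowed = EXPECTED_ORIENTATION.get(call.svtype, ())
    counts: dict[str, EvidenceCounts] = {}

    def bump(sample: str, kind: str) -> None:
        c = counts.setdefault(sample, EvidenceCounts())
        if kind == "dp":
            c.dp += 1
        else:
            c.sr += 1

    for dp in dps:
        if dp.chrom != call.chrom or dp.orientation not in allowed:
            continue
        if lo5 <= dp.start <= hi5 and lo3 <= dp.end <= hi3:
            bump(dp.sample_id, "dp")
    for sr in srs:
        if (
            sr.primary_chrom != call.chrom
            or sr.clipped_chrom != call.chrom
            or sr.orientation not in allowed
        ):
            continue
        s = min(sr.primary_start, sr.clipped_start)
        e = max(sr.primary_end, sr.clipped_end)
        if lo5 <= s <= hi5 and lo3 <= e <= hi3:
            bump(sr.sample_id, "sr")
    return counts


# ---- merging -----------------------------------------------------------

RECIPROCAL_MIN = 0.7
RESIDUE_MAX = 200


def mergeable(a: CandidateCall, b: CandidateCall) -> bool:
    """Same event class and either reciprocal overlap >= 70% or the
    non-overlapping residue of each call at most 200 bases."""
    if a.chrom != b.chrom or MERGE_CLASS[a.svtype] != MERGE_CLASS[b.svtype]:
        return False
    if a.svtype == "BND":
        return False
    ov = overlap_length(a.start, a.end, b.start, b.end)
    la, lb = a.length, b.length
    if la <= 0 or lb <= 0:
        return False
    if ov / la >= RECIPROCAL_MIN and ov / lb >= RECIPROCAL_MIN:
        return True
    return (la - ov) <= RESIDUE_MAX and (lb - ov) <= RESIDUE_MAX


def _merge_sample_maps(
    maps: Iterable[dict[str, EvidenceCounts]]
) -> dict[str, EvidenceCounts]:
    """Per-sample max of SR and DP counts (avoids double-counting reads
    shared between merged calls)."""
    out: dict[str, EvidenceCounts] = {}
    for m in maps:
        for sample, c in m.items():
            cur = out.setdefault(sample, EvidenceCounts())
            cur.sr = max(cur.sr, c.sr)
            cur.dp = max(cur.dp, c.dp)
    return out


def _merge_doc_maps(maps: Iterable[dict[str, DocMetrics]]) -> dict[str, DocMetrics]:
    out: dict[str, DocMetrics] = {}
    for m in maps:
        for sample, metrics in m.items():
            out.setdefault(sample, metrics)
    return out


def _connected_components(calls: list[CandidateCall]) -> list[list[int]]:
    """Single-linkage components under mergeable() (union-find over a
    start-sorted sweep)."""
    order = sorted(range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].start))
    parent = list(range(len(calls)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for ai in range(len(order)):
        i = order[ai]
        for bj in range(ai + 1, len(order)):
            j = order[bj]
            if mergeable(calls[i], calls[j]):
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: min(g))


def merge_doc_calls_across_samples(calls: Sequence[CandidateCall]) -> list[CandidateCall]:
    """Collapse connected components under mergeable() to single calls with
    average start/end coordinates; per-sample evidence is retained."""
    calls = list(calls)
    merged: list[CandidateCall] = []
    by_class: dict[str, list[CandidateCall]] = {}
    for c in calls:
        by_class.setdefault(MERGE_CLASS[c.svtype], []).append(c)
    for group in by_class.values():
        for comp in _connected_components(group):
            members = [group[i] for i in comp]
            if len(members) == 1:
                merged.append(members[0])
                continue
            start = int(round(sum(m.start for m in members) / len(members)))
            end = int(round(sum(m.end for m in members) / len(members)))
            merged.append(
                CandidateCall(
                    chrom=members[0].chrom,
                    start=start,
                    end=max(end, start + 1),
                    svtype=members[0].svtype,
                    caller=members[0].caller,
                    samples=_merge_sample_maps(m.samples for m in members),
                    doc=_merge_doc_maps(m.doc for m in members),
                    precise=any(m.precise for m in members),
                )
            )
    merged.sort(key=lambda c: (c.chrom, c.start, c.end))
    return merged


def _to_variant(call: CandidateCall, callers: frozenset[str]) -> IntegratedVariant:
    samples = {
        s: SampleCall(counts=c, doc=call.doc.get(s))
        for s, c in call.samples.items()
    }
    for s, doc in call.doc.items():
        samples.setdefault(s, SampleCall(doc=doc))
    return IntegratedVariant(
        chrom=call.chrom,
        start=call.start,
        end=call.end,
        svtype=call.svtype,
        callers=callers,
        samples=samples,
        mate_chrom=call.mate_chrom,
        mate_pos=call.mate_pos,
    )


def merge_doc_with_srdp(
    doc_calls: Sequence[CandidateCall], srdp_calls: Sequence[CandidateCall]
) -> list[IntegratedVariant]:
    """Fuse mergeable DOC/SRDP call pairs, preserving the SR/DP caller's
    more precise coordinates; unmatched calls pass through.

    When one SR/DP call could match several DOC calls (or vice versa), the
    pair with the highest reciprocal overlap wins (deterministic tie-break
    by smaller start); the rest remain unmatched.
    """
    doc_calls, srdp_calls = list(doc_calls), list(srdp_calls)
    pairs: list[tuple[float, int, int]] = []
    for i, d in enumerate(doc_calls):
        for j, s in enumerate(srdp_calls):
            if mergeable(d, s):
                ov = overlap_length(d.start, d.end, s.start, s.end)
                score = min(ov / d.length, ov / s.length) if d.length and s.length else 0
                pairs.append((score, i, j))
    pairs.sort(key=lambda t: (-t[0], doc_calls[t[1]].start, srdp_calls[t[2]].start,
                              t[1], t[2]))
    used_doc: set[int] = set()
    used_srdp: set[int] = set()
    out: list[IntegratedVariant] = []
    for score, i, j in pairs:
        if i in used_doc or j in used_srdp:
            continue
        used_doc.add(i)
        used_srdp.add(j)
        d, s = doc_calls[i], srdp_calls[j]
        var = _to_variant(
            replace(
                s,
                samples=_merge_sample_maps([d.samples, s.samples]),
                doc=_merge_doc_maps([s.doc, d.doc]),
            ),
            callers=frozenset({"doc", "srdp"}),
        )
        out.append(var)
    for i, d in enumerate(doc_calls):
        if i not in used_doc:
            out.append(_to_variant(d, frozenset({"doc"})))
    for j, s in enumerate(srdp_calls):
        if j not in used_srdp:
            out.append(_to_variant(s, frozenset({"srdp"})))
    out.sort(key=lambda v: (v.chrom, v.start, v.end, v.svtype))
    return out


def genotype_variant(variant: IntegratedVariant, genome_est=None) -> None:
    """Fill per-sample genotype and CNV flag from DOC metrics; the variant
    is a CNV iff any carrier sample is."""
    for s in variant.samples.values():
        if s.doc is not None:
            s.cnv = flag_cnv(s.doc)
            s.genotype = assign_genotype(s.doc.dra)
        else:
            s.cnv = False
            s.genotype = "./."
    variant.is_cnv = any(s.cnv for s in variant.samples.values())


def split_mixed_support(variant: IntegratedVariant) -> list[IntegratedVariant]:
    """In a joint batch, if some samples have DOC support (CNV) and others
    only DP/SR, emit two variants: one CNV = 1 carrying the DOC-supported
    samples and one copy-neutral (CNV = 0) carrying the rest."""
    cnv_samples = {k: v for k, v in variant.samples.items() if v.cnv}
    other = {
        k: v
        for k, v in variant.samples.items()
        if not v.cnv and v.counts.su > 0
    }
    if not cnv_samples or not other:
        return [variant]
    a = replace(variant, samples=cnv_samples, is_cnv=True)
    b = replace(variant, samples=other, is_cnv=False)
    return [a, b]
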