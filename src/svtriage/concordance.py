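"""Call-set concordance: sensitivity and false-positive bookkeeping.

A truth variant is a true positive when matched by at least one query
variant whose breakpoints are within 1000 bases or whose reciprocal overlap
is at least 80% — or, in multipart mode, by several HIGH/PASS query parts
whose union jointly satisfies the reciprocal criterion (a large truth CNV
split by the caller still counts).  Sensitivity is TP / (TP + FN).
Microarray-style comparison relaxes to 50% reciprocal overlap with no
breakpoint clause.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .genome import merge_intervals, overlap_length, reciprocal_overlap
from .quality import HIGH, PASS


@dataclass(frozen=True)
class MatchCriteria:
    breakpoint_tol: int | None = 1000
    reciprocal: float = 0.8
    allow_multipart: bool = True


DEFAULT_CRITERIA = MatchCriteria()
MICROARRAY_CRITERIA = MatchCriteria(
    breakpoint_tol=None, reciprocal=0.5, allow_multipart=False
)


@dataclass
class ConcordanceResult:
    tp: int
    fp: int
    fn: int
    truth_matches: dict[int, list[int]] = field(default_factory=dict)
    query_matches: dict[int, list[int]] = field(default_factory=dict)

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None


def _svtype(v) -> str:
    return getattr(v, "svtype")


def _tranche(v) -> str | None:
    return getattr(v, "tranche", None)


def _single_match(q, t, criteria: MatchCriteria) -> bool:
    if q.chrom != t.chrom:
        return False
    if criteria.breakpoint_tol is not None:
        if (
            abs(q.start - t.start) <= criteria.breakpoint_tol
            and abs(q.end - t.end) <= criteria.breakpoint_tol
        ):
            return True
    return reciprocal_overlap(q.start, q.end, t.start, t.end) >= criteria.reciprocal


def _multipart_match(parts, t, criteria: MatchCriteria) -> bool:
    """Union of HIGH/PASS parts must itself satisfy the reciprocal-overlap
    criterion against the truth variant."""
    if not parts:
        return False
    union = merge_intervals([(p.start, p.end) for p in parts])
    union_len = sum(e - s for s, e in union)
    ov = sum(overlap_length(s, e, t.start, t.end) for s, e in union)
    t_len = t.end - t.start
    if t_len <= 0 or union_len <= 0:
        return False
    return ov >= criteria.reciprocal * t_len and ov >= criteria.reciprocal * union_len


def match_callsets(
    query: Sequence,
    truth: Sequence,
    criteria: MatchCriteria = DEFAULT_CRITERIA,
) -> ConcordanceResult:
    """TP/FP/FN between a query and a truth call set.

    Matching requires equal SV types; a query record with a type absent
    from the truth set is simply counted unmatched (with a warning the
    first time).  In multipart mode, one truth variant may be jointly
    covered by several query parts given all parts are HIGH or PASS;
    otherwise matching is greedily one-to-one by best overlap with a
    deterministic coordinate tie-break.
    """
    truth_types = {_svtype(t) for t in truth}
    unmatched_types = {_svtype(q) for q in query} - truth_types
    if unmatched_types and truth:
        warnings.warn(
            f"query types {sorted(unmatched_types)} absent from truth set; "
            "counted unmatched"
        )
    truth_matches: dict[int, list[int]] = {}
    query_matches: dict[int, list[int]] = {}

    if criteria.allow_multipart:
        for ti, t in enumerate(truth):
            hits = [
                qi
                for qi, q in enumerate(query)
                if _svtype(q) == _svtype(t) and _single_match(q, t, criteria)
            ]
            if not hits:
                parts_idx = [
                    qi
                    for qi, q in enumerate(query)
                    if _svtype(q) == _svtype(t)
                    and q.chrom == t.chrom
                    and _tranche(q) in (HIGH, PASS)
                    and overlap_length(q.start, q.end, t.start, t.end) > 0
                ]
                if _multipart_match([query[qi] for qi in parts_idx], t, criteria):
                    hits = parts_idx
            if hits:
                truth_matches[ti] = hits
                for qi in hits:
                    query_matches.setdefault(qi, []).append(ti)
    else:
        # greedy one-to-one: best overlap first, coordinate tie-break
        pairs = []
        for ti, t in enumerate(truth):
            for qi, q in enumerate(query):
                if _svtype(q) == _svtype(t) and _single_match(q, t, criteria):
                    ov = overlap_length(q.start, q.end, t.start, t.end)
                    pairs.append((-ov, t.chrom, t.start, q.start, ti, qi))
        used_t: set[int] = set()
        used_q: set[int] = set()
        for _, _, _, _, ti, qi in sorted(pairs):
            if ti in used_t or qi in used_q:
                continue
            used_t.add(ti)
            used_q.add(qi)
            truth_matches[ti] = [qi]
            query_matches[qi] = [ti]

    tp = len(truth_matches)
    fn = len(truth) - tp
    fp = len(query) - len(query_matches)
    return ConcordanceResult(
        tp=tp, fp=fp, fn=fn,
        truth_matches=truth_matches, query_matches=query_matches,
    )


#: size bins used in sensitivity-by-size tables (bases)
DEFAULT_SIZE_BINS = (0, 500, 1_000, 5_000, 10_000, 50_000, 100_000, 500_000, 5_000_000)


def sensitivity_by_size(
    result: ConcordanceResult,
    truth: Sequence,
    bins: Sequence[int] = DEFAULT_SIZE_BINS,
) -> list[dict]:
    """Per-size-bin sensitivity; empty bins report None."""
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        idx = [
            ti for ti, t in enumerate(truth) if lo <= (t.end - t.start) < hi
        ]
        tp = sum(1 for ti in idx if ti in result.truth_matches)
        n = len(idx)
        rows.append(
            {
                "size_min": lo,
                "size_max": hi,
                "n": n,
                "tp": tp,
                "sensitivity": (tp / n) if n else None,
            }
        )
    return rows
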