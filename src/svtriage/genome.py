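"""Genome layout and interval primitives.

All coordinates are 0-based half-open internally.  User-facing writers
(`svtriage.report`) convert to 1-based inclusive on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence


class SvtriageError(Exception):
    """Base class for all package errors."""


class FormatError(SvtriageError):
    """Malformed or unsorted input."""


class EstimationError(SvtriageError):
    """Not enough or inconsistent data to estimate a quantity."""


@dataclass(frozen=True)
class GenomeLayout:
    """Contig table with chromosome classes and baseline-coverage windows.

    ``autosome_windows`` are the per-autosome intervals used to estimate the
    genome-average depth (on the human reference: a 10-Mb window at
    20,000,000-30,000,000 of each autosome, clear of centromeres/telomeres).
    ``y_unique_regions`` are the uniquely mappable Y intervals; X baseline
    uses the whole chromosome for robustness against large CNVs.
    """

    contigs: dict[str, int]
    autosomes: tuple[str, ...]
    chr_x: str | None = None
    chr_y: str | None = None
    autosome_windows: tuple[tuple[str, int, int], ...] = ()
    y_unique_regions: tuple[tuple[int, int], ...] = ()
    decoys: frozenset[str] = frozenset({"NC_007605", "hs37d5"})

    def contig_length(self, chrom: str) -> int:
        try:
            return self.contigs[chrom]
        except KeyError:
            raise EstimationError(f"unknown contig {chrom!r}") from None

    def is_autosome(self, chrom: str) -> bool:
        return chrom in self.autosomes

    @classmethod
    def grch37(cls) -> "GenomeLayout":
        """Human GRCh37 primary chromosomes with the canonical windows."""
        lengths = {
            "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
            "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
            "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
            "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
            "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
            "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
        }
        autosomes = tuple(str(i) for i in range(1, 23))
        windows = tuple((c, 20_000_000, 30_000_000) for c in autosomes)
        return cls(
            contigs=lengths,
            autosomes=autosomes,
            chr_x="X",
            chr_y="Y",
            autosome_windows=windows,
            y_unique_regions=((6_641_418, 10_079_253), (13_800_703, 23_668_908)),
        )

    @classmethod
    def toy(
        cls,
        contigs: dict[str, int],
        chr_x: str | None = None,
        chr_y: str | None = None,
        window_fraction: float = 0.2,
    ) -> "GenomeLayout":
        """Layout for a synthetic genome: the baseline window of each
        autosome is a central slice (``window_fraction`` of its length)."""
        autosomes = tuple(c for c in contigs if c not in (chr_x, chr_y))
        windows = []
        for c in autosomes:
            n = contigs[c]
            w = max(1, int(n * window_fraction))
            mid = n // 2
            windows.append((c, max(0, mid - w // 2), min(n, mid + w // 2)))
        y_regions: tuple[tuple[int, int], ...] = ()
        if chr_y is not None:
            y_regions = ((0, contigs[chr_y]),)
        return cls(
            contigs=dict(contigs),
            autosomes=autosomes,
            chr_x=chr_x,
            chr_y=chr_y,
            autosome_windows=tuple(windows),
            y_unique_regions=y_regions,
        )


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(overlap/len_a, overlap/len_b); 0 for empty intervals."""
    la, lb = a_end - a_start, b_end - b_start
    if la <= 0 or lb <= 0:
        return 0.0
    ov = overlap_length(a_start, a_end, b_start, b_end)
    return min(ov / la, ov / lb)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted, disjoint list."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(
    start: int, end: int, mask: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """[start, end) minus a sorted, non-overlapping mask."""
    parts: list[tuple[int, int]] = []
    cur = start
    for ms, me in mask:
        if me <= cur or ms >= end:
            continue
        if ms > cur:
            parts.append((cur, min(ms, end)))
        cur = max(cur, me)
        if cur >= end:
            break
    if cur < end:
        parts.append((cur, end))
    return [p for p in parts if p[1] > p[0]]


def round_to_half(x: float) -> float:
    """Round to the nearest multiple of 0.5, half away from zero."""
    return math.floor(2.0 * x + 0.5) / 2.0
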