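"""Discordant-pair and split-read evidence extraction.

Discordant pairs (DP) are read pairs with aberrant mapping distance,
orientation or chromosomes; split reads (SR) are reads whose alignment is
split across a breakpoint (one clipped segment with exactly one
supplementary alignment).  Both can be extracted from a coordinate-sorted,
duplicate-marked BAM, or loaded from pre-extracted TSV tables so the
pipeline runs without an aligner; both paths produce identical records.

Orientation labels (intra-chromosomal, by position order on the contig):
``+-`` read-pair pointing inward (the proper orientation; discordant only by
distance, the deletion signature), ``-+`` everted (duplication signature),
``++``/``--`` same-strand (inversion signature), ``inter`` inter-chromosomal.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome import EstimationError, FormatError, merge_intervals

ORIENTATIONS = ("+-", "-+", "++", "--", "inter")

#: expected DP/SR orientation per SV type
EXPECTED_ORIENTATION = {
    "DEL": ("+-",),
    "DUP": ("-+",),
    "INV": ("++", "--"),
    "BND": ("inter",),
}

DEFAULT_DECOYS = frozenset({"NC_007605", "hs37d5"})


@dataclass(frozen=True)
class DiscordantPair:
    chrom: str
    start: int
    end: int
    mate_chrom: str
    orientation: str
    mapq: int
    sample_id: str
    mate_start: int = -1  # mate position for inter-chromosomal matching

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise FormatError(f"bad orientation {self.orientation!r}")
        if self.chrom == self.mate_chrom and not self.start < self.end:
            raise FormatError("intra-chromosomal pair must have start < end")


@dataclass(frozen=True)
class SplitRead:
    primary_chrom: str
    primary_start: int
    primary_end: int
    clipped_chrom: str
    clipped_start: int
    clipped_end: int
    clip_side: str  # "5p" or "3p"
    orientation: str
    mapq: int
    sample_id: str


@dataclass(frozen=True)
class InsertCutoffs:
    """Discordant mapping-distance cutoffs with the region they came from."""

    lower: int
    upper: int
    region: tuple[str, int, int] | None = None

    def __post_init__(self):
        if not 0 < self.lower <= self.upper:
            raise EstimationError(
                f"invalid cutoffs lower={self.lower} upper={self.upper}"
            )


#: default region used to estimate the insert-size cutoffs (contig 1,
#: 1,000,001-5,000,000 one-based; 4 Mb)
DEFAULT_CUTOFF_REGION = ("1", 1_000_000, 5_000_000)

PAIRS_PER_MB = 100


def compute_insert_cutoffs(
    pair_distances: Sequence[int],
    region_length: int,
    pairs_per_mb: int = PAIRS_PER_MB,
    region: tuple[str, int, int] | None = None,
    min_pairs: int = 1000,
) -> InsertCutoffs:
    """Distance cutoffs at an average tail coverage of 100 read pairs per Mb.

    Sorting the normally-oriented pair distances and iterating in descending
    order while summing counts, the upper cutoff is the distance at which
    the cumulative count per Mb of region first reaches ``pairs_per_mb``;
    the lower cutoff symmetric in ascending order.  Ties (many pairs at one
    distance) resolve toward the more permissive, wider cutoff because the
    whole tied block is accumulated before the comparison.
    """
    n = len(pair_distances)
    if n < min_pairs:
        raise EstimationError(
            f"only {n} normally-oriented pairs in cutoff region (need >= {min_pairs})"
        )
    if region_length <= 0:
        raise EstimationError("region_length must be positive")
    threshold = pairs_per_mb * region_length / 1e6
    values, counts = np.unique(np.asarray(pair_distances, dtype=np.int64), return_counts=True)
    # descending tail for the upper cutoff
    cum_desc = np.cumsum(counts[::-1])
    k = int(np.searchsorted(cum_desc, threshold))
    upper = int(values[::-1][min(k, len(values) - 1)])
    # ascending tail for the lower cutoff
    cum_asc = np.cumsum(counts)
    k = int(np.searchsorted(cum_asc, threshold))
    lower = int(values[min(k, len(values) - 1)])
    return InsertCutoffs(lower=lower, upper=upper, region=region)


def _pair_orientation(
    left_reverse: bool, right_reverse: bool
) -> str:
    left = "-" if left_reverse else "+"
    right = "-" if right_reverse else "+"
    return left + right


def _in_regions(tree, start: int, end: int) -> bool:
    return tree is not None and bool(tree.overlap(start, end))


def _region_trees(exclude: Iterable[tuple[str, int, int]] | None):
    if not exclude:
        return {}
    from intervaltree import IntervalTree

    trees: dict[str, "IntervalTree"] = {}
    for chrom, s, e in exclude:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return trees


def extract_discordant_pairs(
    alignments,
    cutoffs: InsertCutoffs,
    exclude: Iterable[tuple[str, int, int]] | None = None,
    sample_id: str = "sample",
    mq_min: int = 0,
) -> list[DiscordantPair]:
    """DPs from a pysam.AlignmentFile: inter-chromosomal, mis-oriented, or
    distance outside [lower, upper].  Duplicates and pairs touching excluded
    regions are dropped.  ``mq_min`` is a configurable MQ floor (default 0:
    no pair is dropped for mapping quality alone)."""
    so = alignments.header.get("HD", {}).get("SO")
    if so != "coordinate":
        raise FormatError(f"alignments must be coordinate-sorted (SO={so!r})")
    trees = _region_trees(exclude)
    out: list[DiscordantPair] = []
    for read in alignments.fetch(until_eof=True):
        if (
            not read.is_paired
            or read.is_unmapped
            or read.mate_is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or not read.is_read1
        ):
            continue
        if read.mapping_quality < mq_min:
            continue
        rlen = read.query_length or (read.reference_end - read.reference_start)
        if read.reference_name != read.next_reference_name:
            pair = DiscordantPair(
                chrom=read.reference_name,
                start=read.reference_start,
                end=read.reference_end,
                mate_chrom=read.next_reference_name,
                orientation="inter",
                mapq=read.mapping_quality,
                sample_id=sample_id,
                mate_start=read.next_reference_start,
            )
        else:
            mate_start = read.next_reference_start
            mate_end = mate_start + rlen  # mate length approximated by read's
            if read.reference_start <= mate_start:
                left_rev, right_rev = read.is_reverse, read.mate_is_reverse
                span = (read.reference_start, max(read.reference_end, mate_end))
            else:
                left_rev, right_rev = read.mate_is_reverse, read.is_reverse
                span = (mate_start, max(mate_end, read.reference_end))
            orientation = _pair_orientation(left_rev, right_rev)
            distance = abs(read.template_length)
            if orientation == "+-" and cutoffs.lower <= distance <= cutoffs.upper:
                continue  # concordant
            pair = DiscordantPair(
                chrom=read.reference_name,
                start=span[0],
                end=max(span[1], span[0] + 1),
                mate_chrom=read.reference_name,
                orientation=orientation,
                mapq=read.mapping_quality,
                sample_id=sample_id,
                mate_start=mate_start,
            )
        tree = trees.get(pair.chrom)
        if tree is not None and _in_regions(tree, pair.start, pair.end):
            continue
        if pair.orientation == "inter":
            mtree = trees.get(pair.mate_chrom)
            if mtree is not None and _in_regions(
                mtree, pair.mate_start, pair.mate_start + 1
            ):
                continue
        out.append(pair)
    return out


def _cigar_ref_length(cigar: str) -> int:
    n = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MDN=X":
                n += int(num)
            num = ""
    return n


def _clip_blocks(cigartuples) -> list[int]:
    """Indices (0 = leading, 1 = trailing) of soft/hard-clipped blocks."""
    blocks = []
    if cigartuples and cigartuples[0][0] in (4, 5):
        blocks.append(0)
    if len(cigartuples) > 1 and cigartuples[-1][0] in (4, 5):
        blocks.append(1)
    return blocks


def extract_split_reads(
    alignments,
    decoys: frozenset[str] = DEFAULT_DECOYS,
    sample_id: str = "sample",
) -> list[SplitRead]:
    """SRs from primary alignments carrying an SA (supplementary) tag.

    Filters (applied silently): reads on decoy contigs, reads with more than
    one clipped part, reads whose alignment parts overlap on the same
    contig, and reads whose clipped part has more than one SA alignment.
    """
    out: list[SplitRead] = []
    for read in alignments.fetch(until_eof=True):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or not read.has_tag("SA")
        ):
            continue
        if read.reference_name in decoys:
            continue
        sa_entries = [e for e in read.get_tag("SA").split(";") if e]
        if len(sa_entries) != 1:
            continue  # clipped part with more than one alignment
        clips = _clip_blocks(read.cigartuples)
        if len(clips) != 1:
            continue  # more than one clipped part (or none)
        sa_chrom, sa_pos, sa_strand, sa_cigar, sa_mapq, _nm = sa_entries[0].split(",")
        if sa_chrom in decoys:
            continue
        sa_start = int(sa_pos) - 1
        sa_end = sa_start + _cigar_ref_length(sa_cigar)
        p_start, p_end = read.reference_start, read.reference_end
        if sa_chrom == read.reference_name and min(p_end, sa_end) > max(
            p_start, sa_start
        ):
            continue  # overlapping alignment parts
        clip_side = "5p" if clips[0] == 0 else "3p"
        primary_strand = "-" if read.is_reverse else "+"
        if sa_chrom != read.reference_name:
            orientation = "inter"
        elif primary_strand != sa_strand:
            orientation = primary_strand * 2  # strand switch: inversion-type
        else:
            # same-strand split: deletion (clip toward the gap) or
            # duplication (clip pointing back) signature by part order
            if (p_start <= sa_start) == (clip_side == "3p"):
                orientation = "+-"
            else:
                orientation = "-+"
        out.append(
            SplitRead(
                primary_chrom=read.reference_name,
                primary_start=p_start,
                primary_end=p_end,
                clipped_chrom=sa_chrom,
                clipped_start=sa_start,
                clipped_end=sa_end,
                clip_side=clip_side,
                orientation=orientation,
                mapq=read.mapping_quality,
                sample_id=sample_id,
            )
        )
    return out


EXCLUDE_DEPTH = 300.0


def build_excluded_regions(
    track: CoverageTrack, threshold: float = EXCLUDE_DEPTH
) -> list[tuple[str, int, int]]:
    """Maximal intervals whose depth exceeds ``threshold`` (default 300x)."""
    out: list[tuple[str, int, int]] = []
    bs = track.bin_size
    for chrom, arr in track.depth.items():
        hot = arr > threshold
        if not hot.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], hot, [False]))))
        for s_bin, e_bin in zip(edges[::2], edges[1::2]):
            out.append((chrom, int(s_bin) * bs, int(e_bin) * bs))
    return out


# ---- evidence table serialization -------------------------------------

DP_COLUMNS = [f.name for f in fields(DiscordantPair)]
SR_COLUMNS = [f.name for f in fields(SplitRead)]


def write_dp_table(pairs: Iterable[DiscordantPair], path: str | Path, index: bool = False) -> None:
    df = pd.DataFrame([vars(p) if not hasattr(p, "__dataclass_fields__") else
                       {f: getattr(p, f) for f in DP_COLUMNS} for p in pairs],
                      columns=DP_COLUMNS)
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    _write_table(df, path, index)


def read_dp_table(path: str | Path) -> list[DiscordantPair]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "mate_chrom": str})
    return [DiscordantPair(**row) for row in df.to_dict("records")]


def write_sr_table(reads: Iterable[SplitRead], path: str | Path, index: bool = False) -> None:
    df = pd.DataFrame([{f: getattr(r, f) for f in SR_COLUMNS} for r in reads],
                      columns=SR_COLUMNS)
    df = df.sort_values(["primary_chrom", "primary_start"]).reset_index(drop=True)
    _write_table(df, path, index)


def read_sr_table(path: str | Path) -> list[SplitRead]:
    df = pd.read_csv(
        path, sep="\t", dtype={"primary_chrom": str, "clipped_chrom": str}
    )
    return [SplitRead(**row) for row in df.to_dict("records")]


def _write_table(df: pd.DataFrame, path: str | Path, index: bool) -> None:
    path = str(path)
    if index or path.endswith(".gz"):
        # block-compressed + coordinate-indexed via htslib
        import pysam

        plain = path[:-3] if path.endswith(".gz") else path
        df.to_csv(plain, sep="\t", index=False)
        pysam.tabix_compress(plain, plain + ".gz", force=True)
        Path(plain).unlink()
        pysam.tabix_index(
            plain + ".gz", seq_col=0, start_col=1, end_col=2, force=True,
            line_skip=1,
        )
    else:
        df.to_csv(path, sep="\t", index=False)


def write_excluded_bed(regions: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in regions:
            fh.write(f"{chrom}\t{s}\t{e}\n")
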