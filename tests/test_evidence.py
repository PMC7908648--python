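"""Evidence extraction: insert cutoffs, DP/SR filters, excluded regions."""

import numpy as np
import pysam
import pytest

from svtriage.coverage import CoverageTrack
from svtriage.evidence import (
    DiscordantPair,
    InsertCutoffs,
    SplitRead,
    build_excluded_regions,
    compute_insert_cutoffs,
    extract_discordant_pairs,
    extract_split_reads,
    read_dp_table,
    read_sr_table,
    write_dp_table,
    write_sr_table,
)
from svtriage.genome import EstimationError, FormatError

from conftest import write_sam


def brute_force_upper(distances, region_length, pairs_per_mb=100):
    """Independent oracle: scan distinct distances descending, summing
    counts, until the per-Mb tail count reaches the threshold."""
    threshold = pairs_per_mb * region_length / 1e6
    total = 0
    for d in sorted(set(distances), reverse=True):
        total += sum(1 for x in distances if x == d)
        if total >= threshold:
            return d
    return min(distances)


def brute_force_lower(distances, region_length, pairs_per_mb=100):
    threshold = pairs_per_mb * region_length / 1e6
    total = 0
    for d in sorted(set(distances)):
        total += sum(1 for x in distances if x == d)
        if total >= threshold:
            return d
    return max(distances)


class TestInsertCutoffs:
    def test_degenerate_single_value(self):
        cutoffs = compute_insert_cutoffs([450] * 4_000_000, 4_000_000)
        assert (cutoffs.lower, cutoffs.upper) == (450, 450)

    def test_tail_counts_against_brute_force(self):
        # 10,000 distances over 1 Mb with exactly 100 values >= 600
        # and exactly 100 values <= 200
        rng = np.random.default_rng(0)
        body = rng.integers(201, 600, size=9_800, endpoint=False).tolist()
        upper_tail = [600] * 40 + rng.integers(601, 900, size=60).tolist()
        lower_tail = [200] * 40 + rng.integers(50, 200, size=60).tolist()
        distances = body + upper_tail + lower_tail
        c = compute_insert_cutoffs(distances, 1_000_000)
        assert c.upper == 600 == brute_force_upper(distances, 1_000_000)
        assert c.lower == 200 == brute_force_lower(distances, 1_000_000)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_oracle_on_random_input(self, seed):
        rng = np.random.default_rng(seed)
        distances = rng.normal(400, 80, size=20_000).astype(int).tolist()
        c = compute_insert_cutoffs(distances, 2_000_000)
        assert c.upper == brute_force_upper(distances, 2_000_000)
        assert c.lower == brute_force_lower(distances, 2_000_000)

    def test_invariant_to_input_ordering(self):
        rng = np.random.default_rng(5)
        distances = rng.integers(100, 1000, size=5_000).tolist()
        a = compute_insert_cutoffs(distances, 1_000_000)
        rng.shuffle(distances)
        b = compute_insert_cutoffs(distances, 1_000_000)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_too_few_pairs_names_count(self):
        with pytest.raises(EstimationError, match="7"):
            compute_insert_cutoffs([400] * 7, 1_000_000)

    def test_cutoffs_must_be_ordered(self):
        with pytest.raises(EstimationError):
            InsertCutoffs(lower=600, upper=200)


def sam_pair(name, chrom, pos, mate_pos, tlen, flag=97, mapq=60, mate_chrom="="):
    seq = "A" * 100
    return (
        f"{name}\t{flag}\t{chrom}\t{pos}\t{mapq}\t100M\t{mate_chrom}\t{mate_pos}"
        f"\t{tlen}\t{seq}\t*"
    )


class TestDiscordantPairs:
    CUTOFFS = InsertCutoffs(lower=200, upper=600)

    def _extract(self, tmp_path, reads, **kw):
        sam = write_sam(tmp_path / "in.sam", reads)
        with pysam.AlignmentFile(str(sam)) as af:
            return extract_discordant_pairs(af, self.CUTOFFS, **kw)

    def test_proper_pair_within_cutoffs_not_returned(self, tmp_path):
        # FR pair, distance 400: concordant
        reads = [sam_pair("p1", "1", 1000, 1300, 400, flag=99)]
        assert self._extract(tmp_path, reads) == []

    def test_long_distance_pair_returned(self, tmp_path):
        reads = [sam_pair("p1", "1", 1000, 5900, 5000, flag=99)]
        (pair,) = self._extract(tmp_path, reads)
        assert pair.orientation == "+-"
        assert pair.start == 999  # SAM is 1-based, records are 0-based
        assert pair.end == 5999

    def test_everted_pair_returned_despite_short_distance(self, tmp_path):
        # leftmost read reverse, rightmost forward: duplication signature
        flag = 0x1 | 0x10 | 0x40  # paired, read reverse, first
        reads = [sam_pair("p1", "1", 1000, 1300, 400, flag=flag)]
        (pair,) = self._extract(tmp_path, reads)
        assert pair.orientation == "-+"

    def test_interchromosomal_pair_returned(self, tmp_path):
        reads = [sam_pair("p1", "1", 1000, 5000, 0, mate_chrom="2")]
        (pair,) = self._extract(tmp_path, reads)
        assert pair.orientation == "inter"
        assert pair.mate_chrom == "2"

    def test_duplicates_dropped(self, tmp_path):
        flag = 99 | 0x400
        reads = [sam_pair("p1", "1", 1000, 5900, 5000, flag=flag)]
        assert self._extract(tmp_path, reads) == []

    def test_excluded_region_dropped(self, tmp_path):
        reads = [sam_pair("p1", "1", 1000, 5900, 5000, flag=99)]
        pairs = self._extract(tmp_path, reads, exclude=[("1", 0, 10_000)])
        assert pairs == []

    def test_unsorted_input_rejected(self, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:queryname\n@SQ\tSN:1\tLN:1000000\n"
        )
        with pysam.AlignmentFile(str(sam)) as af:
            with pytest.raises(FormatError):
                extract_discordant_pairs(af, self.CUTOFFS)


def sam_split(name, chrom, pos, cigar, sa, flag=0, mapq=60):
    seq = "A" * 150
    return (
        f"{name}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*"
        f"\tSA:Z:{sa}"
    )


class TestSplitReads:
    def _extract(self, tmp_path, reads, **kw):
        contigs = (("1", 1_000_000), ("2", 1_000_000), ("hs37d5", 35_477_943))
        sam = write_sam(tmp_path / "in.sam", reads, contigs)
        with pysam.AlignmentFile(str(sam)) as af:
            return extract_split_reads(af, **kw)

    def test_deletion_split_flanks_deleted_interval(self, tmp_path):
        # 75 bases align ending at the 5' breakpoint, 75 clipped bases
        # align starting at the 3' breakpoint: base-pair precision
        reads = [sam_split("s1", "1", 9_926, "75M75S", "1,12001,+,75S75M,60,0")]
        (sr,) = self._extract(tmp_path, reads)
        assert (sr.primary_start, sr.primary_end) == (9_925, 10_000)
        assert (sr.clipped_start, sr.clipped_end) == (12_000, 12_075)
        assert sr.clip_side == "3p"
        assert sr.orientation == "+-"

    def test_two_clipped_parts_discarded(self, tmp_path):
        reads = [sam_split("s1", "1", 1000, "20S110M20S", "1,5000,+,130S20M,60,0")]
        assert self._extract(tmp_path, reads) == []

    def test_overlapping_alignment_parts_discarded(self, tmp_path):
        # supplementary starts 5 bp before the primary ends
        reads = [sam_split("s1", "1", 1001, "75M75S", "1,1071,+,75S75M,60,0")]
        assert self._extract(tmp_path, reads) == []

    def test_multiple_sa_alignments_discarded(self, tmp_path):
        sa = "1,5000,+,75S75M,60,0;1,9000,+,75S75M,30,0"
        reads = [sam_split("s1", "1", 1001, "75M75S", sa)]
        assert self._extract(tmp_path, reads) == []

    def test_decoy_contigs_discarded(self, tmp_path):
        reads = [
            sam_split("s1", "hs37d5", 1001, "75M75S", "1,9000,+,75S75M,60,0"),
            sam_split("s2", "1", 1001, "75M75S", "hs37d5,9000,+,75S75M,60,0"),
        ]
        assert self._extract(tmp_path, reads) == []

    def test_inversion_split_has_strand_switch_orientation(self, tmp_path):
        reads = [sam_split("s1", "1", 1001, "75M75S", "1,9000,-,75S75M,60,0")]
        (sr,) = self._extract(tmp_path, reads)
        assert sr.orientation == "++"


class TestExcludedRegions:
    def test_uniform_track_yields_nothing(self):
        track = CoverageTrack({"1": np.full(100, 30.0)}, bin_size=100)
        assert build_excluded_regions(track) == []

    def test_plateau_is_recovered_exactly(self):
        depth = np.full(1000, 30.0)
        depth[200:300] = 500.0  # 10-kb plateau at 500x
        track = CoverageTrack({"1": depth}, bin_size=100)
        assert build_excluded_regions(track) == [("1", 20_000, 30_000)]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_spiky_track_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        depth = rng.gamma(2.0, 100.0, size=500)
        track = CoverageTrack({"1": depth}, bin_size=10)
        got = build_excluded_regions(track)
        # oracle: threshold every bin, then merge adjacent hot bins
        hot = [i for i, d in enumerate(depth) if d > 300]
        expected = []
        for i in hot:
            if expected and expected[-1][2] == i * 10:
                expected[-1] = ("1", expected[-1][1], (i + 1) * 10)
            else:
                expected.append(("1", i * 10, (i + 1) * 10))
        assert got == expected


class TestEvidenceRoundTrip:
    def test_dp_records_round_trip_losslessly(self, tmp_path, sample_evidence):
        evidence, _ = sample_evidence
        path = tmp_path / "dp.tsv"
        write_dp_table(evidence.dps, path)
        assert sorted(read_dp_table(path), key=lambda d: (d.start, d.end)) == sorted(
            evidence.dps, key=lambda d: (d.start, d.end)
        )

    def test_sr_records_round_trip_losslessly(self, tmp_path, sample_evidence):
        evidence, _ = sample_evidence
        path = tmp_path / "sr.tsv"
        write_sr_table(evidence.srs, path)
        assert sorted(
            read_sr_table(path), key=lambda s: (s.primary_start, s.clipped_start)
        ) == sorted(evidence.srs, key=lambda s: (s.primary_start, s.clipped_start))

    def test_block_compressed_output_readable(self, tmp_path, sample_evidence):
        evidence, _ = sample_evidence
        path = tmp_path / "dp.tsv.gz"
        write_dp_table(evidence.dps, path)
        assert path.exists() and (tmp_path / "dp.tsv.gz.tbi").exists()
        assert len(read_dp_table(path)) == len(evidence.dps)
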