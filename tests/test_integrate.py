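"""Call splitting, cross-annotation, merging and mixed-support splitting."""

import numpy as np
import pytest

from svtriage.coverage import DocMetrics
from svtriage.evidence import DiscordantPair
from svtriage.integrate import (
    CandidateCall,
    EvidenceCounts,
    IntegratedVariant,
    SampleCall,
    annotate_doc_call_with_read_evidence,
    breakpoint_evidence_window,
    genotype_variant,
    merge_doc_calls_across_samples,
    merge_doc_with_srdp,
    mergeable,
    split_at_masked_regions,
    split_mixed_support,
)


def call(start, end, svtype="DEL", caller="doc", chrom="1", samples=None):
    return CandidateCall(
        chrom=chrom, start=start, end=end, svtype=svtype, caller=caller,
        samples=samples or {},
    )


class TestMaskSplitting:
    def test_mask_inside_call_splits_in_two(self):
        parts = split_at_masked_regions(call(100, 900), [(400, 600)])
        assert [(p.start, p.end) for p in parts] == [(100, 400), (600, 900)]

    def test_disjoint_mask_leaves_call_unchanged(self):
        c = call(100, 900)
        assert split_at_masked_regions(c, [(2000, 3000)]) == [c]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_set_difference(self, seed):
        rng = np.random.default_rng(seed)
        start, end = sorted(rng.integers(0, 500, size=2))
        if start == end:
            end += 1
        edges = np.sort(rng.integers(0, 500, size=6))
        mask = [
            (int(a), int(b)) for a, b in zip(edges[::2], edges[1::2]) if a < b
        ]
        parts = split_at_masked_regions(call(int(start), int(end)), mask)
        # oracle: per-base membership, then reconstruct intervals
        bases = set(range(start, end))
        for a, b in mask:
            bases -= set(range(a, b))
        got = set()
        for p in parts:
            got |= set(range(p.start, p.end))
        assert got == bases
        # and no part overlaps the mask
        for p in parts:
            for a, b in mask:
                assert min(p.end, b) <= max(p.start, a)


class TestBreakpointWindows:
    @pytest.mark.parametrize(
        "length,outer,inner",
        [(50_000, 1000, 5000), (1_000_000, 5000, 5000), (2_000, 1000, 1000),
         (200_000, 2000, 5000), (400, 1000, 200)],
    )
    def test_window_formula(self, length, outer, inner):
        assert breakpoint_evidence_window(length) == (outer, inner)


def dp(start, end, orientation="+-", sample="S1", chrom="1"):
    return DiscordantPair(
        chrom=chrom, start=start, end=end, mate_chrom=chrom,
        orientation=orientation, mapq=60, sample_id=sample,
    )


class TestDocReadAnnotation:
    def test_inward_pairs_straddling_breakpoints_counted(self):
        c = call(10_000, 20_000, "DEL")
        dps = [dp(9_800 + i, 20_200 + i) for i in range(5)]
        counts = annotate_doc_call_with_read_evidence(c, dps, [])
        assert counts["S1"].dp == 5

    def test_everted_orientation_not_counted_for_deletion(self):
        c = call(10_000, 20_000, "DEL")
        dps = [dp(9_800, 20_200, orientation="-+") for _ in range(5)]
        assert annotate_doc_call_with_read_evidence(c, dps, []) == {}

    def test_pairs_outside_windows_not_counted(self):
        c = call(10_000, 20_000, "DEL")  # outer 1000, inner 5000
        dps = [dp(8_000, 20_200)]  # 5' end beyond the outer limit
        assert annotate_doc_call_with_read_evidence(c, dps, []) == {}

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_match_window_orientation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c = call(50_000, 150_000, "DUP")
        outer, inner = breakpoint_evidence_window(c.length)
        dps = []
        for _ in range(200):
            s = int(rng.integers(40_000, 60_000))
            e = int(rng.integers(140_000, 160_000))
            o = str(rng.choice(["+-", "-+", "++"]))
            dps.append(dp(s, e, orientation=o))
        counts = annotate_doc_call_with_read_evidence(c, dps, [])
        expected = sum(
            1
            for d in dps
            if d.orientation == "-+"
            and c.start - outer <= d.start <= c.start + inner
            and c.end - inner <= d.end <= c.end + outer
        )
        assert counts.get("S1", EvidenceCounts()).dp == expected


def brute_mergeable(a, b):
    """Literal transcription of the merge rule for cross-checking."""
    if a.chrom != b.chrom:
        return False
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    ra = ov / (a.end - a.start)
    rb = ov / (b.end - b.start)
    residues_ok = (a.end - a.start - ov) <= 200 and (b.end - b.start - ov) <= 200
    return (ra >= 0.7 and rb >= 0.7) or residues_ok


class TestMergeable:
    def test_reciprocal_overlap_clause(self):
        assert mergeable(call(0, 1000), call(150, 1150))  # 85% / 85%

    def test_insufficient_overlap(self):
        assert not mergeable(call(0, 1000), call(900, 5000))

    def test_residue_clause(self):
        assert mergeable(call(0, 10_000), call(150, 10_100))

    def test_different_event_class_never_merges(self):
        assert not mergeable(call(0, 1000, "DEL"), call(0, 1000, "DUP"))
        assert not mergeable(call(0, 1000, "INV"), call(0, 1000, "DEL"))

    @pytest.mark.parametrize("seed", range(20))
    def test_symmetric_and_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        sa, sb = (int(x) for x in rng.integers(0, 5000, size=2))
        la, lb = (int(x) for x in rng.integers(1, 3000, size=2))
        a, b = call(sa, sa + la), call(sb, sb + lb)
        assert mergeable(a, b) == mergeable(b, a) == brute_mergeable(a, b)


class TestCrossSampleMerge:
    def test_identical_call_in_three_samples_collapses(self):
        calls = [
            call(1000, 2000, samples={s: EvidenceCounts(dp=3)})
            for s in ("A", "B", "C")
        ]
        merged = merge_doc_calls_across_samples(calls)
        assert len(merged) == 1
        assert set(merged[0].samples) == {"A", "B", "C"}
        assert (merged[0].start, merged[0].end) == (1000, 2000)

    def test_non_mergeable_calls_stay_separate(self):
        merged = merge_doc_calls_across_samples(
            [call(0, 1000), call(5000, 9000)]
        )
        assert len(merged) == 2

    def test_merged_coordinates_are_averages(self):
        merged = merge_doc_calls_across_samples(
            [call(1000, 2000, samples={"A": EvidenceCounts()}),
             call(1100, 2100, samples={"B": EvidenceCounts()})]
        )
        assert (merged[0].start, merged[0].end) == (1050, 2050)

    def test_merging_is_idempotent(self):
        calls = [call(1000, 2000, samples={"A": EvidenceCounts(dp=2)}),
                 call(1050, 2020, samples={"B": EvidenceCounts(dp=4)}),
                 call(9000, 12_000, samples={"A": EvidenceCounts(dp=1)})]
        once = merge_doc_calls_across_samples(calls)
        twice = merge_doc_calls_across_samples(once)
        assert [(c.start, c.end, c.samples) for c in twice] == [
            (c.start, c.end, c.samples) for c in once
        ]

    @pytest.mark.parametrize("seed", range(10))
    def test_components_match_graph_closure_oracle(self, seed):
        import networkx as nx

        rng = np.random.default_rng(seed)
        calls = []
        for _ in range(30):
            s = int(rng.integers(0, 50_000))
            calls.append(call(s, s + int(rng.integers(300, 5000))))
        merged = merge_doc_calls_across_samples(calls)
        g = nx.Graph()
        g.add_nodes_from(range(len(calls)))
        for i in range(len(calls)):
            for j in range(i + 1, len(calls)):
                if brute_mergeable(calls[i], calls[j]):
                    g.add_edge(i, j)
        assert len(merged) == nx.number_connected_components(g)


class TestDocSrdpFusion:
    def test_srdp_coordinates_preserved(self):
        d = call(10_000, 20_050, "DEL", "doc", samples={"S1": EvidenceCounts()})
        s = call(10_012, 20_001, "DEL", "srdp",
                 samples={"S1": EvidenceCounts(sr=4, dp=5)})
        (v,) = merge_doc_with_srdp([d], [s])
        assert (v.start, v.end) == (10_012, 20_001)
        assert v.callers == {"doc", "srdp"}
        assert v.samples["S1"].counts.su == 9

    def test_doc_only_call_passes_through(self):
        d = call(10_000, 20_000, "DUP", "doc", samples={"S1": EvidenceCounts()})
        (v,) = merge_doc_with_srdp([d], [])
        assert v.callers == {"doc"}
        assert (v.start, v.end) == (10_000, 20_000)

    def test_best_reciprocal_overlap_wins(self):
        d1 = call(10_000, 20_000, "DEL", "doc")
        d2 = call(10_000, 19_000, "DEL", "doc")
        s = call(10_000, 19_900, "DEL", "srdp")
        out = merge_doc_with_srdp([d1, d2], [s])
        fused = [v for v in out if v.callers == {"doc", "srdp"}]
        assert len(fused) == 1
        assert len(out) == 2  # the other doc call remains unmatched

    @pytest.mark.parametrize("seed", range(5))
    def test_fusion_matches_bipartite_oracle(self, seed):
        rng = np.random.default_rng(seed)
        docs, srdps = [], []
        for k in range(15):
            s = int(rng.integers(0, 100_000))
            docs.append(call(s, s + int(rng.integers(1000, 8000)), "DEL", "doc"))
            t = int(rng.integers(0, 100_000))
            srdps.append(call(t, t + int(rng.integers(1000, 8000)), "DEL", "srdp"))
        out = merge_doc_with_srdp(docs, srdps)
        n_fused = sum(1 for v in out if v.callers == {"doc", "srdp"})
        # oracle: greedy max-overlap matching over brute-force pairs
        pairs = []
        for i, d in enumerate(docs):
            for j, s in enumerate(srdps):
                if brute_mergeable(d, s):
                    ov = max(0, min(d.end, s.end) - max(d.start, s.start))
                    score = min(ov / d.length, ov / s.length)
                    pairs.append((-score, d.start, s.start, i, j))
        used_d, used_s = set(), set()
        expected = 0
        for _, _, _, i, j in sorted(pairs):
            if i not in used_d and j not in used_s:
                used_d.add(i)
                used_s.add(j)
                expected += 1
        assert n_fused == expected
        assert len(out) == len(docs) + len(srdps) - expected


def metrics(dra):
    return DocMetrics(doc=30 * dra, dra=dra, drf=dra, mq_restricted=True)


def joint_variant(sample_dras, counts=None):
    samples = {}
    for sid, dra in sample_dras.items():
        samples[sid] = SampleCall(
            counts=(counts or {}).get(sid, EvidenceCounts()),
            doc=metrics(dra),
        )
    v = IntegratedVariant(
        chrom="1", start=10_000, end=20_000, svtype="DEL",
        callers=frozenset({"doc"}), samples=samples,
    )
    genotype_variant(v)
    return v


class TestMixedSupportSplitting:
    def test_uniform_doc_support_stays_one_variant(self):
        v = joint_variant({"A": 0.5, "B": 0.5})
        assert split_mixed_support(v) == [v]

    def test_mixed_support_splits_into_cnv_and_neutral(self):
        v = joint_variant(
            {"A": 0.5, "B": 1.0},
            counts={"B": EvidenceCounts(sr=4, dp=4)},
        )
        parts = split_mixed_support(v)
        assert len(parts) == 2
        cnv, neutral = parts
        assert cnv.is_cnv and set(cnv.samples) == {"A"}
        assert not neutral.is_cnv and set(neutral.samples) == {"B"}

    def test_all_copy_neutral_stays_one_variant(self):
        v = joint_variant(
            {"A": 1.0, "B": 1.0},
            counts={"A": EvidenceCounts(sr=3), "B": EvidenceCounts(dp=3)},
        )
        parts = split_mixed_support(v)
        assert len(parts) == 1
        assert not parts[0].is_cnv
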