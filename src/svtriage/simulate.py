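"""Synthetic evidence generator: the package's test bed.

Simulates the evidence a short-read WGS pipeline extracts — binned coverage
and mapping-quality tracks, discordant pairs and split reads at variant
breakpoints — directly at the evidence level rather than at the read level.
This exercises every downstream formula (DOC ratios, genotyping, merging,
tranches, population frequencies, concordance) without an aligner.

Study-condition defaults: 30x depth (clinical WGS runs at 30-40x), 150-bp
reads and ~400 +/- 80 bp fragments (HiSeq X paired-end), 100-bp coverage
bins (the DOC caller's window size), planted variants non-overlapping with
5-kb flanking spacing.  What the generator does NOT emulate: GC-coverage
bias, read error profiles, and repeat-mediated evidence loss beyond the
configurable low-MQ patches.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, GenomeCoverageEstimate
from .evidence import EXPECTED_ORIENTATION, DiscordantPair, SplitRead
from .genome import GenomeLayout, SvtriageError
from .integrate import CandidateCall, EvidenceCounts
from .popfreq import ControlCohortDB, ControlVariant

MIN_SPACING = 5_000

COPY_FACTOR = {
    ("DEL", "0/1"): 0.5,
    ("DEL", "1/1"): 0.0,
    ("DUP", "0/1"): 1.5,
    ("DUP", "1/1"): 2.0,
    ("INV", "0/1"): 1.0,
    ("INV", "1/1"): 1.0,
}


@dataclass(frozen=True)
class PlantedVariant:
    chrom: str
    start: int
    end: int
    svtype: str  # DEL / DUP / INV
    genotype: str = "0/1"
    af: float = 0.0  # cohort allele frequency when simulating controls

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimulationConfig:
    contigs: dict[str, int]
    variants: tuple[PlantedVariant, ...] = ()
    depth: float = 30.0
    read_length: int = 150
    fragment_mean: float = 400.0
    fragment_sd: float = 80.0
    bin_size: int = 100
    mq_default: float = 60.0
    #: (chrom, start, end, mq): regions emulating ambiguous mapping; depth
    #: stays but SR/DP evidence is suppressed and MQ drops
    low_mq_patches: tuple[tuple[str, int, int, float], ...] = ()
    #: background DP/SR noise records per Mb (mapping artifacts)
    noise_per_mb: float = 2.0
    seed: int = 0

    def __post_init__(self):
        by_chrom: dict[str, list[PlantedVariant]] = {}
        for v in self.variants:
            if v.end <= v.start:
                raise SvtriageError(f"empty planted variant {v}")
            if v.end > self.contigs.get(v.chrom, 0):
                raise SvtriageError(f"variant {v} outside contig")
            by_chrom.setdefault(v.chrom, []).append(v)
        for chrom, vs in by_chrom.items():
            vs = sorted(vs, key=lambda v: v.start)
            for a, b in zip(vs, vs[1:]):
                if b.start - a.end < MIN_SPACING:
                    raise SvtriageError(
                        f"planted variants {a} and {b} closer than "
                        f"{MIN_SPACING} bp"
                    )

    def layout(self) -> GenomeLayout:
        """Toy layout whose baseline windows are the variant-free gaps.

        Mirrors the real design's choice of baseline windows clear of
        copy-altered regions (there: centromere/telomere-free 10-Mb
        windows); the median across gap windows is robust to any residual
        overlap.
        """
        margin = 1_000
        min_window = 5_000
        windows: list[tuple[str, int, int]] = []
        for chrom, length in self.contigs.items():
            vs = sorted(
                (v for v in self.variants if v.chrom == chrom),
                key=lambda v: v.start,
            )
            edges = [0]
            for v in vs:
                edges.extend([v.start, v.end])
            edges.append(length)
            for gap_start, gap_end in zip(edges[::2], edges[1::2]):
                s, e = gap_start + margin, gap_end - margin
                if e - s >= min_window:
                    windows.append((chrom, s, e))
        base = GenomeLayout.toy(self.contigs)
        if windows:
            base = replace(base, autosome_windows=tuple(windows))
        return base


@dataclass
class EvidenceSet:
    sample_id: str
    track: CoverageTrack
    dps: list[DiscordantPair]
    srs: list[SplitRead]


def _rng(config: SimulationConfig, *salt) -> np.random.Generator:
    """Independent, reproducible stream per (seed, salt)."""
    key = ":".join([str(config.seed), *map(str, salt)]).encode()
    digest = hashlib.sha256(key).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _copy_profile(config: SimulationConfig, genotypes: dict[int, str]):
    """Per-bin copy factor arrays from the planted variants."""
    bs = config.bin_size
    factors = {
        c: np.ones((n + bs - 1) // bs) for c, n in config.contigs.items()
    }
    for i, v in enumerate(config.variants):
        gt = genotypes.get(i)
        if gt is None or gt == "0/0":
            continue
        f = COPY_FACTOR.get((v.svtype, gt), 1.0)
        factors[v.chrom][v.start // bs : (v.end - 1) // bs + 1] = f
    return factors


def _mq_track(config: SimulationConfig) -> dict[str, np.ndarray]:
    bs = config.bin_size
    mq = {
        c: np.full((n + bs - 1) // bs, config.mq_default)
        for c, n in config.contigs.items()
    }
    for chrom, s, e, value in config.low_mq_patches:
        mq[chrom][s // bs : (e - 1) // bs + 1] = value
    return mq


def _in_low_mq(config: SimulationConfig, chrom: str, pos: int) -> bool:
    return any(
        c == chrom and s <= pos < e for c, s, e, _ in config.low_mq_patches
    )


#: expected supporting reads per unit depth and allele fraction
DP_YIELD = 1.0
SR_YIELD = 0.6


def simulate_sample(
    config: SimulationConfig,
    genotypes: dict[int, str] | None = None,
    sample_id: str = "S1",
) -> tuple[EvidenceSet, pd.DataFrame]:
    """Evidence for one sample plus its truth table.

    ``genotypes`` maps planted-variant index to genotype (default: every
    variant at its configured genotype).  Coverage reflects the copy state
    (het DEL ~ 0.5x, hom DEL ~ 0x, het DUP ~ 1.5x) with Poisson read-start
    noise; DP/SR records appear at breakpoints with counts proportional to
    depth and allele fraction and the orientation expected for the type,
    suppressed inside low-MQ patches.
    """
    if genotypes is None:
        genotypes = {i: v.genotype for i, v in enumerate(config.variants)}
    rng = _rng(config, "sample", sample_id)
    bs, rl = config.bin_size, config.read_length
    factors = _copy_profile(config, genotypes)
    depth = {}
    reads_per_bin = config.depth * bs / rl
    for chrom, f in factors.items():
        starts = rng.poisson(reads_per_bin * f)
        depth[chrom] = starts * (rl / bs)
    track = CoverageTrack(depth, _mq_track(config), bs)

    dps: list[DiscordantPair] = []
    srs: list[SplitRead] = []
    truth_rows = []
    for i, v in enumerate(config.variants):
        gt = genotypes.get(i)
        truth_rows.append(
            {
                "chrom": v.chrom, "start": v.start, "end": v.end,
                "svtype": v.svtype, "genotype": gt or "0/0",
                "length": v.length,
            }
        )
        if gt in (None, "0/0"):
            continue
        allele_fraction = 1.0 if gt == "1/1" else 0.5
        suppressed = _in_low_mq(config, v.chrom, v.start) or _in_low_mq(
            config, v.chrom, max(v.start, v.end - 1)
        )
        if suppressed:
            continue
        orientation = EXPECTED_ORIENTATION[v.svtype][0]
        n_dp = rng.poisson(DP_YIELD * config.depth * allele_fraction)
        n_sr = rng.poisson(SR_YIELD * config.depth * allele_fraction)
        for _ in range(n_dp):
            left_off = rng.integers(rl, int(config.fragment_mean))
            right_off = rng.integers(rl, int(config.fragment_mean))
            dps.append(
                DiscordantPair(
                    chrom=v.chrom,
                    start=max(0, v.start - int(left_off)),
                    end=min(config.contigs[v.chrom], v.end + int(right_off)),
                    mate_chrom=v.chrom,
                    orientation=orientation,
                    mapq=60,
                    sample_id=sample_id,
                )
            )
        for _ in range(n_sr):
            split = int(rng.integers(20, rl - 20))
            srs.append(
                SplitRead(
                    primary_chrom=v.chrom,
                    primary_start=max(0, v.start - split),
                    primary_end=v.start,
                    clipped_chrom=v.chrom,
                    clipped_start=v.end,
                    clipped_end=min(
                        config.contigs[v.chrom], v.end + (rl - split)
                    ),
                    clip_side="3p",
                    orientation=orientation,
                    mapq=60,
                    sample_id=sample_id,
                )
            )
    # background mapping-artifact noise, uniformly scattered
    for chrom, n in config.contigs.items():
        n_noise = rng.poisson(config.noise_per_mb * n / 1e6)
        for _ in range(n_noise):
            pos = int(rng.integers(0, max(1, n - 10_000)))
            span = int(rng.integers(1_000, 10_000))
            dps.append(
                DiscordantPair(
                    chrom=chrom,
                    start=pos,
                    end=min(n, pos + span),
                    mate_chrom=chrom,
                    orientation=str(rng.choice(["+-", "-+", "++", "--"])),
                    mapq=int(rng.integers(0, 61)),
                    sample_id=sample_id,
                )
            )
    dps.sort(key=lambda d: (d.chrom, d.start, d.end))
    srs.sort(key=lambda s: (s.primary_chrom, s.primary_start))
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "svtype", "genotype", "length"]
    )
    return EvidenceSet(sample_id, track, dps, srs), truth


# ---- cohort ------------------------------------------------------------

DRA_NOISE_SD = 0.08  # per-1-kb-interval DRA noise in well-behaved regions


def simulate_cohort(
    config: SimulationConfig,
    n_samples: int,
    dra_noise_sd: float = DRA_NOISE_SD,
) -> tuple[ControlCohortDB, np.ndarray]:
    """Control-cohort evidence database with carriers drawn binomially from
    each planted variant's allele frequency.

    Returns the database and the carrier indicator matrix
    (n_variants, n_samples).  Carriers are heterozygous; the DB holds
    breakpoint SR/DP counts, per-sample 1-kb DRA summaries, and the
    Pass/High control variant set with carrier counts.
    """
    if any(not 0 <= v.af <= 1 for v in config.variants):
        raise SvtriageError("allele frequencies must be in [0, 1]")
    rng = _rng(config, "cohort", n_samples)
    n_var = len(config.variants)
    carriers = np.zeros((n_var, n_samples), dtype=bool)
    for i, v in enumerate(config.variants):
        carriers[i] = rng.random(n_samples) < v.af

    bp_rows = []
    control_variants = []
    for i, v in enumerate(config.variants):
        n_carr = int(carriers[i].sum())
        if n_carr:
            orientation = EXPECTED_ORIENTATION[v.svtype][0]
            for pos in (v.start, v.end):
                count = int(
                    rng.poisson(
                        (DP_YIELD + SR_YIELD) * config.depth * 0.5 * n_carr
                    )
                )
                bp_rows.append(
                    {
                        "chrom": v.chrom, "pos": pos,
                        "orientation": orientation,
                        "count": count, "sample_count": n_carr,
                    }
                )
        control_variants.append(
            ControlVariant(
                chrom=v.chrom, start=v.start, end=v.end, svtype=v.svtype,
                cnv=v.svtype in ("DEL", "DUP"), carriers=n_carr,
            )
        )
    breakpoints = pd.DataFrame(
        bp_rows, columns=["chrom", "pos", "orientation", "count", "sample_count"]
    )

    dra_bins: dict[str, np.ndarray] = {}
    for chrom, length in config.contigs.items():
        n_bins = (length + 999) // 1000
        mat = rng.normal(1.0, dra_noise_sd, size=(n_samples, n_bins))
        for i, v in enumerate(config.variants):
            if v.chrom != chrom or not carriers[i].any():
                continue
            f = COPY_FACTOR.get((v.svtype, "0/1"), 1.0)
            b0, b1 = v.start // 1000, (v.end - 1) // 1000 + 1
            idx = np.flatnonzero(carriers[i])
            mat[np.ix_(idx, np.arange(b0, b1))] = rng.normal(
                f, dra_noise_sd, size=(len(idx), b1 - b0)
            )
        dra_bins[chrom] = np.clip(mat, 0.0, None)

    db = ControlCohortDB(
        n_samples=n_samples,
        breakpoints=breakpoints,
        dra_bins=dra_bins,
        variants=control_variants,
    )
    return db, carriers


# ---- caller-style candidate calls --------------------------------------


def emit_candidate_calls(
    truth: pd.DataFrame,
    style: str,
    config: SimulationConfig,
    sample_id: str = "S1",
    jitter: float = 0.0,
    dropout: float = 0.0,
    evidence: EvidenceSet | None = None,
) -> list[CandidateCall]:
    """Caller-shaped candidate calls from a truth table.

    ``doc`` style mimics a read-depth caller: CNV types only, boundaries
    quantized to the 100-base DOC window after Gaussian jitter, no SR/DP
    counts.  ``srdp`` style mimics a split-read/discordant-pair caller:
    exact breakpoints with the sample's SR/DP support counts.  ``dropout``
    is the per-call omission probability (exercises single-caller paths).
    """
    if style not in ("doc", "srdp"):
        raise SvtriageError(f"unknown caller style {style!r}")
    rng = _rng(config, "calls", style, sample_id, jitter, dropout)
    out: list[CandidateCall] = []
    quantum = config.bin_size
    for row in truth.itertuples():
        if row.genotype in ("0/0", None):
            continue
        if style == "doc" and row.svtype not in ("DEL", "DUP"):
            continue
        if dropout and rng.random() < dropout:
            continue
        start, end = int(row.start), int(row.end)
        if style == "doc":
            if jitter:
                start += int(rng.normal(0, jitter))
                end += int(rng.normal(0, jitter))
            start = max(0, (start // quantum) * quantum)
            end = max(start + quantum, ((end + quantum - 1) // quantum) * quantum)
            counts = EvidenceCounts()
        else:
            sr = dp = 0
            if evidence is not None:
                for d in evidence.dps:
                    if (
                        d.chrom == row.chrom
                        and abs(d.start - start) < config.fragment_mean * 2
                        and abs(d.end - end) < config.fragment_mean * 2
                        and d.orientation in EXPECTED_ORIENTATION[row.svtype]
                    ):
                        dp += 1
                for s in evidence.srs:
                    if (
                        s.primary_chrom == row.chrom
                        and abs(s.primary_end - start) <= config.read_length
                        and abs(s.clipped_start - end) <= config.read_length
                    ):
                        sr += 1
            if sr == 0 and dp == 0:
                if evidence is not None:
                    continue  # caller sees no read support: no call
                af = 1.0 if row.genotype == "1/1" else 0.5
                dp = int(rng.poisson(DP_YIELD * config.depth * af))
                sr = int(rng.poisson(SR_YIELD * config.depth * af))
                if dp + sr == 0:
                    continue
            counts = EvidenceCounts(sr=sr, dp=dp)
        out.append(
            CandidateCall(
                chrom=row.chrom,
                start=start,
                end=end,
                svtype=row.svtype,
                caller=style,
                samples={sample_id: counts},
                precise=style == "srdp",
            )
        )
    return out


# ---- naive DOC segmenter -----------------------------------------------


def segment_doc_track(
    track: CoverageTrack,
    genome_est: GenomeCoverageEstimate,
    sample_id: str = "S1",
    smooth_bins: int = 5,
    min_bins: int = 5,
    max_gap_bins: int = 2,
) -> list[CandidateCall]:
    """Threshold-run segmentation of a DRA track into doc-style calls.

    A deliberately naive fixed-bin segmenter used only to turn simulated
    coverage tracks into read-depth-caller-shaped candidates: smoothed DRA
    runs below 0.8 become DEL candidates, runs above 1.2 become DUP
    candidates.  It is not a reimplementation of any published caller.
    """
    out: list[CandidateCall] = []
    bs = track.bin_size
    for chrom, arr in track.depth.items():
        baseline = genome_est.baseline(chrom)
        dra = arr / baseline
        if smooth_bins > 1:
            kernel = np.ones(smooth_bins)
            # normalise by actual kernel coverage so contig edges are unbiased
            dra = np.convolve(dra, kernel, mode="same") / np.convolve(
                np.ones_like(dra), kernel, mode="same"
            )
        state = np.where(dra < 0.8, -1, np.where(dra > 1.2, 1, 0))
        for target, svtype in ((-1, "DEL"), (1, "DUP")):
            hits = state == target
            # close gaps up to max_gap_bins
            idx = np.flatnonzero(hits)
            if len(idx) == 0:
                continue
            runs = []
            run_start = prev = idx[0]
            for k in idx[1:]:
                if k - prev <= max_gap_bins + 1:
                    prev = k
                else:
                    runs.append((run_start, prev))
                    run_start = prev = k
            runs.append((run_start, prev))
            for b0, b1 in runs:
                if b1 - b0 + 1 < min_bins:
                    continue
                out.append(
                    CandidateCall(
                        chrom=chrom,
                        start=int(b0) * bs,
                        end=(int(b1) + 1) * bs,
                        svtype=svtype,
                        caller="doc",
                        samples={sample_id: EvidenceCounts()},
                    )
                )
    out.sort(key=lambda c: (c.chrom, c.start, c.end))
    return out
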