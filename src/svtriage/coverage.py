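"""Depth-of-coverage tracks and DOC-derived CNV metrics.

The depth-of-coverage (DOC) of a candidate interval is normalised two ways:
DRA, the ratio to the genome-average depth (chromosome-appropriate baseline),
and DRF, the ratio to the mean depth of the two flanking regions of the same
length as the interval.  Both feed the CNV flag; the genotype is assigned
purely from DRA because split-read / discordant-pair fractions are unreliable
genotype indicators near repeats.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .genome import EstimationError, FormatError, GenomeLayout, round_to_half


class CoverageTrack:
    """Per-contig binned depth (and optionally mean mapping quality).

    Bins of ``bin_size`` bases tile each contig without gaps; the last bin
    may represent fewer bases.  Depth is the mean per-base depth within the
    bin; MQ is the mean Phred-scale mapping quality (0-60 for BWA MEM).
    """

    def __init__(
        self,
        depth: dict[str, np.ndarray],
        mq: dict[str, np.ndarray] | None = None,
        bin_size: int = 100,
    ):
        self.bin_size = int(bin_size)
        self.depth = {c: np.asarray(a, dtype=float) for c, a in depth.items()}
        self.mq = (
            {c: np.asarray(a, dtype=float) for c, a in mq.items()}
            if mq is not None
            else None
        )
        for c, a in self.depth.items():
            if np.any(a < 0):
                raise FormatError(f"negative depth on contig {c}")

    @property
    def contigs(self) -> list[str]:
        return list(self.depth)

    def contig_length(self, chrom: str) -> int:
        return len(self.depth[chrom]) * self.bin_size

    def _bin_weights(self, chrom: str, start: int, end: int):
        """Bin indices overlapping [start, end) and overlapped bases each."""
        bs = self.bin_size
        arr = self.depth[chrom]
        start = max(0, start)
        end = min(end, len(arr) * bs)
        if end <= start:
            return np.empty(0, dtype=int), np.empty(0)
        b0, b1 = start // bs, (end - 1) // bs + 1
        idx = np.arange(b0, b1)
        w = np.full(len(idx), float(bs))
        w[0] = min(end, (b0 + 1) * bs) - start
        w[-1] = end - max(start, (b1 - 1) * bs)
        if len(idx) == 1:
            w[0] = end - start
        return idx, w

    def mean_depth(
        self, chrom: str, start: int, end: int, mq_min: float | None = None
    ) -> float:
        """Base-weighted mean depth over [start, end); NaN if no bases
        (e.g. the interval lies outside the contig or no bin passes the
        MQ filter)."""
        idx, w = self._bin_weights(chrom, start, end)
        if len(idx) == 0:
            return float("nan")
        d = self.depth[chrom][idx]
        if mq_min is not None and self.mq is not None:
            keep = self.mq[chrom][idx] >= mq_min
            idx, w, d = idx[keep], w[keep], d[keep]
            if len(idx) == 0:
                return float("nan")
        return float(np.average(d, weights=w))

    def qualifying_length(self, chrom: str, start: int, end: int, mq_min: float) -> int:
        """Bases of [start, end) covered by bins with mean MQ >= mq_min."""
        if self.mq is None:
            return max(0, min(end, self.contig_length(chrom)) - max(0, start))
        idx, w = self._bin_weights(chrom, start, end)
        if len(idx) == 0:
            return 0
        return int(np.sum(w[self.mq[chrom][idx] >= mq_min]))

    # ---- serialization -------------------------------------------------

    def write_wiggle(self, path: str | Path, which: str = "depth") -> None:
        """Fixed-step wiggle (1-based starts, step = span = bin_size)."""
        data = self.depth if which == "depth" else self.mq
        if data is None:
            raise FormatError("track has no MQ data")
        with open(path, "w") as fh:
            for chrom, arr in data.items():
                fh.write(
                    f"fixedStep chrom={chrom} start=1 step={self.bin_size} "
                    f"span={self.bin_size}\n"
                )
                fh.write("\n".join(f"{v:g}" for v in arr))
                fh.write("\n")

    @classmethod
    def read_wiggle(
        cls, depth_path: str | Path, mq_path: str | Path | None = None
    ) -> "CoverageTrack":
        depth, bin_size = _parse_fixed_step(depth_path)
        mq = None
        if mq_path is not None:
            mq, mq_bin = _parse_fixed_step(mq_path)
            if mq_bin != bin_size:
                raise FormatError("depth and MQ wiggle bin sizes differ")
        return cls(depth, mq, bin_size)

    @classmethod
    def read_bigwig(
        cls,
        depth_path: str | Path,
        mq_path: str | Path | None = None,
        bin_size: int = 100,
    ) -> "CoverageTrack":
        import pyBigWig

        def load(path):
            bw = pyBigWig.open(str(path))
            try:
                out = {}
                for chrom, n in bw.chroms().items():
                    nbins = (n + bin_size - 1) // bin_size
                    vals = bw.stats(chrom, 0, n, nBins=nbins, type="mean")
                    out[chrom] = np.array(
                        [v if v is not None else 0.0 for v in vals], dtype=float
                    )
                return out
            finally:
                bw.close()

        depth = load(depth_path)
        mq = load(mq_path) if mq_path is not None else None
        return cls(depth, mq, bin_size)


def _parse_fixed_step(path: str | Path):
    data: dict[str, list[float]] = {}
    bin_size = None
    cur: list[float] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=", 1) for f in line.split()[1:])
                if int(kv.get("start", 1)) != 1:
                    raise FormatError("fixedStep blocks must start at 1")
                step = int(kv["step"])
                if bin_size is None:
                    bin_size = step
                elif step != bin_size:
                    raise FormatError("mixed step sizes in wiggle")
                cur = data.setdefault(kv["chrom"], [])
            elif cur is None:
                raise FormatError("wiggle data before fixedStep header")
            else:
                cur.append(float(line))
    if bin_size is None:
        raise FormatError("empty wiggle file")
    return {c: np.array(v) for c, v in data.items()}, bin_size


@dataclass
class GenomeCoverageEstimate:
    """Genome-average depth plus rounded sex-chromosome ratios.

    Sex-chromosome coverage is rounded in fractions of 0.5 of the autosomal
    coverage, so a normal male has X ratio 0.5 and Y ratio 0.5, and that
    rounded baseline makes DRA on a haploid X come out near 1.
    """

    autosomal: float
    sex_ratios: dict[str, float]
    layout: GenomeLayout

    def baseline(self, chrom: str) -> float:
        """Chromosome-appropriate genome-average denominator for DRA."""
        ratio = self.sex_ratios.get(chrom)
        if ratio is not None and ratio > 0:
            return ratio * self.autosomal
        return self.autosomal

    def ploidy(self, chrom: str) -> int:
        ratio = self.sex_ratios.get(chrom)
        if ratio is None:
            return 2
        return int(round(ratio * 2))


@dataclass
class DocMetrics:
    """Per-variant depth metrics.

    ``drf`` is None when neither flank exists (whole-contig variants);
    ``mq_restricted`` records whether the MQ >= 50 restriction was applied
    (it is dropped when less than one third of the variant length qualifies).
    """

    doc: float
    dra: float
    drf: float | None
    mq_restricted: bool


def estimate_genome_coverage(
    track: CoverageTrack, layout: GenomeLayout
) -> GenomeCoverageEstimate:
    """Median of the per-autosome baseline-window mean depths; X from the
    whole chromosome, Y from its unique regions, both rounded to the nearest
    0.5 fraction of the autosomal estimate."""
    window_means = []
    for chrom, start, end in layout.autosome_windows:
        if chrom not in track.depth:
            raise EstimationError(f"autosome {chrom} missing from coverage track")
        window_means.append(track.mean_depth(chrom, start, end))
    if not window_means:
        raise EstimationError("layout defines no autosome baseline windows")
    autosomal = float(statistics.median(window_means))
    if not autosomal > 0:
        raise EstimationError("autosomal baseline coverage is zero")
    ratios: dict[str, float] = {}
    if layout.chr_x is not None and layout.chr_x in track.depth:
        x_mean = track.mean_depth(layout.chr_x, 0, track.contig_length(layout.chr_x))
        ratios[layout.chr_x] = round_to_half(x_mean / autosomal)
    if layout.chr_y is not None and layout.chr_y in track.depth:
        num = 0.0
        den = 0
        for s, e in layout.y_unique_regions:
            m = track.mean_depth(layout.chr_y, s, e)
            if not np.isnan(m):
                num += m * (e - s)
                den += e - s
        y_mean = num / den if den else 0.0
        ratios[layout.chr_y] = round_to_half(y_mean / autosomal)
    return GenomeCoverageEstimate(autosomal, ratios, layout)


MQ_THRESHOLD = 50.0
MQ_MIN_FRACTION = 1.0 / 3.0


def _restricted_mean(track: CoverageTrack, chrom: str, start: int, end: int):
    """Mean depth with the MQ>=50 restriction unless < 1/3 of the length
    qualifies.  Returns (mean, restricted?)."""
    length = end - start
    if length <= 0:
        return float("nan"), False
    if track.mq is not None:
        qual = track.qualifying_length(chrom, start, end, MQ_THRESHOLD)
        if qual >= MQ_MIN_FRACTION * length:
            return track.mean_depth(chrom, start, end, mq_min=MQ_THRESHOLD), True
    return track.mean_depth(chrom, start, end), False


def compute_doc_metrics(
    chrom: str,
    start: int,
    end: int,
    track: CoverageTrack,
    genome_est: GenomeCoverageEstimate,
) -> DocMetrics:
    """DOC / DRA / DRF for [start, end).

    Flanks are each as long as the variant, clipped at contig edges; with a
    single available flank, that flank alone is the DRF denominator; with
    none, DRF is undefined.
    """
    doc, restricted = _restricted_mean(track, chrom, start, end)
    if np.isnan(doc):
        raise EstimationError(f"no coverage data for {chrom}:{start}-{end}")
    baseline = genome_est.baseline(chrom)
    if not baseline > 0:
        raise EstimationError(f"zero baseline coverage for contig {chrom}")
    dra = doc / baseline
    length = end - start
    contig_len = track.contig_length(chrom)
    flank_docs = []
    left = (max(0, start - length), start)
    right = (end, min(contig_len, end + length))
    for fs, fe in (left, right):
        if fe > fs:
            m, _ = _restricted_mean(track, chrom, fs, fe)
            if not np.isnan(m):
                flank_docs.append(m)
    drf: float | None = None
    if flank_docs:
        denom = float(np.mean(flank_docs))
        drf = doc / denom if denom > 0 else None
    return DocMetrics(doc=doc, dra=dra, drf=drf, mq_restricted=restricted)


CNV_LOW = 0.8
CNV_HIGH = 1.2
HOM_LOW = 0.2
HOM_HIGH = 1.75


def flag_cnv(metrics: DocMetrics) -> bool:
    """CNV = 1 iff DRA or DRF is < 0.8 or > 1.2 (DRF ignored if undefined)."""
    if metrics.dra < CNV_LOW or metrics.dra > CNV_HIGH:
        return True
    drf = metrics.drf
    return drf is not None and (drf < CNV_LOW or drf > CNV_HIGH)


def assign_genotype(dra: float, ploidy: int = 2) -> str:
    """DRA in [0.2, 0.8) or (1.2, 1.75] -> 0/1; < 0.2 or > 1.75 -> 1/1;
    the copy-neutral band [0.8, 1.2] gets ./. (no CNV genotype)."""
    if dra < 0:
        raise ValueError("DRA must be non-negative")
    if dra < HOM_LOW or dra > HOM_HIGH:
        return "1/1"
    if dra < CNV_LOW or dra > CNV_HIGH:
        return "0/1"
    return "./."


def copy_number_estimate(dra: float, ploidy: int = 2) -> int:
    """Point estimate of integer copy number, for aneuploidy reporting."""
    return int(round(dra * ploidy))


def population_coverage_sd(dra_matrix: np.ndarray) -> np.ndarray:
    """Per 1-kb interval population SD of DRA across control samples.

    ``dra_matrix`` is (n_samples, n_intervals) on a shared grid anchored at
    position 1.  Population SD (ddof=0): the cohort is the full reference
    set, the track is descriptive.
    """
    m = np.asarray(dra_matrix, dtype=float)
    if m.ndim != 2:
        raise EstimationError("DRA summaries must share a 2-D sample x interval grid")
    return np.std(m, axis=0, ddof=0)
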