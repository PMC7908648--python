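"""Control-cohort evidence database and population allele frequencies.

Five population allele frequency (PAF) measures support rare-variant
prioritization:

* PAFSU — from raw control SR/DP evidence at the breakpoints:
  ``PAFSU = SUC / SU / NCS`` where SU is the variant's supporting read
  count, SUC the matching control count within 1000 bases of each
  breakpoint with the orientation expected for the SV type, and NCS the
  number of control samples.  Captures variants near or below the calling
  threshold; may exceed 1 in mapping-artifact regions.
* PAFDRA — fraction of control samples showing the same copy-number change
  (loss: DRA < 0.8, gain: DRA > 1.2) over at least 90% of the CNV's 1-kb
  intervals.  Captures CNVs in segmental duplications lacking SR/DP.
* PAFV — fraction of control samples carrying a matching Pass/High control
  variant.
* PAF1KG / PAFG — allele frequencies of the best-matching record in an
  external reference set (1000 Genomes / gnomAD).

A variant is RARE when none of PAFV, PAFSU, PAFDRA, PAF1KG exceeds 0.01
(strict; PAFG is annotation-only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coverage import CNV_HIGH, CNV_LOW
from .evidence import EXPECTED_ORIENTATION
from .genome import EstimationError, overlap_length

BREAKPOINT_WINDOW = 1000
DRA_BIN = 1000
RARE_MAX_PAF = 0.01


@dataclass
class PafSet:
    pafsu: float | None = None
    pafdra: float | None = None
    pafv: float | None = None
    paf1kg: float | None = None
    pafg: float | None = None
    rare: bool = True


@dataclass(frozen=True)
class ControlVariant:
    chrom: str
    start: int
    end: int
    svtype: str
    cnv: bool
    carriers: int
    af: float | None = None  # external sets carry an AF instead of carriers


@dataclass
class ControlCohortDB:
    """Breakpoint-level SR/DP counts, 1-kb DRA summaries and Pass/High
    variants for ``n_samples`` control genomes.

    ``breakpoints`` columns: chrom, pos, orientation, count, sample_count.
    ``dra_bins`` maps contig -> (n_samples, n_intervals) DRA matrix on the
    1-kb grid anchored at position 1.
    """

    n_samples: int
    breakpoints: pd.DataFrame
    dra_bins: dict[str, np.ndarray] = field(default_factory=dict)
    variants: list[ControlVariant] = field(default_factory=list)

    def __post_init__(self):
        if self.n_samples < 1:
            raise EstimationError("control cohort must contain >= 1 sample")
        self.breakpoints = self.breakpoints.sort_values(
            ["chrom", "pos"]
        ).reset_index(drop=True)

    # ---- queries -------------------------------------------------------

    def breakpoint_counts(
        self, chrom: str, pos: int, orientations: Sequence[str],
        window: int = BREAKPOINT_WINDOW,
    ) -> int:
        bp = self.breakpoints
        sel = bp[
            (bp["chrom"] == chrom)
            & (bp["pos"] >= pos - window)
            & (bp["pos"] <= pos + window)
            & (bp["orientation"].isin(orientations))
        ]
        return int(sel["count"].sum())

    # ---- serialization -------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "meta.json").write_text(
            json.dumps({"n_samples": self.n_samples,
                        "contigs": list(self.dra_bins)}) + "\n"
        )
        self.breakpoints.to_csv(directory / "breakpoints.tsv", sep="\t", index=False)
        pd.DataFrame(
            [vars(v) if not hasattr(v, "__dataclass_fields__") else
             {k: getattr(v, k) for k in v.__dataclass_fields__}
             for v in self.variants],
            columns=["chrom", "start", "end", "svtype", "cnv", "carriers", "af"],
        ).to_csv(directory / "variants.tsv", sep="\t", index=False)
        dra_dir = directory / "dra"
        dra_dir.mkdir(exist_ok=True)
        for chrom, mat in self.dra_bins.items():
            np.savetxt(dra_dir / f"{chrom}.tsv", mat, delimiter="\t", fmt="%.4f")

    @classmethod
    def load(cls, directory: str | Path) -> "ControlCohortDB":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        bp = pd.read_csv(directory / "breakpoints.tsv", sep="\t",
                         dtype={"chrom": str})
        vdf = pd.read_csv(directory / "variants.tsv", sep="\t", dtype={"chrom": str})
        variants = [
            ControlVariant(
                chrom=r.chrom, start=int(r.start), end=int(r.end),
                svtype=r.svtype, cnv=bool(r.cnv), carriers=int(r.carriers),
                af=None if pd.isna(r.af) else float(r.af),
            )
            for r in vdf.itertuples()
        ]
        dra = {}
        for chrom in meta["contigs"]:
            mat = np.loadtxt(directory / "dra" / f"{chrom}.tsv", delimiter="\t",
                             ndmin=2)
            dra[chrom] = mat
        return cls(meta["n_samples"], bp, dra, variants)


# ---- PAFSU -------------------------------------------------------------


def compute_pafsu(
    chrom: str,
    start: int,
    end: int,
    svtype: str,
    su: int,
    db: ControlCohortDB,
    window: int = BREAKPOINT_WINDOW,
) -> float | None:
    """SUC / SU / NCS; None when the variant has no supporting reads.

    SUC sums control SR/DP within ``window`` bases of each breakpoint with
    the orientation expected for the SV type; the two per-breakpoint sums
    are added without deduplication.
    """
    if su <= 0:
        return None
    orientations = EXPECTED_ORIENTATION.get(svtype, ())
    suc = db.breakpoint_counts(chrom, start, orientations, window)
    suc += db.breakpoint_counts(chrom, end, orientations, window)
    return suc / su / db.n_samples


# ---- PAFDRA ------------------------------------------------------------


def compute_pafdra(
    chrom: str,
    start: int,
    end: int,
    svtype: str,
    db: ControlCohortDB,
    min_fraction: float = 0.9,
) -> float | None:
    """Fraction of control samples with the same copy-number change over at
    least ``min_fraction`` of the CNV's overlapped 1-kb intervals.

    Loss (DEL): DRA < 0.8; gain (DUP): DRA > 1.2.  A CNV shorter than one
    interval uses its single overlapping interval.  None for SV types
    without a copy direction or contigs absent from the summaries.
    """
    if svtype == "DEL":
        direction_low, direction_high = True, False
    elif svtype == "DUP":
        direction_low, direction_high = False, True
    else:
        return None
    mat = db.dra_bins.get(chrom)
    if mat is None:
        return None
    first = start // DRA_BIN
    last = max(first, (end - 1) // DRA_BIN)
    last = min(last, mat.shape[1] - 1)
    first = min(first, mat.shape[1] - 1)
    window = mat[:, first : last + 1]
    if direction_low:
        changed = window < CNV_LOW
    else:
        changed = window > CNV_HIGH
    frac = changed.mean(axis=1)
    return float(np.count_nonzero(frac >= min_fraction) / db.n_samples)


# ---- variant matching and PAFV / external PAFs -------------------------


@dataclass(frozen=True)
class MatchCriteria:
    breakpoint_tol: int = 1000
    ref_fraction: float = 0.2
    query_fraction: float = 0.9
    short_query_fraction: float = 0.7
    short_length: int = 1000


DEFAULT_MATCH = MatchCriteria()


def match_variant(
    query: ControlVariant | object,
    reference: ControlVariant | object,
    criteria: MatchCriteria = DEFAULT_MATCH,
) -> bool:
    """Concordance of one query variant against one reference variant.

    The variant type (DEL, DUP, INV) and CNV state must match.  Copy-
    neutral SVs match when both breakpoints are within 1000 bases.  CNVs of
    at least 1 kb require overlap of >= 20% of the reference length and
    >= 90% of the query length; CNVs under 1 kb require >= 70% of the query
    length (the 20% reference clause is retained).
    """
    if query.chrom != reference.chrom or query.svtype != reference.svtype:
        return False
    q_cnv = getattr(query, "cnv", getattr(query, "is_cnv", True))
    r_cnv = getattr(reference, "cnv", getattr(reference, "is_cnv", True))
    if bool(q_cnv) != bool(r_cnv):
        return False
    if not q_cnv:
        return (
            abs(query.start - reference.start) <= criteria.breakpoint_tol
            and abs(query.end - reference.end) <= criteria.breakpoint_tol
        )
    ov = overlap_length(query.start, query.end, reference.start, reference.end)
    q_len = query.end - query.start
    r_len = reference.end - reference.start
    if q_len <= 0 or r_len <= 0:
        return False
    if ov < criteria.ref_fraction * r_len:
        return False
    q_frac = (
        criteria.short_query_fraction
        if q_len < criteria.short_length
        else criteria.query_fraction
    )
    return ov >= q_frac * q_len


def _matches(query, records, criteria) -> list:
    return [r for r in records if match_variant(query, r, criteria)]


def compute_pafv(
    query, db: ControlCohortDB, criteria: MatchCriteria = DEFAULT_MATCH
) -> float:
    """Matched control-variant carrier count / NCS (best match by overlap
    when several control variants satisfy the criteria)."""
    hits = _matches(query, db.variants, criteria)
    if not hits:
        return 0.0
    best = max(
        hits,
        key=lambda r: overlap_length(query.start, query.end, r.start, r.end),
    )
    return best.carriers / db.n_samples


def compute_external_paf(
    query,
    reference_set: Sequence[ControlVariant],
    criteria: MatchCriteria = DEFAULT_MATCH,
) -> float:
    """AF of the best-matching record of an external frequency set; 0 when
    nothing matches."""
    hits = _matches(query, reference_set, criteria)
    if not hits:
        return 0.0
    best = max(
        hits,
        key=lambda r: overlap_length(query.start, query.end, r.start, r.end),
    )
    return best.af if best.af is not None else 0.0


def flag_rare(pafs: PafSet, threshold: float = RARE_MAX_PAF) -> bool:
    """Rare iff none of PAFV, PAFSU, PAFDRA, PAF1KG exceeds the threshold
    (strictly); missing values count as 0.  PAFG is annotation-only."""
    considered = (pafs.pafv, pafs.pafsu, pafs.pafdra, pafs.paf1kg)
    return not any(p is not None and p > threshold for p in considered)


def read_external_set_vcf(path: str | Path, cnv_types=("DEL", "DUP")) -> list[ControlVariant]:
    """External SV frequency set from a VCF with SVTYPE/END/AF fields."""
    from cyvcf2 import VCF

    out: list[ControlVariant] = []
    for rec in VCF(str(path)):
        svtype = rec.INFO.get("SVTYPE")
        if svtype is None:
            continue
        end = rec.INFO.get("END", rec.end)
        af = rec.INFO.get("AF")
        if isinstance(af, tuple):
            af = af[0]
        out.append(
            ControlVariant(
                chrom=rec.CHROM,
                start=rec.start,
                end=int(end),
                svtype=svtype,
                cnv=svtype in cnv_types,
                carriers=0,
                af=float(af) if af is not None else None,
            )
        )
    return out
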