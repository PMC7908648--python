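"""Gene, disease-term, candidate-gene and pedigree annotation, and the
rare-gene-affecting filter.

"Gene-affecting" means any overlap with the gene body (pseudogenes are
expected to be pre-filtered from the gene models); disease terms come from
a prepared tab-separated gene-to-term mapping rather than live OMIM /
Orphanet queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .integrate import IntegratedVariant
from .quality import HIGH, PASS


@dataclass(frozen=True)
class GeneModel:
    name: str
    chrom: str
    start: int
    end: int
    disease_terms: tuple[str, ...] = ()


@dataclass
class Annotations:
    genes: list[str] = field(default_factory=list)
    disease_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    candg: list[str] = field(default_factory=list)
    ia: int = 0
    iua: int = 0
    dgv_matches: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PedigreeSample:
    sample_id: str
    family_id: str
    father: str | None
    mother: str | None
    sex: str
    status: str  # affected / unaffected / unknown


class PedigreeInfo:
    def __init__(self, samples: Iterable[PedigreeSample]):
        self.samples = {s.sample_id: s for s in samples}

    @classmethod
    def read_ped(cls, path: str | Path) -> "PedigreeInfo":
        """Six-column PED: family, individual, father, mother, sex, status
        (1 = unaffected, 2 = affected, other = unknown)."""
        out = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fam, ind, father, mother, sex, status = line.split()[:6]
                out.append(
                    PedigreeSample(
                        sample_id=ind,
                        family_id=fam,
                        father=None if father == "0" else father,
                        mother=None if mother == "0" else mother,
                        sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                        status={"1": "unaffected", "2": "affected"}.get(
                            status, "unknown"
                        ),
                    )
                )
        return cls(out)


class GeneIndex:
    """Interval index over gene models (pseudogene-free)."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    @classmethod
    def read_bed(
        cls,
        path: str | Path,
        disease_map: dict[str, tuple[str, ...]] | None = None,
    ) -> "GeneIndex":
        """BED (chrom, start, end, name); columns beyond 4 ignored."""
        genes = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                genes.append(
                    GeneModel(
                        name=name,
                        chrom=f[0],
                        start=int(f[1]),
                        end=int(f[2]),
                        disease_terms=(disease_map or {}).get(name, ()),
                    )
                )
        return cls(genes)

    @classmethod
    def read_gff3(
        cls,
        path: str | Path,
        disease_map: dict[str, tuple[str, ...]] | None = None,
    ) -> "GeneIndex":
        """Gene features from a GFF3 (type == gene, pseudogenes excluded by
        biotype attribute when present)."""
        genes = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                if "pseudogene" in attrs.get("biotype", ""):
                    continue
                name = attrs.get("Name", attrs.get("ID", f"{f[0]}:{f[3]}"))
                genes.append(
                    GeneModel(
                        name=name,
                        chrom=f[0],
                        start=int(f[3]) - 1,
                        end=int(f[4]),
                        disease_terms=(disease_map or {}).get(name, ()),
                    )
                )
        return cls(genes)

    def overlapping(self, chrom: str, start: int, end: int, padding: int = 0):
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(start - padding, end + padding)
        return sorted((h.data for h in hits), key=lambda g: (g.start, g.name))


def read_disease_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Two-column TSV: gene symbol, comma-separated disease terms."""
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, terms = line.rstrip("\n").split("\t")[:2]
            out[gene] = tuple(t for t in terms.split(",") if t)
    return out


def annotate_genes(
    variant: IntegratedVariant,
    index: GeneIndex,
    candidate_genes: Sequence[str] = (),
    padding: int = 0,
) -> Annotations:
    genes = index.overlapping(variant.chrom, variant.start, variant.end, padding)
    ann = variant.annotations if isinstance(variant.annotations, Annotations) else Annotations()
    ann.genes = [g.name for g in genes]
    ann.disease_terms = {g.name: g.disease_terms for g in genes if g.disease_terms}
    cand = set(candidate_genes)
    ann.candg = [g for g in ann.genes if g in cand]
    variant.annotations = ann
    return ann


def pedigree_counts(
    carrier_samples: Iterable[str], ped: PedigreeInfo
) -> tuple[int, int]:
    """(IA, IUA): carriers among affected and unaffected individuals;
    unknown-status carriers are excluded from both."""
    ia = iua = 0
    for sid in carrier_samples:
        ps = ped.samples.get(sid)
        if ps is None:
            warnings.warn(f"sample {sid!r} has a call but no pedigree entry")
            continue
        if ps.status == "affected":
            ia += 1
        elif ps.status == "unaffected":
            iua += 1
    return ia, iua


def filter_rare_gene_affecting(
    variants: Sequence[IntegratedVariant],
) -> list[IntegratedVariant]:
    """Rare variants overlapping at least one gene, with PASS or HIGH
    confidence.  Applying the filter twice is the identity."""
    out = []
    for v in variants:
        if v.tranche not in (HIGH, PASS):
            continue
        if v.pafs is None or not v.pafs.rare:
            continue
        if v.annotations is None or not v.annotations.genes:
            continue
        out.append(v)
    return out
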