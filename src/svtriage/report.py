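"""Result serialization: annotated variant TSV, structural-variant VCF,
IGV session XML, and the cohort-z-score QC report.

All writers are deterministic given identical input; coordinates are
1-based inclusive in every user-facing file.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome import SvtriageError
from .integrate import IntegratedVariant

TABLE_COLUMNS = [
    "chrom", "start", "end", "svtype", "length", "sample", "cnv", "genotype",
    "copy_number", "tranche", "su", "sr", "dp", "dra", "drf", "mq_variant",
    "mq_breakpoints", "gc", "cr", "segdup_overlap", "segdup_similarity",
    "pafsu", "pafdra", "pafv", "paf1kg", "pafg", "rare", "genes", "candg",
    "ia", "iua",
]


def _fmt(x, digits: int = 4):
    if x is None:
        return "NA"
    if isinstance(x, bool):
        return int(x)
    if isinstance(x, float):
        return round(x, digits)
    return x


def variant_rows(variants: Sequence[IntegratedVariant]) -> list[dict]:
    """One row per variant per carrier sample (1-based inclusive coords)."""
    rows = []
    for v in variants:
        q = v.quality
        p = v.pafs
        a = v.annotations
        for sample, sc in sorted(v.samples.items()):
            dra = sc.doc.dra if sc.doc else None
            rows.append(
                {
                    "chrom": v.chrom,
                    "start": v.start + 1,
                    "end": v.end,
                    "svtype": v.svtype,
                    "length": v.length,
                    "sample": sample,
                    "cnv": int(v.is_cnv),
                    "genotype": sc.genotype,
                    "copy_number": _fmt(
                        None if dra is None else int(round(dra * 2))
                    ),
                    "tranche": v.tranche or "NA",
                    "su": sc.counts.su,
                    "sr": sc.counts.sr,
                    "dp": sc.counts.dp,
                    "dra": _fmt(dra),
                    "drf": _fmt(sc.doc.drf if sc.doc else None),
                    "mq_variant": _fmt(q.avg_mq_variant if q else None, 2),
                    "mq_breakpoints": _fmt(q.avg_mq_breakpoints if q else None, 2),
                    "gc": _fmt(q.gc_percent if q else None, 2),
                    "cr": _fmt(q.compression_ratio if q else None),
                    "segdup_overlap": _fmt(q.segdup_match[0] if q and q.segdup_match else None, 2),
                    "segdup_similarity": _fmt(q.segdup_match[1] if q and q.segdup_match else None, 2),
                    "pafsu": _fmt(p.pafsu if p else None, 6),
                    "pafdra": _fmt(p.pafdra if p else None, 6),
                    "pafv": _fmt(p.pafv if p else None, 6),
                    "paf1kg": _fmt(p.paf1kg if p else None, 6),
                    "pafg": _fmt(p.pafg if p else None, 6),
                    "rare": int(p.rare) if p else "NA",
                    "genes": ",".join(a.genes) if a and a.genes else "NA",
                    "candg": ",".join(a.candg) if a and a.candg else "NA",
                    "ia": a.ia if a else "NA",
                    "iua": a.iua if a else "NA",
                }
            )
    return rows


def write_variant_table(
    variants: Sequence[IntegratedVariant], path: str | Path
) -> pd.DataFrame:
    df = pd.DataFrame(variant_rows(variants), columns=TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_variant_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)


# ---- VCF ---------------------------------------------------------------

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=svtriage
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INV,Description="Inversion">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">
##INFO=<ID=CNV,Number=1,Type=Integer,Description="1 if copy number changed">
##INFO=<ID=TRANCHE,Number=1,Type=String,Description="Confidence tranche">
##INFO=<ID=PAFSU,Number=1,Type=Float,Description="Population AF from control SR/DP evidence">
##INFO=<ID=PAFDRA,Number=1,Type=Float,Description="Population AF from control read depth">
##INFO=<ID=PAFV,Number=1,Type=Float,Description="Population AF from control variants">
##INFO=<ID=PAF1KG,Number=1,Type=Float,Description="1000 Genomes AF of matched variant">
##INFO=<ID=PAFG,Number=1,Type=Float,Description="gnomAD AF of matched variant">
##INFO=<ID=RARE,Number=0,Type=Flag,Description="No PAF above 0.01">
##INFO=<ID=GENES,Number=.,Type=String,Description="Overlapped genes">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype from read depth">
##FORMAT=<ID=SR,Number=1,Type=Integer,Description="Split reads">
##FORMAT=<ID=DP2,Number=1,Type=Integer,Description="Discordant pairs">
##FORMAT=<ID=SU,Number=1,Type=Integer,Description="Supporting reads (SR+DP)">
"""


def write_vcf(
    variants: Sequence[IntegratedVariant],
    path: str | Path,
    contigs: dict[str, int] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> None:
    """Structural-variant VCF 4.2 with symbolic ALTs; BND records use
    breakend notation."""
    if sample_ids is None:
        ids = sorted({s for v in variants for s in v.samples})
    else:
        ids = list(sample_ids)
    lines = [VCF_HEADER.rstrip("\n")]
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                   "FORMAT"] + ids
    lines.append("\t".join(header_cols))
    for i, v in enumerate(
        sorted(variants, key=lambda v: (v.chrom, v.start, v.end, v.svtype)), 1
    ):
        if v.svtype == "BND" and v.mate_chrom is not None:
            alt = f"N[{v.mate_chrom}:{(v.mate_pos or 0) + 1}["
            info = [f"SVTYPE=BND"]
        else:
            alt = f"<{v.svtype}>"
            svlen = -v.length if v.svtype == "DEL" else v.length
            info = [f"SVTYPE={v.svtype}", f"END={v.end}", f"SVLEN={svlen}"]
        info.append(f"CNV={int(v.is_cnv)}")
        if v.tranche:
            info.append(f"TRANCHE={v.tranche}")
        p = v.pafs
        if p is not None:
            for key, val in (
                ("PAFSU", p.pafsu), ("PAFDRA", p.pafdra), ("PAFV", p.pafv),
                ("PAF1KG", p.paf1kg), ("PAFG", p.pafg),
            ):
                if val is not None:
                    info.append(f"{key}={val:.6g}")
            if p.rare:
                info.append("RARE")
        if v.annotations is not None and v.annotations.genes:
            info.append("GENES=" + ",".join(v.annotations.genes))
        fmt = "GT:SR:DP2:SU"
        samples = []
        for sid in ids:
            sc = v.samples.get(sid)
            if sc is None:
                samples.append("./.:.:.:.")
            else:
                samples.append(
                    f"{sc.genotype}:{sc.counts.sr}:{sc.counts.dp}:{sc.counts.su}"
                )
        lines.append(
            "\t".join(
                [v.chrom, str(v.start + 1), f"SV{i:06d}", "N", alt, ".", "PASS",
                 ";".join(info), fmt] + samples
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_candidate_vcf(path: str | Path, caller: str = "srdp"):
    """Candidate calls from a VCF with SVTYPE/END and optional SR/PE/SU
    counts (per-record INFO, applied to the single/first sample)."""
    from cyvcf2 import VCF

    from .integrate import CandidateCall, EvidenceCounts

    out = []
    vcf = VCF(str(path))
    sample_ids = vcf.samples or ["sample"]
    for rec in vcf:
        svtype = rec.INFO.get("SVTYPE")
        if svtype is None:
            continue
        end = int(rec.INFO.get("END", rec.end))
        sr = int(rec.INFO.get("SR", 0))
        dp = int(rec.INFO.get("PE", rec.INFO.get("DP", 0)))
        su = rec.INFO.get("SU")
        if su is not None and sr == 0 and dp == 0:
            dp = int(su)
        out.append(
            CandidateCall(
                chrom=rec.CHROM,
                start=rec.start,
                end=end,
                svtype=svtype,
                caller=caller,
                samples={sample_ids[0]: EvidenceCounts(sr=sr, dp=dp)},
                precise=caller == "srdp",
            )
        )
    return out


def write_candidate_table(calls, path: str | Path) -> None:
    """BED-like candidate-call table (one row per call per sample)."""
    rows = []
    for c in calls:
        samples = c.samples or {"sample": None}
        for sid, counts in samples.items():
            rows.append(
                {
                    "chrom": c.chrom, "start": c.start, "end": c.end,
                    "svtype": c.svtype, "caller": c.caller, "sample": sid,
                    "sr": counts.sr if counts else 0,
                    "dp": counts.dp if counts else 0,
                }
            )
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "svtype", "caller", "sample", "sr", "dp"]
    ).to_csv(path, sep="\t", index=False)


def read_candidate_table(path: str | Path, caller: str | None = None):
    """Candidate calls from a BED-like table; rows sharing coordinates and
    type collapse into one call with per-sample counts."""
    from .integrate import CandidateCall, EvidenceCounts

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    out: dict[tuple, "CandidateCall"] = {}
    for r in df.itertuples():
        row_caller = caller or getattr(r, "caller", "srdp")
        key = (r.chrom, int(r.start), int(r.end), r.svtype, row_caller)
        call = out.get(key)
        if call is None:
            call = CandidateCall(
                chrom=r.chrom, start=int(r.start), end=int(r.end),
                svtype=r.svtype, caller=row_caller,
                precise=row_caller == "srdp",
            )
            out[key] = call
        call.samples[str(r.sample)] = EvidenceCounts(
            sr=int(getattr(r, "sr", 0)), dp=int(getattr(r, "dp", 0))
        )
    return list(out.values())


# ---- IGV session -------------------------------------------------------

#: the review session's 11 data tracks, in display order: coverage in a
#: matched control, the sample (all reads and MQ>=20 reads), mean mapping
#: quality, the control-cohort coverage SD, segmental duplications, the
#: integrated calls, raw DP and SR evidence, control-cohort calls, and DGV.
#: The reference gene annotation rides along as an extra resource
#: ("genes"), shown by IGV's annotation panel rather than a data track.
IGV_TRACKS = [
    ("control_doc", "DOC control"),
    ("sample_doc", "DOC"),
    ("sample_doc_mq20", "DOC MQ20"),
    ("mq", "MQ"),
    ("doc_sd", "DOC SD (controls)"),
    ("segdup", "Seg-Dup"),
    ("calls", "SV calls"),
    ("dp", "DP"),
    ("sr", "SR"),
    ("control_calls", "Control cohort calls"),
    ("dgv", "DGV"),
]


def build_igv_session(
    track_paths: dict[str, str],
    path: str | Path,
    genome: str = "hg19",
    locus: str | None = None,
) -> None:
    """IGV session XML referencing the review tracks; raises listing any
    missing mandatory track keys."""
    missing = [key for key, _ in IGV_TRACKS if key not in track_paths]
    if missing:
        raise SvtriageError(f"missing IGV track paths: {', '.join(missing)}")
    root = ET.Element("Session", genome=genome, version="8")
    if locus:
        root.set("locus", locus)
    resources = ET.SubElement(root, "Resources")
    panel = ET.SubElement(root, "Panel", name="DataPanel")
    for key, label in IGV_TRACKS:
        p = track_paths[key]
        ET.SubElement(resources, "Resource", path=p)
        ET.SubElement(panel, "Track", id=p, name=label)
    if "genes" in track_paths:
        ET.SubElement(resources, "Resource", path=track_paths["genes"])
        feature = ET.SubElement(root, "Panel", name="FeaturePanel")
        ET.SubElement(
            feature, "Track", id=track_paths["genes"], name="Genes"
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def read_igv_session(path: str | Path) -> dict[str, str]:
    tree = ET.parse(path)
    out = {}
    for track in tree.getroot().iter("Track"):
        out[track.get("name")] = track.get("id")
    return out


# ---- QC report ---------------------------------------------------------


@dataclass
class QcMetrics:
    values: dict[str, float]
    z_scores: dict[str, float | None]
    flagged: list[str]
    passed: bool


Z_LIMIT = 2.0


def qc_report(
    sample_metrics: dict[str, float],
    control_stats: pd.DataFrame,
    html_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
    sample_id: str = "sample",
) -> QcMetrics:
    """Z-scores of sample metrics against the control-cohort distributions
    (columns: metric, mean, sd[, n]); metrics with |z| > 2, or with an
    undefined z (control SD 0), are flagged for review.  The sample passes
    when no computable input metric exceeds the limit.
    """
    stats = control_stats.set_index("metric")
    z_scores: dict[str, float | None] = {}
    flagged: list[str] = []
    for name, value in sample_metrics.items():
        if name not in stats.index:
            z_scores[name] = None
            continue
        mean, sd = float(stats.loc[name, "mean"]), float(stats.loc[name, "sd"])
        if sd == 0:
            z_scores[name] = None
            flagged.append(name)
            continue
        z = (value - mean) / sd
        z_scores[name] = z
        if abs(z) > Z_LIMIT:
            flagged.append(name)
    passed = not any(
        z is not None and abs(z) > Z_LIMIT for z in z_scores.values()
    )
    qc = QcMetrics(dict(sample_metrics), z_scores, flagged, passed)
    if tsv_path is not None:
        rows = [
            {
                "metric": k,
                "value": v,
                "z": "NA" if z_scores.get(k) is None else round(z_scores[k], 3),
                "flag": int(k in flagged),
            }
            for k, v in sample_metrics.items()
        ]
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if html_path is not None:
        body = "\n".join(
            "<tr class={cls}><td>{m}</td><td>{v:g}</td><td>{z}</td></tr>".format(
                cls="flag" if k in flagged else "ok",
                m=k,
                v=v,
                z="NA" if z_scores.get(k) is None else f"{z_scores[k]:.2f}",
            )
            for k, v in sample_metrics.items()
        )
        html = (
            "<html><head><style>tr.flag{background:#fdd}</style></head><body>"
            f"<h1>QC report: {sample_id}</h1>"
            f"<p>Status: {'PASS' if passed else 'REVIEW'}</p>"
            "<table border=1><tr><th>metric</th><th>value</th><th>z</th></tr>"
            f"{body}</table></body></html>"
        )
        Path(html_path).write_text(html)
    return qc
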