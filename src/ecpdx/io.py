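"""Readers and writers for the tabular formats the pipeline touches.

Dialects (all TSV, 1-based inclusive coordinates):

* **MAF-like variants** — columns ``Hugo_Symbol, Chromosome, Start_Position,
  Reference_Allele, Tumor_Seq_Allele2, Variant_Type, t_alt_count, t_depth,
  HGVSp_Short, Context3, Variant_ID``.  ``Variant_Type`` is inferred from
  allele lengths when absent; VAF is ``t_alt_count / t_depth``.
* **SEG-like segments** — ``Chromosome, Start, End, Total_CN, Minor_CN``
  (the classic SEG layout extended with allele-specific integer copy
  numbers).  Segments are canonically sorted at ingestion; overlaps are an
  error.
* **microsatellite summary** — ``n_assessed, n_unstable``.
* **volume series** — ``animal_id, arm, day, volume_mm3``.
* **sample sheet** — one row per sample pointing at the files above.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .core import (
    AllelicSegment,
    MicrosatellitePanelResult,
    SampleProfile,
    SomaticVariant,
    TherapyArmSeries,
    VolumeMeasurement,
)

__all__ = [
    "read_variants_maf", "write_variants_maf",
    "read_variants_vcf",
    "read_segments_seg", "write_segments_seg",
    "read_ms_summary", "write_ms_summary",
    "read_volume_series", "write_volume_series",
    "SampleSheet", "SampleSheetEntry", "read_sample_sheet", "load_profile",
    "write_report", "REPORT_COLUMNS",
]

MAF_MANDATORY = ("Chromosome", "Start_Position", "Reference_Allele",
                 "Tumor_Seq_Allele2", "t_alt_count", "t_depth")


def _infer_vclass(ref: str, alt: str) -> str:
    if ref == "-" or len(alt) > len(ref):
        return "INS"
    if alt == "-" or len(alt) < len(ref):
        return "DEL"
    if len(ref) == 1:
        return "SNP"
    if len(ref) == 2:
        return "DNP"
    return "TNP"


def _opt(row, col) -> Optional[str]:
    if col not in row or pd.isna(row[col]) or str(row[col]) == "":
        return None
    return str(row[col])


def read_variants_maf(path: str | Path) -> list[SomaticVariant]:
    """Read the MAF-like variant dialect; see the module docstring."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in MAF_MANDATORY:
        if col not in df.columns:
            raise ValueError(f"variant file {path}: missing mandatory column {col!r}")
    out = []
    for i, row in df.iterrows():
        try:
            ref = str(row["Reference_Allele"])
            alt = str(row["Tumor_Seq_Allele2"])
            vclass = _opt(row, "Variant_Type") or _infer_vclass(ref, alt)
            depth = int(row["t_depth"])
            alt_count = int(row["t_alt_count"])
            vaf = alt_count / depth if depth > 0 else 0.0
            out.append(SomaticVariant(
                chrom=str(row["Chromosome"]),
                pos=int(row["Start_Position"]),
                ref=ref, alt=alt, vclass=vclass, vaf=vaf, depth=depth,
                context3=_opt(row, "Context3") if vclass == "SNP" else None,
                gene=_opt(row, "Hugo_Symbol"),
                protein_change=_opt(row, "HGVSp_Short"),
                id=_opt(row, "Variant_ID"),
            ))
        except (ValueError, KeyError) as e:
            raise ValueError(f"variant file {path}, line {i + 2}: {e}") from e
    return out


def write_variants_maf(variants: list[SomaticVariant], path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append({
            "Hugo_Symbol": v.gene or "",
            "Chromosome": v.chrom,
            "Start_Position": v.pos,
            "Reference_Allele": v.ref,
            "Tumor_Seq_Allele2": v.alt,
            "Variant_Type": v.vclass,
            "t_alt_count": int(round(v.vaf * v.depth)),
            "t_depth": v.depth,
            "HGVSp_Short": v.protein_change or "",
            "Context3": v.context3 or "",
            "Variant_ID": v.id or "",
        })
    pd.DataFrame(rows, columns=["Hugo_Symbol", "Chromosome", "Start_Position",
                                "Reference_Allele", "Tumor_Seq_Allele2",
                                "Variant_Type", "t_alt_count", "t_depth",
                                "HGVSp_Short", "Context3", "Variant_ID"]
                 ).to_csv(path, sep="\t", index=False)


def read_variants_vcf(path: str | Path) -> list[SomaticVariant]:
    """Thin VCF adapter producing the same records as the MAF reader.

    Multi-allelic rows are split; indel notation is accepted as-is (no
    realignment).  Depth comes from the first sample's AD/DP when present,
    else from INFO/DP.
    """
    from cyvcf2 import VCF

    out = []
    vcf = VCF(str(path))
    for rec in vcf:
        depth = 0
        alt_counts: list[int] = []
        try:
            ad = rec.format("AD")
            if ad is not None:
                depth = int(ad[0].sum())
                alt_counts = [int(x) for x in ad[0][1:]]
        except (KeyError, TypeError):
            pass
        if depth == 0:
            depth = int(rec.INFO.get("DP", 0) or 0)
        for k, alt in enumerate(rec.ALT):
            ref, a = rec.REF, alt
            # trim the shared leading base of VCF-style indels
            if len(ref) > 1 or len(a) > 1:
                if ref[0] == a[0]:
                    ref, a = ref[1:] or "-", a[1:] or "-"
            alt_n = alt_counts[k] if k < len(alt_counts) else 0
            vclass = _infer_vclass(ref, a)
            out.append(SomaticVariant(
                chrom=rec.CHROM.removeprefix("chr"), pos=rec.POS,
                ref=ref, alt=a, vclass=vclass,
                vaf=alt_n / depth if depth > 0 else 0.0, depth=depth,
                context3=None, id=rec.ID))
    return out


SEG_COLUMNS = ("Chromosome", "Start", "End", "Total_CN", "Minor_CN")


def read_segments_seg(path: str | Path) -> list[AllelicSegment]:
    """Read the extended SEG dialect; sorted by (chrom, start) on return."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in SEG_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"segment file {path}: missing mandatory column {col!r}")
    segs = []
    for i, row in df.iterrows():
        try:
            segs.append(AllelicSegment(
                chrom=str(row["Chromosome"]), start_bp=int(row["Start"]),
                end_bp=int(row["End"]), total_cn=int(row["Total_CN"]),
                minor_cn=int(row["Minor_CN"])))
        except ValueError as e:
            raise ValueError(f"segment file {path}, line {i + 2}: {e}") from e
    segs.sort(key=lambda s: (s.chrom, s.start_bp))
    for a, b in zip(segs, segs[1:]):
        if a.chrom == b.chrom and b.start_bp <= a.end_bp:
            raise ValueError(
                f"segment file {path}: overlapping segments "
                f"{a.chrom}:{a.start_bp}-{a.end_bp} and {b.chrom}:{b.start_bp}-{b.end_bp}")
    return segs


def write_segments_seg(segments: list[AllelicSegment], path: str | Path) -> None:
    rows = [{"Chromosome": s.chrom, "Start": s.start_bp, "End": s.end_bp,
             "Total_CN": s.total_cn, "Minor_CN": s.minor_cn}
            for s in sorted(segments, key=lambda s: (s.chrom, s.start_bp))]
    pd.DataFrame(rows, columns=list(SEG_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_ms_summary(path: str | Path) -> MicrosatellitePanelResult:
    df = pd.read_csv(path, sep="\t")
    return MicrosatellitePanelResult(n_assessed=int(df["n_assessed"].iloc[0]),
                                     n_unstable=int(df["n_unstable"].iloc[0]))


def write_ms_summary(ms: MicrosatellitePanelResult, path: str | Path) -> None:
    pd.DataFrame([{"n_assessed": ms.n_assessed, "n_unstable": ms.n_unstable}]
                 ).to_csv(path, sep="\t", index=False)


def read_volume_series(path: str | Path) -> list[TherapyArmSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (animal, arm), grp in df.groupby(["animal_id", "arm"], sort=True):
        grp = grp.sort_values("day")
        out.append(TherapyArmSeries(
            animal_id=str(animal), arm=str(arm),
            measurements=tuple(VolumeMeasurement(int(r.day), float(r.volume_mm3))
                               for r in grp.itertuples())))
    return out


def write_volume_series(series: list[TherapyArmSeries], path: str | Path) -> None:
    rows = [{"animal_id": s.animal_id, "arm": s.arm, "day": m.day,
             "volume_mm3": m.volume_mm3}
            for s in series for m in s.measurements]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SampleSheetEntry:
    sample_id: str
    role: str
    variants_path: str
    segments_path: Optional[str]
    ms_path: Optional[str]
    callable_mb: float
    purity: Optional[float] = None
    lineage: Optional[str] = None
    passage: Optional[int] = None
    patient_id: Optional[str] = None


@dataclass
class SampleSheet:
    entries: list[SampleSheetEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids in a sheet must be unique")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Load a sample sheet and check that every referenced file exists."""
    base = Path(path).parent
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries = []
    for _, row in df.iterrows():
        paths = {}
        for col in ("variants_path", "segments_path", "ms_path"):
            p = _opt(row, col)
            if p is not None:
                p = str(base / p) if not os.path.isabs(p) else p
                if not os.path.exists(p):
                    raise FileNotFoundError(f"sample sheet references missing file {p}")
            paths[col] = p
        if paths["variants_path"] is None:
            raise ValueError(f"sample {row['sample_id']}: variants_path is required")
        purity = _opt(row, "purity")
        passage = _opt(row, "passage")
        entries.append(SampleSheetEntry(
            sample_id=str(row["sample_id"]), role=str(row["role"]),
            variants_path=paths["variants_path"],
            segments_path=paths["segments_path"], ms_path=paths["ms_path"],
            callable_mb=float(row["callable_mb"]),
            purity=float(purity) if purity else None,
            lineage=_opt(row, "lineage"),
            passage=int(passage) if passage else None,
            patient_id=_opt(row, "patient_id")))
    return SampleSheet(entries=entries)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    rows = []
    for e in sheet.entries:
        rows.append({"sample_id": e.sample_id, "role": e.role,
                     "variants_path": e.variants_path,
                     "segments_path": e.segments_path or "",
                     "ms_path": e.ms_path or "",
                     "callable_mb": e.callable_mb,
                     "purity": "" if e.purity is None else e.purity,
                     "lineage": e.lineage or "",
                     "passage": "" if e.passage is None else e.passage,
                     "patient_id": e.patient_id or ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_profile(entry: SampleSheetEntry) -> SampleProfile:
    """Materialize one sample sheet entry into a SampleProfile."""
    return SampleProfile(
        sample_id=entry.sample_id, role=entry.role,
        callable_mb=entry.callable_mb,
        variants=read_variants_maf(entry.variants_path),
        segments=(read_segments_seg(entry.segments_path)
                  if entry.segments_path else []),
        ms_result=read_ms_summary(entry.ms_path) if entry.ms_path else None,
        purity=entry.purity, lineage=entry.lineage, passage=entry.passage,
        patient_id=entry.patient_id)


REPORT_COLUMNS = (
    "sample_id", "role", "lineage", "passage", "tmb", "msi_score", "pct_cna",
    "n_cna_segments", "exposures", "dominant_etiology", "ntai", "lst",
    "hrd_loh", "hrd_sum", "hrd_call", "sig3_fraction", "subtype",
    "pole_exonuclease_mut", "pole_other_mut", "tp53_mut", "mmr_gene_hits",
)


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_report(results: list[dict], path: str | Path) -> None:
    """One TSV row per sample with burden, exposure, HRD and subtype columns.

    Rows are sorted by sample_id and all floats fixed-formatted, so
    rewriting the same results is byte-identical.
    """
    rows = sorted(results, key=lambda r: r.get("sample_id", ""))
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join(_fmt(r.get(c)) for c in REPORT_COLUMNS) + "\n")
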