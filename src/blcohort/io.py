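"""Readers and writers for the pipeline's tabular formats.

Formats: minimal VCF 4.2 and MAF-like TSV for variants, TSV for clinical
and purity/copy-number tables, BED for covered regions, YAML for
configuration.  Internal conventions: 1-based closed coordinates
(VCF-style anchored alleles) and contig names without a ``chr`` prefix;
BED intervals (0-based half-open) are converted at the boundary.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
import yaml

from .clonality import SamplePurityCN
from .filtering import VariantCall, variants_to_frame

__all__ = [
    "read_variants",
    "write_variants_tsv",
    "write_vcf",
    "read_bed",
    "write_clinical",
    "read_clinical",
    "write_purity_cn",
    "read_purity_cn",
    "load_yaml_config",
    "dump_yaml_config",
    "file_sha256",
]

MAF_COLUMNS = [
    "Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome", "Start_Position",
    "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
    "t_alt_count", "t_depth",
]


def _strip_chr(contig: str) -> str:
    return contig[3:] if contig.lower().startswith("chr") else contig


def _check_contig_style(contigs) -> None:
    has_chr = any(str(c).lower().startswith("chr") for c in contigs)
    plain = any(not str(c).lower().startswith("chr") for c in contigs)
    if has_chr and plain:
        raise ValueError(
            "mixed contig naming styles (chr-prefixed and plain) in one input"
        )


def read_variants(path, format: str = "maf_tsv") -> list[VariantCall]:
    """Read variant calls from a MAF-like TSV or a VCF 4.2 file.

    MAF rows must carry ``t_alt_count``/``t_depth``; VAF is derived as
    alt/depth.  Malformed rows are rejected with their row numbers;
    symbolic ALT alleles (e.g. ``<DEL>``) are not supported.
    """
    if format == "maf_tsv":
        return _read_maf(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown variant format {format!r}")


def _read_maf(path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF-like TSV missing columns: {missing}")
    _check_contig_style(df["Chromosome"].unique())
    out, bad = [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            depth = int(row.t_depth)
            alt_count = int(row.t_alt_count)
            if alt_count > depth or depth < 0:
                raise ValueError("alt_count exceeds depth")
            cls = getattr(row, "Variant_Classification", "") or ""
            out.append(
                VariantCall(
                    sample_id=str(row.Tumor_Sample_Barcode),
                    chrom=_strip_chr(str(row.Chromosome)),
                    pos=int(row.Start_Position),
                    ref=str(row.Reference_Allele).upper(),
                    alt=str(row.Tumor_Seq_Allele2).upper(),
                    gene=str(row.Hugo_Symbol) if pd.notna(row.Hugo_Symbol) else "",
                    consequences=[("NA", cls)] if cls and cls == cls else [],
                    vaf=alt_count / depth if depth else float("nan"),
                    alt_count=alt_count,
                    depth=depth,
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((i, str(exc)))
    if bad:
        raise ValueError(f"malformed MAF rows (row, reason): {bad[:10]}")
    return out


def _read_vcf(path) -> list[VariantCall]:
    from cyvcf2 import VCF

    out = []
    contigs = set()
    vcf = VCF(str(path))
    samples = vcf.samples
    for i, rec in enumerate(vcf, start=1):
        contigs.add(rec.CHROM)
        for alt in rec.ALT:
            if alt.startswith("<") or alt == "*":
                raise ValueError(
                    f"VCF record {i} ({rec.CHROM}:{rec.POS}): symbolic ALT {alt!r} unsupported"
                )
            sid = samples[0] if samples else "sample"
            out.append(
                VariantCall(
                    sample_id=sid,
                    chrom=_strip_chr(rec.CHROM),
                    pos=rec.POS,
                    ref=rec.REF.upper(),
                    alt=alt.upper(),
                    caller_pass=rec.FILTER is None,  # None encodes PASS in cyvcf2
                )
            )
    _check_contig_style(contigs)
    return out


def write_variants_tsv(variants, path) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def write_vcf(variants, path) -> None:
    """Write a minimal single-column VCF 4.2 (sites + basic INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            info = f"GENE={v.gene or '.'};VAF={v.vaf:.4f}"
            filt = "PASS" if v.caller_pass else "FAIL"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\t{info}\n")


def read_bed(path) -> list[tuple]:
    """BED intervals as ``(chrom, start, end)`` (kept 0-based half-open)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {i}: fewer than 3 columns")
            out.append((_strip_chr(parts[0]), int(parts[1]), int(parts[2])))
    return out


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "age_years", "sex", "cohort", "followup_years", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical TSV missing columns: {sorted(missing)}")
    return df


def write_purity_cn(purity_cn: dict, purity_path, segments_path) -> None:
    rows = [
        {"sample_id": p.sample_id, "purity": p.purity_f, "ploidy": p.ploidy}
        for p in purity_cn.values()
    ]
    pd.DataFrame(rows).to_csv(purity_path, sep="\t", index=False)
    seg_rows = [
        {"sample_id": p.sample_id, "chrom": c, "start": s, "end": e, "cn": cn}
        for p in purity_cn.values()
        for c, s, e, cn in p.segments
    ]
    pd.DataFrame(seg_rows).to_csv(segments_path, sep="\t", index=False)


def read_purity_cn(purity_path, segments_path) -> dict:
    pur = pd.read_csv(purity_path, sep="\t")
    seg = pd.read_csv(segments_path, sep="\t", dtype={"chrom": str})
    out = {}
    for row in pur.itertuples(index=False):
        s = seg[seg["sample_id"] == row.sample_id]
        segments = [(str(r.chrom), int(r.start), int(r.end), int(r.cn))
                    for r in s.itertuples(index=False)]
        out[row.sample_id] = SamplePurityCN(
            sample_id=row.sample_id, purity_f=float(row.purity),
            ploidy=float(row.ploidy), segments=segments,
        )
    return out


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
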