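"""Cancer cell fraction (CCF) estimation and clonality calls.

The fraction of tumor cells carrying a mutation is estimated from the
observed variant allele frequency by correcting for tumor purity and for
the local copy-number state of tumor and admixed normal cells:

    CCF = VAF / purity * ((1 - purity) * cn_normal + purity * cn_tumor)

with diploid normal cells (``cn_normal = 2``).  Mutations with CCF >= 0.9
are called clonal.  Multiplicity (number of mutated copies) is deliberately
not modelled; estimates above 1 are reported and flagged rather than
clipped, since they usually indicate a multi-copy mutation or a purity/CN
mismatch worth inspecting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SamplePurityCN",
    "CCFRecord",
    "compute_ccf",
    "call_clonal",
    "lookup_cn",
    "ccf_table",
]

logger = logging.getLogger(__name__)

CLONAL_THRESHOLD = 0.9


@dataclass
class SamplePurityCN:
    """Per-sample purity, ploidy and tumor copy-number segments.

    Segments are half-open ``[start, end)`` on 1-based coordinates and must
    not overlap within a chromosome.
    """

    sample_id: str
    purity_f: float
    ploidy: float
    segments: list = field(default_factory=list)  # [(chrom, start, end, cn_tumor)]
    n_cn_normal: int = 2

    def __post_init__(self):
        if not (0 < self.purity_f <= 1):
            raise ValueError(f"purity must be in (0, 1], got {self.purity_f}")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        by_chrom: dict = {}
        for chrom, start, end, cn in self.segments:
            if end <= start:
                raise ValueError(f"malformed segment {chrom}:{start}-{end}")
            if cn < 0:
                raise ValueError("negative tumor copy number")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping segments on {chrom}")


@dataclass
class CCFRecord:
    variant_key: tuple
    sample_id: str
    vaf_f: float
    ccf_f: float
    n_cn_tumor_used: int
    clonal: bool = False
    cn_fallback: bool = False  # True when no segment covered the variant

    @property
    def superclonal(self) -> bool:
        return self.ccf_f > 1.0


def compute_ccf(vaf: float, purity: float, cn_tumor: float, cn_normal: float = 2.0) -> float:
    """CCF from VAF, tumor purity and local copy numbers (no clipping)."""
    if purity == 0:
        raise ZeroDivisionError("CCF undefined at purity 0")
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if not (0 <= vaf <= 1):
        raise ValueError(f"VAF must be in [0, 1], got {vaf}")
    if cn_tumor < 0 or cn_normal < 0:
        raise ValueError("copy numbers must be non-negative")
    return vaf / purity * ((1.0 - purity) * cn_normal + purity * cn_tumor)


def call_clonal(records, threshold: float = CLONAL_THRESHOLD):
    """Set the clonal flag (CCF >= threshold, boundary inclusive) in place.

    Returns ``(records, summary)`` where summary counts clonal/subclonal
    variants per sample.
    """
    for r in records:
        r.clonal = r.ccf_f >= threshold
    rows = {}
    for r in records:
        d = rows.setdefault(r.sample_id, {"sample_id": r.sample_id, "n_clonal": 0, "n_subclonal": 0})
        d["n_clonal" if r.clonal else "n_subclonal"] += 1
    summary = pd.DataFrame(rows.values(), columns=["sample_id", "n_clonal", "n_subclonal"])
    return records, summary


def lookup_cn(variant_key: tuple, purity_cn: SamplePurityCN) -> tuple[int, bool]:
    """Tumor copy number at a variant position.

    Returns ``(cn_tumor, fallback)``; when the variant lies outside every
    segment (or on an absent chromosome) the ploidy rounded to the nearest
    integer is used and ``fallback`` is True.
    """
    chrom, pos = variant_key[0], variant_key[1]
    for seg_chrom, start, end, cn in purity_cn.segments:
        if seg_chrom == chrom and start <= pos < end:
            return int(cn), False
    fallback = int(round(purity_cn.ploidy))
    logger.warning(
        "variant %s:%s outside all CN segments of %s; ploidy fallback cn=%d",
        chrom, pos, purity_cn.sample_id, fallback,
    )
    return fallback, True


def ccf_table(variants, purity_cn_by_sample: dict, threshold: float = CLONAL_THRESHOLD):
    """Estimate CCF for every variant whose sample has purity/CN data.

    Samples without purity/CN are skipped with a logged count (no
    imputation).  Returns ``(records, n_skipped)``.
    """
    records, n_skipped = [], 0
    for v in variants:
        pcn = purity_cn_by_sample.get(v.sample_id)
        if pcn is None:
            n_skipped += 1
            continue
        key = v.key()
        cn, fb = lookup_cn(key, pcn)
        ccf = compute_ccf(v.vaf, pcn.purity_f, cn, pcn.n_cn_normal)
        records.append(
            CCFRecord(
                variant_key=key,
                sample_id=v.sample_id,
                vaf_f=v.vaf,
                ccf_f=ccf,
                n_cn_tumor_used=cn,
                clonal=ccf >= threshold,
                cn_fallback=fb,
            )
        )
    if n_skipped:
        logger.info("skipped %d variants from samples without purity/CN", n_skipped)
    return records, n_skipped
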