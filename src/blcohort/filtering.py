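"""Panel-of-normals construction and the ordered somatic filter hierarchy.

Raw variant calls from a targeted panel are dominated by germline
polymorphisms and pipeline artifacts.  This module turns them into called
somatic mutations through an explicit, ordered chain of filters (panel of
normals, population allele frequency, dbSNP-common, read support,
consequence class), recording a per-variant verdict trail and a per-step
retention table so the provenance of every call is auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantCall",
    "PanelOfNormals",
    "FilterConfig",
    "DEFAULT_SEVERITY_ORDER",
    "normalize_variant_key",
    "left_align",
    "strongest_consequence",
    "build_pon",
    "apply_filter_hierarchy",
    "variants_to_frame",
]

_ALLELE_RE = re.compile(r"^[ACGTN]+$")

#: Consequence classes ordered from most to least severe at protein level.
DEFAULT_SEVERITY_ORDER = (
    "frameshift",
    "nonsense",
    "stop_lost",
    "start_lost",
    "splice_site",
    "inframe_indel",
    "missense",
    "splice_region",
    "synonymous",
    "UTR",
    "intronic",
    "upstream",
    "intergenic",
)


@dataclass
class VariantCall:
    """One called variant in one sample, with its annotation and filter trail."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    consequences: list = field(default_factory=list)  # [(transcript_id, class)]
    vaf: float = float("nan")
    alt_count: int = 0
    depth: int = 0
    caller_pass: bool = True
    pop_af: float | None = None
    in_cosmic: bool = False
    dbsnp_common: bool = False
    clinvar_class: str | None = None
    paired_normal: bool = True
    filter_trail: list = field(default_factory=list)  # [(step_name, kept)]

    def key(self) -> tuple:
        return normalize_variant_key(self.chrom, self.pos, self.ref, self.alt)


def _check_allele(allele: str, what: str) -> None:
    if not allele:
        raise ValueError(f"empty {what} allele")
    if not _ALLELE_RE.match(allele):
        raise ValueError(f"{what} allele {allele!r} contains non-nucleotide characters")


def normalize_variant_key(
    chrom: str, pos: int, ref: str, alt: str, reference: str | None = None
) -> tuple:
    """Canonical key ``(chrom, pos, ref, alt)`` for matching variant records.

    Shared suffix then shared prefix bases are trimmed (parsimony), the
    position advancing over trimmed prefix bases; after full trimming one
    allele of an indel may be empty.  SNVs pass through unchanged.  If
    ``reference`` (the contig sequence, 1-based conceptually) is given,
    pure indels are additionally left-aligned by shifting through repeat
    context, so equivalent representations of the same event in repetitive
    sequence collapse to one key.
    """
    chrom = str(chrom)
    ref = ref.upper()
    alt = alt.upper()
    _check_allele(ref, "ref")
    _check_allele(alt, "alt")
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    # trim shared suffix, then shared prefix (position advances over prefix)
    while len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValueError("ref and alt are identical after normalization")
    if reference is not None and (ref == "" or alt == ""):
        pos, ref, alt = _left_shift(pos, ref, alt, reference)
    return (chrom, pos, ref, alt)


def _left_shift(pos: int, ref: str, alt: str, reference: str) -> tuple[int, str, str]:
    """Shift a trimmed pure indel left through repeat context (VCF convention)."""
    seq = ref if alt == "" else alt
    while pos > 1 and seq and reference[pos - 2] == seq[-1]:
        seq = reference[pos - 2] + seq[:-1]
        pos -= 1
    if alt == "":
        return pos, seq, ""
    return pos, "", seq


def left_align(chrom: str, pos: int, ref: str, alt: str, reference: str) -> tuple:
    """Left-aligned anchored representation of a variant (VCF style).

    Returns ``(chrom, pos, ref, alt)`` where indels carry the shared
    anchor base preceding the event, matching how VCF rows are written.
    """
    c, p, r, a = normalize_variant_key(chrom, pos, ref, alt, reference=reference)
    if r and a:
        return (c, p, r, a)
    if p < 1:
        raise ValueError("cannot anchor at position 0")
    anchor = reference[p - 2] if p > 1 else reference[0]
    if p > 1:
        return (c, p - 1, anchor + r, anchor + a)
    return (c, p, r + reference[p - 1 + len(r)], a + reference[p - 1 + len(r)])


def strongest_consequence(consequences, severity_order=DEFAULT_SEVERITY_ORDER):
    """Pick the (transcript, class) pair with the most severe protein-level class.

    Genes commonly have several transcripts and the same genomic variant can
    be intronic on one and protein-changing on another; calling on the
    transcript with the strongest consequence avoids discarding such
    variants.  Ties break on the lexicographically smallest transcript id.
    """
    if not consequences:
        raise ValueError("empty consequence list")
    rank = {c: i for i, c in enumerate(severity_order)}
    for _, cls in consequences:
        if cls not in rank:
            raise ValueError(f"unknown consequence class: {cls!r}")
    return min(consequences, key=lambda tc: (rank[tc[1]], tc[0]))


@dataclass
class PanelOfNormals:
    """Catalog of variant keys recurrently seen across normal subjects.

    A key is a member iff it was seen in at least ``min_support`` distinct
    normal subjects; membership removes germline variants and recurrent
    pipeline artifacts from tumor call sets.
    """

    entries: dict = field(default_factory=dict)  # key -> n distinct subjects
    min_support: int = 2

    def __contains__(self, key) -> bool:
        return self.entries.get(key, 0) >= self.min_support

    def __len__(self) -> int:
        return sum(1 for v in self.entries.values() if v >= self.min_support)


def build_pon(normal_variants, min_support: int = 2) -> PanelOfNormals:
    """Build a panel of normals from per-subject normal-sample variant calls.

    Duplicate records of the same key within one subject count once; the
    support count is the number of distinct subjects carrying the key.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    seen: set[tuple] = set()
    counts: dict = {}
    for v in normal_variants:
        pair = (v.sample_id, v.key())
        if pair in seen:
            continue
        seen.add(pair)
        counts[pair[1]] = counts.get(pair[1], 0) + 1
    return PanelOfNormals(entries=counts, min_support=min_support)


@dataclass
class FilterConfig:
    """Ordered multistage filter hierarchy configuration.

    Steps run in the order of :attr:`steps`; each is recorded in every
    variant's filter trail.  ``cosmic_rescue`` retains a variant failing the
    population-frequency or dbSNP-common steps when it is a confirmed
    somatic mutation in COSMIC.
    """

    caller_pass_required: bool = True
    pon: PanelOfNormals | None = None
    max_pop_af: float = 0.001
    drop_dbsnp_common: bool = True
    cosmic_rescue: bool = True
    min_depth: int = 20
    min_alt_count: int = 3
    min_vaf: float = 0.05
    min_vaf_unpaired: float = 0.10
    consequence_blacklist: frozenset = frozenset({"synonymous", "intronic", "intergenic", "UTR", "upstream"})
    severity_order: tuple = DEFAULT_SEVERITY_ORDER
    steps: tuple = (
        "caller_pass",
        "panel_of_normals",
        "population_af",
        "dbsnp_common",
        "min_depth",
        "min_alt_count",
        "min_vaf",
        "consequence",
    )

    def __post_init__(self):
        if not (0 <= self.max_pop_af <= 1):
            raise ValueError("max_pop_af must be in [0, 1]")
        if not (0 <= self.min_vaf <= 1) or not (0 <= self.min_vaf_unpaired <= 1):
            raise ValueError("VAF thresholds must be in [0, 1]")
        if self.min_depth < 0 or self.min_alt_count < 0:
            raise ValueError("read-support thresholds must be non-negative")


def _step_verdict(v: VariantCall, step: str, cfg: FilterConfig) -> bool:
    if step == "caller_pass":
        return v.caller_pass or not cfg.caller_pass_required
    if step == "panel_of_normals":
        return cfg.pon is None or v.key() not in cfg.pon
    if step == "population_af":
        ok = v.pop_af is None or v.pop_af <= cfg.max_pop_af
        return ok or (cfg.cosmic_rescue and v.in_cosmic)
    if step == "dbsnp_common":
        ok = not (cfg.drop_dbsnp_common and v.dbsnp_common)
        return ok or (cfg.cosmic_rescue and v.in_cosmic)
    if step == "min_depth":
        return v.depth >= cfg.min_depth
    if step == "min_alt_count":
        return v.alt_count >= cfg.min_alt_count
    if step == "min_vaf":
        thr = cfg.min_vaf if v.paired_normal else cfg.min_vaf_unpaired
        return v.vaf >= thr
    if step == "consequence":
        if not v.consequences:
            return True
        _, cls = strongest_consequence(v.consequences, cfg.severity_order)
        return cls not in cfg.consequence_blacklist
    raise ValueError(f"unknown filter step: {step!r}")


def apply_filter_hierarchy(variants, config: FilterConfig):
    """Run the ordered filter chain over a list of :class:`VariantCall`.

    Returns ``(called, retention)``: the surviving calls (with filter
    trails populated; a trail stops at the first failing step) and a
    retention table with one row per step giving ``n_in``, ``n_out`` and
    the percentage of the *original* input remaining after the step.
    """
    n0 = len(variants)
    alive = list(variants)
    for v in alive:
        v.filter_trail = []
    rows = []
    for step in config.steps:
        n_in = len(alive)
        nxt = []
        for v in alive:
            kept = _step_verdict(v, step, config)
            v.filter_trail.append((step, kept))
            if kept:
                nxt.append(v)
        alive = nxt
        rows.append(
            {
                "step": step,
                "n_in": n_in,
                "n_out": len(alive),
                "pct_remaining": 100.0 * len(alive) / n0 if n0 else 0.0,
            }
        )
    retention = pd.DataFrame(rows, columns=["step", "n_in", "n_out", "pct_remaining"])
    return alive, retention


def replay_trails(variants) -> list:
    """Re-derive the called set from recorded filter trails alone."""
    return [v for v in variants if v.filter_trail and all(kept for _, kept in v.filter_trail)]


def variants_to_frame(variants) -> pd.DataFrame:
    """Tabulate VariantCall records as a MAF-like DataFrame."""
    return pd.DataFrame(
        {
            "Tumor_Sample_Barcode": [v.sample_id for v in variants],
            "Hugo_Symbol": [v.gene for v in variants],
            "Chromosome": [v.chrom for v in variants],
            "Start_Position": [v.pos for v in variants],
            "Reference_Allele": [v.ref for v in variants],
            "Tumor_Seq_Allele2": [v.alt for v in variants],
            "Variant_Classification": [
                strongest_consequence(v.consequences)[1] if v.consequences else ""
                for v in variants
            ],
            "t_alt_count": [v.alt_count for v in variants],
            "t_depth": [v.depth for v in variants],
            "vaf": [v.vaf for v in variants],
        }
    )
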