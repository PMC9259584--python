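"""Gene x patient mutation matrix and sub-cohort association testing.

Builds the binary/count mutation matrix from called somatic variants,
compares per-gene mutation frequencies between clinically defined
sub-cohorts with one-tailed Fisher exact tests (testing the observed
enriched side), controls the false discovery rate with Benjamini-Hochberg
at q = 0.1 over genes with at least 2% overall mutation frequency, and
summarizes pairwise mutual exclusivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MutationMatrix",
    "AssocResult",
    "build_matrix",
    "fisher_one_sided",
    "bh_fdr",
    "run_comparisons",
    "exclusivity_summary",
    "per_sample_rate",
    "results_frame",
    "stars",
]

MIN_FREQUENCY = 0.02  # genes eligible for testing: >= 2% cohort mutation frequency
Q_THRESHOLD = 0.1


@dataclass
class MutationMatrix:
    """Gene x patient mutation counts with aligned clinical records."""

    genes: list
    patients: list
    counts: pd.DataFrame  # genes x patients, non-negative ints
    clinical: pd.DataFrame  # one row per patient, aligned to columns

    def __post_init__(self):
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("duplicate patients")
        if list(self.counts.columns) != list(self.patients):
            raise ValueError("count columns must match patient order")
        if list(self.clinical["patient_id"]) != list(self.patients):
            raise ValueError("clinical order must match patient order")

    @property
    def indicator(self) -> pd.DataFrame:
        return (self.counts >= 1).astype(int)

    def frequency(self, gene: str, mask=None) -> float:
        row = self.indicator.loc[gene]
        if mask is not None:
            row = row[np.asarray(mask, dtype=bool)]
        return float(row.mean()) if len(row) else float("nan")

    def mean_count_per_case(self, gene: str) -> float:
        """Average number of mutations per case (all cases, multiplicity kept)."""
        return float(self.counts.loc[gene].mean())


@dataclass
class AssocResult:
    gene: str
    group_a_k: int
    group_a_n: int
    group_b_k: int
    group_b_n: int
    direction: str  # side actually tested: 'a_greater' or 'b_greater'
    p_one_sided: float
    fdr_q: float = float("nan")
    significant: bool = False
    stars: str = "ns"

    @property
    def freq_a(self) -> float:
        return self.group_a_k / self.group_a_n

    @property
    def freq_b(self) -> float:
        return self.group_b_k / self.group_b_n


def stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def build_matrix(variants, clinical: pd.DataFrame) -> MutationMatrix:
    """Aggregate called variants into a gene x patient count matrix.

    Every variant's sample must map to a clinical record; orphan samples
    raise an explicit error listing them.  Patients without variants get
    all-zero columns, preserving cohort denominators.
    """
    patients = list(clinical["patient_id"])
    pset = set(patients)
    orphans = sorted({v.sample_id for v in variants} - pset)
    if orphans:
        raise ValueError(f"variants from samples without clinical records: {orphans}")
    genes = sorted({v.gene for v in variants if v.gene})
    counts = pd.DataFrame(0, index=genes, columns=patients, dtype=int)
    for v in variants:
        if v.gene:
            counts.loc[v.gene, v.sample_id] += 1
    return MutationMatrix(genes=genes, patients=patients, counts=counts,
                          clinical=clinical.reset_index(drop=True))


def fisher_one_sided(k_a: int, n_a: int, k_b: int, n_b: int, direction: str = "a_greater") -> float:
    """One-tailed Fisher exact p: tables at least as extreme in one direction.

    Conditions on the margins: the tail probability of a hypergeometric
    draw of ``k_a`` successes in ``n_a`` draws from ``k_a + k_b`` successes
    among ``n_a + n_b`` subjects.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ValueError("mutated counts must lie within group sizes")
    if direction == "b_greater":
        k_a, n_a, k_b, n_b = k_b, n_b, k_a, n_a
    elif direction != "a_greater":
        raise ValueError(f"unknown direction {direction!r}")
    m = k_a + k_b
    return float(stats.hypergeom.sf(k_a - 1, n_a + n_b, m, n_a))


def bh_fdr(p_values, q_threshold: float = Q_THRESHOLD):
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= q_threshold


#: Clinical contrasts mirrored from the study: each maps a comparison name to
#: a (mask_a, mask_b) pair over the clinical table.
def _comparison_masks(clinical: pd.DataFrame, comparison: str):
    c = clinical
    if comparison == "pediatric_vs_adult":
        return c["cohort"] == "pediatric", c["cohort"] == "adult"
    if comparison == "female_vs_male":
        return c["sex"] == "female", c["sex"] == "male"
    if comparison == "under10_vs_over10":
        ped = c["cohort"] == "pediatric"
        return ped & (c["age_years"] < 10), ped & (c["age_years"] >= 10)
    if comparison == "cns_vs_no_cns":
        ped = c["cohort"] == "pediatric"
        return ped & c["cns_involved"].astype(bool), ped & ~c["cns_involved"].astype(bool)
    if comparison == "bm_vs_no_bm":
        ped = c["cohort"] == "pediatric"
        return ped & c["bm_involved"].astype(bool), ped & ~c["bm_involved"].astype(bool)
    if comparison == "bal_vs_bl":
        return c["entity"] == "B-AL", c["entity"] == "BL"
    raise ValueError(f"unknown comparison {comparison!r}")


def run_comparisons(
    matrix: MutationMatrix,
    comparison: str,
    min_frequency: float = MIN_FREQUENCY,
    q_threshold: float = Q_THRESHOLD,
):
    """One-sided Fisher tests for every eligible gene in one clinical contrast.

    Eligible genes have at least ``min_frequency`` overall mutation
    frequency among the compared patients.  The tested side per gene
    follows the observed frequency difference (recorded in ``direction``);
    FDR is controlled within this comparison family.  Patients with a
    missing grouping field fall in neither group and are dropped from this
    comparison only.
    """
    mask_a, mask_b = _comparison_masks(matrix.clinical, comparison)
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(f"comparison {comparison!r} has an empty group")
    ind = matrix.indicator
    either = mask_a | mask_b
    results = []
    for gene in matrix.genes:
        row = ind.loc[gene].to_numpy()
        if row[either].mean() < min_frequency:
            continue
        k_a = int(row[mask_a].sum())
        k_b = int(row[mask_b].sum())
        direction = "a_greater" if k_a / n_a >= k_b / n_b else "b_greater"
        p = fisher_one_sided(k_a, n_a, k_b, n_b, direction)
        results.append(
            AssocResult(gene=gene, group_a_k=k_a, group_a_n=n_a,
                        group_b_k=k_b, group_b_n=n_b,
                        direction=direction, p_one_sided=p)
        )
    if results:
        q, sig = bh_fdr([r.p_one_sided for r in results], q_threshold)
        for r, qv, s in zip(results, q, sig):
            r.fdr_q = float(qv)
            r.significant = bool(s)
            r.stars = stars(r.p_one_sided)
    return results


def exclusivity_summary(matrix: MutationMatrix, gene_a: str, gene_b: str, mask=None) -> dict:
    """Pairwise co-occurrence cells and percent of cases with exactly one/either."""
    for g in (gene_a, gene_b):
        if g not in matrix.counts.index:
            raise KeyError(f"gene {g!r} not in matrix")
    a = matrix.indicator.loc[gene_a].to_numpy().astype(bool)
    b = matrix.indicator.loc[gene_b].to_numpy().astype(bool)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        a, b = a[m], b[m]
    n = a.size
    both = int((a & b).sum())
    only_a = int((a & ~b).sum())
    only_b = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    return {
        "both": both,
        "only_a": only_a,
        "only_b": only_b,
        "neither": neither,
        "n": n,
        "both_pct": 100.0 * both / n if n else float("nan"),
        "exactly_one_pct": 100.0 * (only_a + only_b) / n if n else float("nan"),
        "either_pct": 100.0 * (both + only_a + only_b) / n if n else float("nan"),
    }


def per_sample_rate(n_mutations: int, n_cases: int, decimals: int = 2) -> float:
    """Average number of mutations per case, rounded for reporting."""
    if n_cases <= 0:
        raise ValueError("number of cases must be positive")
    return round(n_mutations / n_cases, decimals)


def results_frame(results) -> pd.DataFrame:
    """AssocResult list as a tidy DataFrame."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "group_a_k": [r.group_a_k for r in results],
            "group_a_n": [r.group_a_n for r in results],
            "group_b_k": [r.group_b_k for r in results],
            "group_b_n": [r.group_b_n for r in results],
            "freq_a": [r.freq_a for r in results],
            "freq_b": [r.freq_b for r in results],
            "direction": [r.direction for r in results],
            "p_one_sided": [r.p_one_sided for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "significant": [r.significant for r in results],
            "stars": [r.stars for r in results],
        }
    )
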