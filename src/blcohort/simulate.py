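"""Synthetic Burkitt-lymphoma cohort generator.

Generates the complete input stack the downstream analyses consume —
clinical table, tumor variant calls (true somatic plus germline, recurrent
artifact and random-noise calls), matched-normal variant calls for
panel-of-normals construction, per-sample purity/ploidy/copy-number
segments, and orthogonal-validation truth lists — with the statistical
structure the analyses assume:

* per-gene mutation probability follows a logistic transition over age,
  ``p(age) = p_young + (p_old - p_young) * sigmoid((age - a0) / w)``,
  centered by default at 35 years with width 5;
* sex-biased genes multiply the (female-baseline) mutation odds for males;
* relapse, death-in-remission, second-malignancy and other-death times are
  drawn from cause-specific exponential hazards, with per-lesion
  multiplicative hazard ratios on relapse and administrative censoring;
* variant allele frequencies are generated by inverting the purity/copy-
  number CCF relation from a drawn cancer cell fraction (a clonal mass at
  1.0 plus a subclonal tail) and then binomially resampled at a fixed
  sequencing depth.

A single integer seed drives one generator stream; fixed seed means
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .clonality import SamplePurityCN
from .filtering import VariantCall

__all__ = [
    "GeneModel",
    "CohortConfig",
    "SimulatedCohort",
    "default_gene_models",
    "plateau_from_adult_frequency",
    "calibrate_relapse_hazards",
    "logistic_mutation_prob",
    "simulate_clinical",
    "simulate_cohort",
    "simulate_sanger_truth",
]

logger = logging.getLogger(__name__)

EVENT_TYPES = ("relapse_progression", "death_in_remission", "second_malignancy", "death_other")

#: Approximate GRCh38 loci used to place synthetic variants (chrom, start, end).
GENE_LOCI = {
    "MYC": ("8", 127_735_434, 127_742_951),
    "ID3": ("1", 23_557_930, 23_559_794),
    "TP53": ("17", 7_668_402, 7_687_550),
    "CCND3": ("6", 41_934_933, 41_956_413),
    "SMARCA4": ("19", 10_960_928, 11_062_273),
    "DDX3X": ("X", 41_333_308, 41_364_472),
    "ARID1A": ("1", 26_696_031, 26_782_110),
    "FBXO11": ("2", 47_806_920, 47_906_498),
    "FOXO1": ("13", 40_555_667, 40_666_641),
    "TCF3": ("19", 1_609_290, 1_652_615),
    "GNA13": ("17", 65_007_822, 65_056_741),
    "PTEN": ("10", 87_863_113, 87_971_930),
    "PCBP1": ("2", 70_087_954, 70_089_968),
    "BCL2": ("18", 63_123_346, 63_320_128),
    "YY1AP1": ("1", 155_665_401, 155_690_940),
    "CREBBP": ("16", 3_725_054, 3_880_726),
    "PIM1": ("6", 37_170_173, 37_175_558),
    "CARD11": ("7", 2_906_142, 3_043_945),
    "SOCS1": ("16", 11_254_417, 11_256_204),
    "DTX1": ("12", 113_057_651, 113_098_457),
    "P2RY8": ("X", 1_462_581, 1_537_185),
}

GPC5_REGION = ("13", 91_398_619, 92_867_237)  # recurrent gain/amplification locus


@dataclass(frozen=True)
class GeneModel:
    """Generative mutation model for one gene.

    ``p_young``/``p_old`` are the mutation probabilities of *female*
    patients at the young and old plateaus of the logistic age transition;
    males multiply the odds by ``sex_odds_male``.  A mutated case carries
    ``1 + Poisson(mean_muts_if_mutated - 1)`` distinct variants.
    """

    gene: str
    p_young: float
    p_old: float
    sex_odds_male: float = 1.0
    mean_muts_if_mutated: float = 1.0

    def __post_init__(self):
        if not (0 <= self.p_young <= 1 and 0 <= self.p_old <= 1):
            raise ValueError(f"{self.gene}: probabilities must lie in [0, 1]")
        if self.sex_odds_male <= 0:
            raise ValueError(f"{self.gene}: sex_odds_male must be positive")
        if self.mean_muts_if_mutated < 1:
            raise ValueError(f"{self.gene}: mean_muts_if_mutated must be >= 1")


def _triangular_pdf(a, lo=18.0, mode=52.0, hi=85.0):
    a = np.asarray(a, dtype=float)
    up = 2 * (a - lo) / ((hi - lo) * (mode - lo))
    down = 2 * (hi - a) / ((hi - lo) * (hi - mode))
    return np.where(a < mode, up, down) * ((a >= lo) & (a <= hi))


def plateau_from_adult_frequency(
    p_young: float, adult_freq: float, a0: float = 35.0, w: float = 5.0
) -> float:
    """Old-age plateau giving the target *observed* adult mutation frequency.

    A cohort's adult frequency averages the logistic curve over the adult
    age distribution, which includes young adults still close to the
    pediatric plateau; the printed adult frequency therefore sits between
    the two plateaus.  With the default triangular adult ages,
    ``E[sigmoid((A - a0)/w)] ~ 0.82``, so reproducing a printed adult
    frequency requires a more extreme plateau than the frequency itself.
    """
    grid = np.linspace(18.0, 85.0, 2001)
    sig = 1.0 / (1.0 + np.exp(-(grid - a0) / w))
    mean_sig = np.trapezoid(_triangular_pdf(grid) * sig, grid)
    p_old = p_young + (adult_freq - p_young) / mean_sig
    return float(np.clip(p_old, 0.0, 1.0))


def default_gene_models() -> list[GeneModel]:
    """Gene panel mirroring the printed cohort frequencies.

    Frequencies echo the study's figures: ID3 mutated in ~76% of children
    vs ~40% of adults (with ~1.7 variants per mutated case), MYC in ~70%
    with multiple variants per case (1.7 per case on average), DDX3X with a
    strong male bias (~46% male vs ~4% female in children), BCL2 and
    YY1AP1 essentially absent before the age transition, TP53/CCND3/MYC
    age-independent.  Old-age plateaus are derived from the target adult
    frequencies via :func:`plateau_from_adult_frequency`; for ID3 this puts
    the plateau at ~42% of the pediatric level, consistent with its
    mutation density relative to children falling to about 40%.
    """

    def gm(gene, p_young, adult_freq, **kw):
        return GeneModel(gene, p_young,
                         plateau_from_adult_frequency(p_young, adult_freq), **kw)

    return [
        gm("MYC", 0.70, 0.72, mean_muts_if_mutated=2.4),
        gm("ID3", 0.76, 0.40, mean_muts_if_mutated=1.7),
        gm("TP53", 0.30, 0.32, mean_muts_if_mutated=1.3),
        gm("CCND3", 0.28, 0.24, mean_muts_if_mutated=1.2),
        gm("SMARCA4", 0.30, 0.12, mean_muts_if_mutated=1.1),
        gm("DDX3X", 0.04, 0.02, sex_odds_male=20.0, mean_muts_if_mutated=1.1),
        gm("ARID1A", 0.32, 0.13, mean_muts_if_mutated=1.1),
        gm("FBXO11", 0.22, 0.15, mean_muts_if_mutated=1.1),
        gm("FOXO1", 0.20, 0.15, mean_muts_if_mutated=1.1),
        gm("TCF3", 0.25, 0.20, mean_muts_if_mutated=1.1),
        gm("GNA13", 0.15, 0.05),
        gm("PTEN", 0.08, 0.02),
        gm("PCBP1", 0.10, 0.08),
        gm("BCL2", 0.005, 0.45, mean_muts_if_mutated=1.5),
        gm("YY1AP1", 0.005, 0.30, mean_muts_if_mutated=1.2),
        gm("CREBBP", 0.03, 0.20),
        gm("PIM1", 0.02, 0.15),
        gm("CARD11", 0.03, 0.15),
        gm("SOCS1", 0.02, 0.12),
        gm("DTX1", 0.02, 0.12),
        gm("P2RY8", 0.05, 0.03),
    ]


def calibrate_relapse_hazards(
    cif_mut: float = 0.25,
    cif_wt: float = 0.06,
    horizon: float = 3.0,
    competing_hazard: float = 0.022,
) -> tuple[float, float]:
    """Baseline relapse hazard and lesion hazard ratio hitting target CIFs.

    Under cause-specific exponential hazards the relapse CIF at time ``t``
    is ``lam_r / lam * (1 - exp(-lam * t))`` with ``lam = lam_r + lam_c``.
    Solves for the wild-type baseline ``lam_r`` reaching ``cif_wt`` at the
    horizon and the multiplier reaching ``cif_mut``.
    """

    def cif_at(lam_r):
        lam = lam_r + competing_hazard
        return lam_r / lam * (1.0 - np.exp(-lam * horizon))

    lam_wt = brentq(lambda l: cif_at(l) - cif_wt, 1e-8, 10.0)
    lam_mut = brentq(lambda l: cif_at(l) - cif_mut, 1e-8, 10.0)
    return lam_wt, lam_mut / lam_wt


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_pediatric: int = 191
    n_adult: int = 97
    seed: int = 0
    gene_models: list = field(default_factory=default_gene_models)
    transition_center_a0: float = 35.0
    transition_width_w: float = 5.0
    male_fraction_pediatric: float = 0.70
    male_fraction_adult: float = 0.60
    censor_time: float = 8.0
    cause_hazards: dict = None  # event type -> baseline rate per year
    hazard_ratios: dict = None  # lesion symbol -> multiplier on relapse hazard
    depth: int = 200
    clonal_fraction: float = 0.8
    purity_range: tuple = (0.4, 0.95)
    gpc5_gain_prob: float = 0.18
    n_matched_normals: int = 86
    n_germline_per_sample: int = 1600
    n_noise_per_sample: int = 600
    n_artifact_sites: int = 600
    artifact_tumor_prob: float = 0.5
    artifact_normal_prob: float = 0.5
    n_snp_sites: int = 8000

    def __post_init__(self):
        if self.n_pediatric < 0 or self.n_adult < 0 or self.n_pediatric + self.n_adult < 2:
            raise ValueError("cohort sizes must be non-negative and total >= 2")
        for frac in (self.male_fraction_pediatric, self.male_fraction_adult,
                     self.clonal_fraction, self.gpc5_gain_prob,
                     self.artifact_tumor_prob, self.artifact_normal_prob):
            if not (0 <= frac <= 1):
                raise ValueError(f"proportion out of [0, 1]: {frac}")
        if self.transition_width_w <= 0:
            raise ValueError("transition width must be positive")
        if self.cause_hazards is None:
            lam_wt, hr = calibrate_relapse_hazards()
            self.cause_hazards = {
                "relapse_progression": lam_wt,
                "death_in_remission": 0.015,
                "second_malignancy": 0.005,
                "death_other": 0.002,
            }
            if self.hazard_ratios is None:
                self.hazard_ratios = {"TP53": hr}
        if self.hazard_ratios is None:
            self.hazard_ratios = {}
        for rate in self.cause_hazards.values():
            if rate < 0:
                raise ValueError("hazards must be non-negative")
        for mult in self.hazard_ratios.values():
            if mult < 0:
                raise ValueError("hazard ratios must be non-negative")


@dataclass
class SimulatedCohort:
    clinical: pd.DataFrame
    variants: list  # tumor VariantCall records (somatic + germline + artifact + noise)
    normals: list  # VariantCall records from matched-normal subjects
    purity_cn: dict  # sample_id -> SamplePurityCN
    gene_status: pd.DataFrame  # genes x patients, true mutation indicator
    truth: pd.DataFrame  # per somatic variant: true CCF, exact VAF, copy number
    config: CohortConfig = None


def logistic_mutation_prob(age, model: GeneModel, a0: float, w: float, male) -> np.ndarray:
    """Per-patient mutation probability under the logistic age transition."""
    age = np.asarray(age, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-(age - a0) / w))
    p = model.p_young + (model.p_old - model.p_young) * sig
    male = np.asarray(male, dtype=bool)
    if model.sex_odds_male != 1.0:
        odds = p / np.clip(1.0 - p, 1e-12, None) * model.sex_odds_male
        p_male = odds / (1.0 + odds)
        p = np.where(male, p_male, p)
    return np.clip(p, 0.0, 1.0)


def _draw_ages(rng, n_ped: int, n_adult: int) -> np.ndarray:
    # pediatric: discretized symmetric-beta ages on [0, 18], median 9
    ped = np.round(rng.beta(2.0, 2.0, n_ped) * 18.0)
    # adult: triangular on (18, 85] with mode 52
    adult = rng.triangular(18.0, 52.0, 85.0, n_adult)
    adult = np.round(np.maximum(adult, 18.01), 1)
    return np.concatenate([ped, adult])


def simulate_clinical(config: CohortConfig, rng: np.random.Generator | None = None):
    """Clinical table plus true per-gene mutation status and counts.

    Returns ``(clinical, gene_status, gene_counts)`` where the frames'
    columns are patient ids in cohort order.  Event times are drawn from
    cause-specific exponential hazards; lesions named in
    ``config.hazard_ratios`` (mutated genes, or the GPC5 copy-gain flag)
    multiply the relapse hazard.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_pediatric + config.n_adult
    patient_ids = [f"P{i:04d}" for i in range(n)]
    ages = _draw_ages(rng, config.n_pediatric, config.n_adult)
    cohort = np.where(ages <= 18, "pediatric", "adult")
    male_frac = np.where(cohort == "pediatric", config.male_fraction_pediatric,
                         config.male_fraction_adult)
    male = rng.random(n) < male_frac
    genes = [m.gene for m in config.gene_models]
    status = np.zeros((len(genes), n), dtype=bool)
    counts = np.zeros((len(genes), n), dtype=int)
    for gi, model in enumerate(config.gene_models):
        p = logistic_mutation_prob(ages, model, config.transition_center_a0,
                                   config.transition_width_w, male)
        status[gi] = rng.random(n) < p
        extra = rng.poisson(model.mean_muts_if_mutated - 1.0, n)
        counts[gi] = np.where(status[gi], 1 + extra, 0)

    gpc5_gain = (cohort == "pediatric") & (rng.random(n) < config.gpc5_gain_prob)

    # cause-specific exponential event times with lesion multipliers on relapse
    lam_relapse = np.full(n, config.cause_hazards.get("relapse_progression", 0.0))
    for lesion, mult in config.hazard_ratios.items():
        if lesion == "GPC5":
            carrier = gpc5_gain
        elif lesion in genes:
            carrier = status[genes.index(lesion)]
        else:
            carrier = np.zeros(n, dtype=bool)
        lam_relapse = np.where(carrier, lam_relapse * mult, lam_relapse)
    cause_times = {}
    with np.errstate(divide="ignore"):
        cause_times["relapse_progression"] = np.where(
            lam_relapse > 0, rng.exponential(1.0, n) / np.clip(lam_relapse, 1e-300, None), np.inf
        )
        for ev in EVENT_TYPES[1:]:
            lam = config.cause_hazards.get(ev, 0.0)
            cause_times[ev] = (
                rng.exponential(1.0 / lam, n) if lam > 0 else np.full(n, np.inf)
            )
    t_event = np.min(np.stack([cause_times[ev] for ev in EVENT_TYPES]), axis=0)
    which = np.argmin(np.stack([cause_times[ev] for ev in EVENT_TYPES]), axis=0)
    censor = rng.uniform(2.0, config.censor_time, n)
    followup = np.minimum(t_event, censor)
    event = np.where(t_event <= censor,
                     np.array(EVENT_TYPES, dtype=object)[which], "none")

    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "age_years": ages,
            "sex": np.where(male, "male", "female"),
            "cohort": cohort,
            "entity": np.where(rng.random(n) < 0.24, "B-AL", "BL"),
            "bm_involved": rng.random(n) < 0.30,
            "cns_involved": rng.random(n) < 0.10,
            "stage": rng.choice(["I", "II", "III", "IV"], n, p=[0.05, 0.15, 0.55, 0.25]),
            "rituximab": (cohort == "pediatric") & (rng.random(n) < 0.21),
            "gpc5_gain": gpc5_gain,
            "followup_years": followup,
            "event": event,
        }
    )
    gene_status = pd.DataFrame(status, index=genes, columns=patient_ids)
    gene_counts = pd.DataFrame(counts, index=genes, columns=patient_ids)
    return clinical, gene_status, gene_counts


_CONSEQUENCE_CLASSES = np.array(
    ["missense", "nonsense", "frameshift", "inframe_indel", "synonymous", "intronic"]
)
_CONSEQUENCE_P = np.array([0.50, 0.18, 0.18, 0.04, 0.06, 0.04])
_BASES = np.array(list("ACGT"))


def _somatic_variants(config, rng, clinical, gene_counts, purity_cn):
    """Emit true somatic variant calls by inverting the CCF relation."""
    variants, truth_rows = [], []
    genes = list(gene_counts.index)
    for pid, purity in zip(clinical["patient_id"], clinical["_purity"]):
        pcn = purity_cn[pid]
        for gene in genes:
            k = int(gene_counts.loc[gene, pid])
            if k == 0:
                continue
            chrom, start, end = GENE_LOCI[gene]
            for _ in range(k):
                pos = int(rng.integers(start, end))
                ref, alt = rng.choice(_BASES, 2, replace=False)
                cn = next((c for sc, s, e, c in pcn.segments if sc == chrom and s <= pos < e), 2)
                ccf = 1.0 if rng.random() < config.clonal_fraction else rng.uniform(0.1, 0.9)
                vaf_exact = ccf * purity / ((1.0 - purity) * 2.0 + purity * cn)
                alt_count = int(rng.binomial(config.depth, vaf_exact))
                vaf = alt_count / config.depth
                cls = str(rng.choice(_CONSEQUENCE_CLASSES, p=_CONSEQUENCE_P))
                variants.append(
                    VariantCall(
                        sample_id=pid, chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
                        gene=gene, consequences=[("NM_0001", cls)],
                        vaf=vaf, alt_count=alt_count, depth=config.depth,
                        caller_pass=True, pop_af=None,
                        in_cosmic=bool(rng.random() < 0.4),
                    )
                )
                truth_rows.append(
                    {"sample_id": pid, "gene": gene, "chrom": chrom, "pos": pos,
                     "ccf_true": ccf, "vaf_exact": vaf_exact, "vaf_observed": vaf,
                     "purity": purity, "cn_tumor": cn}
                )
    return variants, pd.DataFrame(truth_rows)


def _site_pool(rng, size, chroms=("1", "2", "3", "5", "7", "11", "13", "17", "19", "X")):
    chrom = rng.choice(np.array(chroms, dtype=object), size)
    pos = rng.integers(1_000_000, 200_000_000, size)
    ref = rng.choice(_BASES, size)
    alt_shift = rng.integers(1, 4, size)
    base_idx = np.searchsorted(_BASES, ref)
    alt = _BASES[(base_idx + alt_shift) % 4]
    return chrom, pos, ref, alt


def _noise_and_germline(config, rng, sample_ids, paired):
    """Germline SNPs, recurrent artifacts, and per-sample random noise calls."""
    # shared pools; germline sites carry population allele frequencies and a
    # subject carries a site with probability proportional to its frequency,
    # so common sites recur across subjects (PON- and pop-AF-discoverable)
    g_chrom, g_pos, g_ref, g_alt = _site_pool(rng, config.n_snp_sites)
    g_af = rng.beta(0.8, 2.0, config.n_snp_sites).clip(0.002, 0.5)
    g_incl = (g_af * (config.n_germline_per_sample / g_af.sum())).clip(0.0, 1.0)
    a_chrom, a_pos, a_ref, a_alt = _site_pool(rng, config.n_artifact_sites)

    def germline_calls(sid):
        idx = np.flatnonzero(rng.random(config.n_snp_sites) < g_incl)
        k = idx.size
        hom = rng.random(k) < 0.1
        vaf = np.where(hom, 1.0, rng.normal(0.5, 0.04, k)).clip(0.3, 1.0)
        depth = config.depth
        out = []
        for i, v in zip(idx, vaf):
            alt_count = int(round(v * depth))
            out.append(
                VariantCall(
                    sample_id=sid, chrom=str(g_chrom[i]), pos=int(g_pos[i]),
                    ref=str(g_ref[i]), alt=str(g_alt[i]), gene="",
                    vaf=alt_count / depth, alt_count=alt_count, depth=depth,
                    caller_pass=True, pop_af=float(g_af[i]),
                    dbsnp_common=bool(g_af[i] >= 0.05),
                )
            )
        return out

    def artifact_calls(sid, prob):
        mask = rng.random(config.n_artifact_sites) < prob
        out = []
        for i in np.flatnonzero(mask):
            depth = config.depth
            vaf = float(rng.uniform(0.02, 0.09))
            out.append(
                VariantCall(
                    sample_id=sid, chrom=str(a_chrom[i]), pos=int(a_pos[i]),
                    ref=str(a_ref[i]), alt=str(a_alt[i]), gene="",
                    vaf=vaf, alt_count=int(round(vaf * depth)), depth=depth,
                    caller_pass=True, pop_af=None,
                )
            )
        return out

    def noise_calls(sid, k):
        chrom, pos, ref, alt = _site_pool(rng, k)
        out = []
        for i in range(k):
            fail_mode = rng.random()
            depth = config.depth
            if fail_mode < 0.6:  # caller-rejected
                cp, vaf = False, float(rng.uniform(0.01, 0.3))
            elif fail_mode < 0.8:  # low depth
                cp, vaf, depth = True, float(rng.uniform(0.05, 0.3)), int(rng.integers(3, 19))
            else:  # low allele support
                cp, vaf = True, float(rng.uniform(0.001, 0.012))
            alt_count = max(0, int(round(vaf * depth)))
            out.append(
                VariantCall(
                    sample_id=sid, chrom=str(chrom[i]), pos=int(pos[i]),
                    ref=str(ref[i]), alt=str(alt[i]), gene="",
                    vaf=vaf, alt_count=alt_count, depth=depth, caller_pass=cp,
                    pop_af=None,
                )
            )
        return out

    tumor_nonsomatic = []
    for sid, is_paired in zip(sample_ids, paired):
        calls = (
            germline_calls(sid)
            + artifact_calls(sid, config.artifact_tumor_prob)
            + noise_calls(sid, config.n_noise_per_sample)
        )
        for c in calls:
            c.paired_normal = bool(is_paired)
        tumor_nonsomatic.extend(calls)

    normals = []
    for j in range(config.n_matched_normals):
        nid = f"N{j:04d}"
        normals.extend(germline_calls(nid))
        normals.extend(artifact_calls(nid, config.artifact_normal_prob))
    return tumor_nonsomatic, normals


def _purity_cn(config, rng, clinical, purities):
    out = {}
    for pid, gain, purity in zip(clinical["patient_id"], clinical["gpc5_gain"], purities):
        segments = []
        for chrom in sorted({loc[0] for loc in GENE_LOCI.values()} | {"13"}):
            if chrom == "13":
                g_chrom, g_start, g_end = GPC5_REGION
                cn_gain = int(rng.choice([3, 4])) if gain else 2
                segments += [("13", 1, g_start, 2), ("13", g_start, g_end, cn_gain),
                             ("13", g_end, 300_000_000, 2)]
            else:
                segments.append((chrom, 1, 300_000_000, 2))
        ncn = sum((e - s) * c for _, s, e, c in segments)
        tot = sum(e - s for _, s, e, _ in segments)
        out[pid] = SamplePurityCN(sample_id=pid, purity_f=float(purity),
                                  ploidy=ncn / tot, segments=segments)
    return out


def simulate_cohort(config: CohortConfig, include_noise: bool = True) -> SimulatedCohort:
    """Generate the full synthetic input stack under one seed."""
    rng = np.random.default_rng(config.seed)
    clinical, gene_status, gene_counts = simulate_clinical(config, rng)
    purities = rng.uniform(*config.purity_range, len(clinical))
    clinical = clinical.assign(_purity=purities)
    purity_cn = _purity_cn(config, rng, clinical, purities)
    variants, truth = _somatic_variants(config, rng, clinical, gene_counts, purity_cn)
    normals = []
    if include_noise:
        n = len(clinical)
        paired = np.zeros(n, dtype=bool)
        n_paired = min(config.n_matched_normals, n)
        paired[:n_paired] = True
        nonsomatic, normals = _noise_and_germline(
            config, rng, list(clinical["patient_id"]), paired
        )
        variants = variants + nonsomatic
    clinical = clinical.drop(columns=["_purity"])
    return SimulatedCohort(
        clinical=clinical, variants=variants, normals=normals,
        purity_cn=purity_cn, gene_status=gene_status, truth=truth, config=config,
    )


def simulate_sanger_truth(variants, n_regions: int, fn_injected: int,
                          fp_injected: int, seed: int):
    """Two call lists differing by exactly the injected discordances.

    Selects ``n_regions`` covered genes, takes the somatic calls within
    them as shared truth, removes ``fn_injected`` calls from the pipeline
    list (orthogonal-only) and adds ``fp_injected`` novel pipeline-only
    calls.  Returns ``{"sanger_calls", "pipeline_calls", "covered_regions"}``.
    """
    from .validation import PipelineCall, SangerCall

    rng = np.random.default_rng(seed)
    covered_genes = [g for g in ("ID3", "CCND3", "TCF3", "TP53", "FOXO1",
                                 "FBXO11", "PCBP1", "P2RY8") if g in GENE_LOCI][:n_regions]
    regions = [(GENE_LOCI[g][0], GENE_LOCI[g][1] - 1, GENE_LOCI[g][2]) for g in covered_genes]
    covered = [v for v in variants if v.gene in covered_genes]
    # distinct sites only: orthogonal validation is per genomic event
    seen, sites = set(), []
    for v in covered:
        k = (v.chrom, v.pos, v.ref, v.alt)
        if k not in seen:
            seen.add(k)
            sites.append(v)
    if fn_injected + fp_injected > len(sites):
        raise ValueError("injected discordances exceed available covered variants")
    order = rng.permutation(len(sites))
    fn_idx = set(order[:fn_injected].tolist())
    sanger = [SangerCall(v.chrom, v.pos, v.ref, v.alt) for v in sites]
    pipeline = [PipelineCall(v.chrom, v.pos, v.ref, v.alt)
                for i, v in enumerate(sites) if i not in fn_idx]
    for j in range(fp_injected):
        g = covered_genes[j % len(covered_genes)]
        chrom, start, end = GENE_LOCI[g]
        pos = int(rng.integers(start, end))
        ref, alt = (str(b) for b in rng.choice(_BASES, 2, replace=False))
        pipeline.append(PipelineCall(chrom, pos, ref, alt))
    return {"sanger_calls": sanger, "pipeline_calls": pipeline,
            "covered_regions": regions}
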