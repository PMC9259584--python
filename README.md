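# blcohort

Cohort-level somatic-mutation analyses for Burkitt lymphoma (BL) and
Burkitt leukemia (B-AL) sequencing studies, built for comparing pediatric
and adult cohorts: somatic-variant filtering with a panel of normals,
cancer-cell-fraction clonality estimation, gene–sub-cohort association
testing, a cutoff-free mutation-density-over-age analysis, competing-risks
relapse-incidence estimation, and orthogonal-validation reconciliation.
A synthetic-cohort generator reproduces the statistical structure these
analyses assume, so the whole pipeline is exercisable and testable without
access-restricted patient data.

## The analyses

**Variant filtering** (`blcohort.filtering`). Raw targeted-panel calls are
mostly germline variants and artifacts. A panel of normals (PON) collects
variant keys seen in ≥ 2 independent normal subjects; an ordered filter
chain (caller flag → PON → population allele frequency → dbSNP-common
(≥ 5%) → read depth → alt support → VAF → protein-level consequence, with
an optional COSMIC rescue) reduces raw calls to called somatic mutations,
recording a per-variant verdict trail and per-step retention. Variant keys
are parsimony-trimmed and, given a reference, left-aligned, so equivalent
indel representations match. Per variant, the transcript with the
strongest protein-level consequence is used.

**Clonality** (`blcohort.clonality`). The cancer cell fraction of a
mutation is estimated from its variant allele frequency *f*<sub>VAF</sub>,
tumor purity *f*<sub>purity</sub> and local copy numbers:

> *f*<sub>CCF</sub> = *f*<sub>VAF</sub>/*f*<sub>purity</sub> ·
> ((1 − *f*<sub>purity</sub>)·*n*<sub>CN,normal</sub> +
> *f*<sub>purity</sub>·*n*<sub>CN,tumor</sub>)

with diploid normal cells; mutations with *f*<sub>CCF</sub> ≥ 0.9 are
called clonal. Estimates above 1 are flagged, never silently clipped.

**Association** (`blcohort.assoc`). A gene × patient mutation matrix feeds
one-tailed Fisher exact tests (on the observed enriched side) between
clinical sub-cohorts (pediatric/adult, sex, CNS, bone marrow, B-AL/BL,
age < 10), with Benjamini–Hochberg FDR at *q* = 0.1 over genes with ≥ 2%
cohort frequency, plus pairwise mutual-exclusivity summaries.

**Age profile** (`blcohort.age`). Rather than dichotomizing at 18 years,
mutation frequency is profiled continuously: boundary-reflected Gaussian
KDEs of the ages of mutated and of all cases are combined into a smoothed
frequency curve; a per-gene, per-tail permutation test ranks patients by
age and scores mutated cases with the classic unweighted running-sum
statistic (exhaustive enumeration where feasible, 10⁵ permutations
otherwise); a transition summary locates where each gene's profile shifts
and the cohort's median transition age.

**Survival** (`blcohort.survival`). From-scratch Kaplan–Meier with
Greenwood SEs, the K-sample log-rank test, the Kalbfleisch–Prentice
cumulative incidence function under competing risks (death in remission
and second malignancy compete with relapse) with delta-method SEs, and
Gray's test on subdistribution hazards (ρ = 0), with an exact permutation
mode for small samples.

**Validation** (`blcohort.validation`). Two call sets (e.g. Sanger vs
pipeline) are matched by normalized key within covered regions and
partitioned into matches, representation-review matches, confirmed-filtered
calls, hard false negatives and false positives, with operational
(union-denominator) and classical sensitivity/specificity.

**Synthetic cohorts** (`blcohort.simulate`). Per-gene mutation probability
follows a logistic transition over age, p(age) = p_young +
(p_old − p_young)·σ((age − a₀)/w), centered at 35 years; sex-biased genes
multiply mutation odds in males; event times come from cause-specific
exponential hazards with lesion hazard ratios on relapse; VAFs invert the
CCF relation from a drawn clonal/subclonal CCF and are binomially
resampled at 200× depth; germline, recurrent-artifact and random-noise
calls are injected at realistic rates so the filter hierarchy has real
work to do.

## Worked example

`examples/06_survival.py` simulates 1000 pediatric patients whose true
3-year relapse incidence is 25% for TP53-mutant and 6% for TP53-wild-type
cases, then re-estimates both under competing risks:

```
TP53 mut: 3-year relapse incidence 25.3% +/- 2.6% (n = 294)
TP53 wt: 3-year relapse incidence 4.3% +/- 0.8% (n = 706)
Gray's test:   chi2 = 137.1, p = 1.14e-31
log-rank (EFS): chi2 = 81.4, p = 1.8e-19
overall event-free survival at 3 y: 81.8% +/- 1.2%
```

The cumulative-incidence estimates recover the generative truth within
about two standard errors, and Gray's test — which correctly treats deaths
in remission as competing events instead of censoring them — strongly
separates the two groups. The other scripts in `examples/` walk through
simulation, filtering, clonality, association, the age profile and
validation reconciliation the same way; each prints the numbers it
computes with a line on what they mean.

A thin CLI wraps the same functions:

```
blcohort run --out out/ --seed 1          # full pipeline on a synthetic cohort
blcohort filter --normals n.tsv --tumors t.tsv --out called.tsv
blcohort survival --clinical c.tsv --variants called.tsv --by TP53 --test gray
```

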