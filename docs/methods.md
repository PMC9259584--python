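# Methods

This note documents the models and estimators implemented in `blcohort`,
the assumptions behind the synthetic-cohort generator, the numerical
choices made where the design was genuinely open, and what the tests do
and do not establish about real data.

## Synthetic cohort model

The generator produces a pediatric and an adult sub-cohort from a single
`numpy.random.default_rng(seed)` stream, so a fixed seed yields
bit-identical output.

**Ages.** Pediatric ages are drawn from Beta(2, 2) scaled to [0, 18] and
rounded to whole years (median 9); adult ages from a triangular
distribution on (18, 85] with mode 52. These match the cohort medians the
analyses assume; the exact shapes are a modeling choice.

**Mutation status.** Each gene carries a logistic age profile,
p(age) = p_young + (p_old − p_young)·σ((age − a₀)/w), with default center
a₀ = 35 years and width w = 5. The logistic form is a parametric stand-in
for a gradual biological transition between the pediatric and adult
mutation landscapes; nothing in the downstream analyses depends on it
being the true functional form. `p_young`/`p_old` are *female* plateau
probabilities; males multiply the odds by `sex_odds_male` (20 for DDX3X,
giving ~46% male vs ~4% female carriers in children). A mutated case
carries 1 + Poisson(mean − 1) distinct variants, so e.g. MYC at 70%
frequency with mean 2.4 variants per mutated case averages ~1.7 variants
per case overall.

Because an adult cohort includes young adults still near the pediatric
plateau, the *observed* adult frequency is a mixture along the logistic,
not the old-age plateau. Default gene models therefore derive `p_old`
from the target observed adult frequency by inverting
E[σ((A − a₀)/w)] ≈ 0.82 under the triangular adult ages
(`plateau_from_adult_frequency`). For ID3 (76% pediatric, 40% adult
observed) this puts the old plateau at ~42% of the pediatric level —
consistent with the gene's mutation *density* relative to children
plateauing near 40%, while its observed adult *frequency* is 40%: the two
statements describe different quantities and the calibrated model
satisfies both.

**Survival.** Event times are cause-specific exponentials
(relapse/progression, death in remission, second malignancy, other death),
with administrative censoring drawn uniformly on [2, censor_time] years
(default censor_time 8). Lesions named in `hazard_ratios` multiply the
relapse hazard multiplicatively. `calibrate_relapse_hazards` solves
CIF(t) = λ_r/λ·(1 − e^{−λt}) for the baseline relapse hazard and the
carrier hazard ratio hitting target 3-year relapse CIFs of 6% (wild-type)
and 25% (TP53-mutant) against a total competing hazard of 0.022/year.

**Variant calls.** Each somatic variant draws a true CCF (mass 0.8 at 1.0,
else Uniform(0.1, 0.9)), a tumor purity Uniform(0.4, 0.95), and the local
copy number from the sample's segment table (diploid everywhere except a
GPC5-region gain, cn 3–4, in 18% of pediatric samples). The exact VAF
inverts the CCF relation; the observed VAF is Binomial(depth = 200)
resampled. Non-somatic background per tumor sample: ~1600 germline calls
drawn from a shared SNP pool with Beta(0.8, 2) population frequencies
(carried with probability proportional to frequency, so common sites recur
across subjects and enter the PON), ~300 recurrent low-VAF artifact calls
from a shared artifact pool, and 600 random noise calls failing the
caller flag, depth, or allele-support thresholds. These rates put the
end-to-end called-somatic fraction at ~0.2% of raw calls, the regime a
targeted panel produces.

**What the generator does not emulate:** read-level data (no FASTQ/BAM),
mutational signatures, per-gene hotspot structure, segment-level SCNA
landscapes beyond the single GPC5 gain, correlated co-mutation patterns
(genes are independent given age and sex), and non-exponential hazards.
Passing tests therefore demonstrate correctness of the estimators under
this generative model, not robustness to every pathology of real cohorts.

## Filtering

The hierarchy is configuration-driven (`FilterConfig`): step order is
explicit, every variant records a verdict trail that truncates at the
first failing step, and the retention table reports n_in/n_out and the
percentage of the original input remaining after each step. Defaults:
caller PASS required; PON membership at ≥ 2 distinct normal subjects;
population AF ≤ 0.001 (no cutoff is canonical; 0.1% is a common germline
resource threshold); dbSNP-common defined as ≥ 5% population frequency;
COSMIC rescue on (whether confirmed-somatic status rescues a
population-frequency failure is genuinely open; both behaviors are config
options); depth ≥ 20, alt reads ≥ 3, VAF ≥ 0.05 (0.10 for samples without
a matched normal, mirroring paired/unpaired caller modes); synonymous,
intronic, intergenic, UTR and upstream consequences dropped, judged on the
strongest-consequence transcript (ties broken by smallest transcript id).

Variant keys trim the shared allele suffix, then prefix (position
advancing), leaving possibly-empty alleles; with a reference sequence,
pure indels are additionally left-shifted through repeat context (VCF
convention). Keys are the matching currency for the PON and validation.

## Clonality

`compute_ccf` implements the purity/copy-number correction exactly as
stated, ignoring mutation multiplicity; estimates above 1 are flagged
(`superclonal`) and reported unclipped, since persistent CCF ≫ 1 indicates
a multi-copy mutation or a purity/CN mismatch worth inspection. Clonal
means CCF ≥ 0.9 (boundary inclusive). Copy numbers come from half-open
`[start, end)` segments; variants outside all segments fall back to the
ploidy rounded to the nearest integer, with a warning flag — the fallback
is a repository decision. Samples without purity/CN data are skipped with
a logged count, not imputed.

At depth 200 the CCF estimator's error is pure binomial counting noise:
the mean absolute error equals sqrt(2/π)·mult·sqrt(v(1−v)/depth) with
mult = ((1−p)·2 + p·cn)/p, about 0.08 over the generator's purity range
(and ≥ 0.056 even at purity 1), halving when depth quadruples. Tests
verify the error against this analytic prediction rather than a fixed
absolute bound.

## Association

One-tailed Fisher exact p-values are hypergeometric tail probabilities
conditioned on the table margins (`scipy.stats.hypergeom`); the tested
side per gene follows the observed frequency difference and is recorded in
the output, matching how single-sided significance stars are reported per
comparison. FDR is Benjamini–Hochberg step-up (via statsmodels) within
each comparison family over genes with ≥ 2% frequency among the compared
patients; significance at q ≤ 0.1. Patients missing a grouping field drop
out of that comparison only.

## Age profile

`reflected_kde` augments the data with mirror images about both support
bounds, evaluates a Gaussian kernel sum on a uniform grid and renormalizes
to unit mass on the support; bandwidth is Silverman's rule on the
unreflected data. Support defaults to [0, max age]: age 0 is a natural
boundary, and reflection removes the edge decay a plain KDE shows there.

`gene_age_curve` shares one bandwidth (Silverman on all ages) between the
mutated-case and all-case densities. With a shared kernel the ratio
prevalence·dens_mut/dens_all is algebraically a boundary-corrected
Nadaraya–Watson regression of mutation status on age; per-density
bandwidths let kernel-width mismatch distort the ratio where cases are
sparse (in development this biased recovered transition ages ~7 years
early). Both densities, the smoothed frequency, and the curve normalized
to the pediatric (≤ 18 y) mean are emitted, since it is ambiguous whether
a density-over-age display normalizes per gene by the cohort age density.

The enrichment statistic is the classic unweighted running sum: patients
sorted by age (ascending for the young tail, descending for old; ties
broken by stable input order), +1/n_members at mutated cases, −1/n_others
elsewhere, score = maximum of the walk. p = (1 + #{ES* ≥ ES})/(n_perm + 1)
over label permutations (default 10⁵ per tail); complete enumeration
replaces sampling when C(n, members) ≤ 2·10⁵, making the p exact.

`transition_summary` reports, per declining gene, the age interval where
the relative-to-children curve crosses from above 80% to below 60% of the
pediatric mean, and the cohort median of interval midpoints. Rising genes
use the symmetric crossings on the curve normalized to the old-age
(≥ 55 y) plateau, because a relative-to-children normalization degenerates
when the pediatric mean is near zero. A transition additionally requires
the far plateau to sit below the 60% threshold; otherwise the gene is
flagged "no transition" and excluded from the median — without this guard,
sampling noise turns flat genes into degenerate zero-length intervals.

## Survival and competing risks

Kaplan–Meier uses Breslow-style tie handling (all events at a time
processed together; censoring at an event time ordered after the events)
and Greenwood variance. The log-rank test uses the hypergeometric
variance–covariance at each event time and a chi-square reference with
k − 1 degrees of freedom.

The cumulative incidence function is the Kalbfleisch–Prentice estimator
CIF(t) = Σ_{t_i ≤ t} S(t_i−)·d_i/n_i with S the all-cause KM just before
each event time, which makes the conservation identity
KM + Σ event-type CIFs = 1 exact at every event time. Its standard error
is the Marubini–Valsecchi delta-method variance; in tests it matches
R `cmprsk::cuminc` variances within ~5% and a bootstrap within 10%, and
95% intervals achieve 92–98% coverage over 200 replicate cohorts at the
relapse-recovery settings. The "±SE" headline is read at a 3-year horizon
by default (configurable), treated as the plateau estimate.

Gray's test uses the subdistribution score exactly as defined: each
group's events of interest are contrasted against the pooled
subdistribution hazard over modified risk sets
R_j(t) = Y_j(t)·(1 − F1_j(t−))/S_j(t−) that retain competing-event
subjects with weight. For the chi-square p-value the covariance is a
hypergeometric plug-in on the modified risk sets — a design choice: it
reduces *exactly* to the log-rank test when no competing events are
present, and across random competing-risks datasets it tracks the full
Gray covariance (statistics within ~1–4%, p within ~0.005 of
`cmprsk::cuminc`). For small samples, where any chi-square reference is
rough, `p_method="permutation"` permutes group labels — exhaustively when
the number of assignments is ≤ 2·10⁵, so the p is exact. Only ρ = 0
(unweighted) is implemented.

## Validation reconciliation

Calls are matched by normalized key within BED-style covered regions
(excluded calls are counted and logged). Categories partition the union of
calls: exact matches; matches after review, mechanized as
same-key-after-normalization with differing raw representations;
confirmed-filtered (both pipelines saw the site, the hierarchy removed
it); hard false negatives (orthogonal-only); false positives
(pipeline-only). Filtered calls without orthogonal support are not part of
the reconciliation universe. Sensitivity = 1 − FN/total and
specificity = 1 − FP/total use the union count as denominator (the
operational convention); the classical TP/(TP + FN) rate is also reported,
clearly labeled.

## Problem sizes and tolerances

The test suite runs the full default cohort (191 + 97 patients, ~7·10⁵
raw variant calls) once for the end-to-end filter check; parameter
recovery uses 2000-patient cohorts (200 replicates for CI coverage);
transition recovery uses 600-patient cohorts; enrichment calibration uses
2000 permutations per replicate, with the 10⁵ default exercised at cohort
scale once. The acceptance script reports CIF recovery at n = 4000 and
transition/plateau recovery as the median/mean over eight 600-patient
replicates — replicate averaging, rather than one larger cohort, controls
the spread of these smoothed-curve ratios. Conservation identities are
asserted at 10⁻¹⁰, oracle equivalences (Fisher enumeration, exhaustive
permutation) at ~10⁻⁹ relative, and cross-library checks at the printed
precision of the reference (lifelines: 10⁻⁹; R output: ~7 significant
digits).
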