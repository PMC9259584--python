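"""Compare per-gene mutation frequencies between clinical sub-cohorts.

One-tailed Fisher exact tests on the enriched side, Benjamini-Hochberg FDR
at q = 0.1 over genes with >= 2% cohort frequency — the pediatric-vs-adult
contrast recovers the age-dependent genes the generator injected.
"""

from blcohort.assoc import build_matrix, exclusivity_summary, results_frame, run_comparisons
from blcohort.filtering import FilterConfig, apply_filter_hierarchy, build_pon
from blcohort.simulate import CohortConfig, simulate_cohort

cohort = simulate_cohort(CohortConfig(n_pediatric=120, n_adult=60, seed=5),
                         include_noise=False)
called, _ = apply_filter_hierarchy(cohort.variants, FilterConfig())
matrix = build_matrix([v for v in called if v.gene], cohort.clinical)

results = run_comparisons(matrix, "pediatric_vs_adult")
df = results_frame(results).sort_values("p_one_sided")
cols = ["gene", "freq_a", "freq_b", "direction", "p_one_sided", "fdr_q", "stars"]
print(df[cols].head(8).to_string(index=False))
# freq_a is the pediatric frequency, freq_b the adult one; 'a_greater' rows
# are pediatric-enriched genes (ID3, SMARCA4, ...), 'b_greater' rows
# adult-enriched ones (BCL2, YY1AP1, ...).

excl = exclusivity_summary(matrix, "ARID1A", "SMARCA4")
print(f"\nARID1A/SMARCA4 co-occurrence: both {excl['both_pct']:.0f}%, "
      f"exactly one {excl['exactly_one_pct']:.0f}% of cases")
# Under independence both ~ product of the single-gene frequencies; observed
# cohorts with much lower co-occurrence suggest mutual exclusivity.
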