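"""Cutoff-free mutation-density-over-age analysis.

Instead of dichotomizing at 18 years, mutation frequency is profiled
continuously: boundary-reflected KDE curves over age, a rank-by-age
permutation enrichment test per tail, and a transition summary locating
where each gene's profile shifts.
"""

import numpy as np

from blcohort.age import age_rank_enrichment, gene_age_curve, transition_summary
from blcohort.simulate import CohortConfig, GeneModel, simulate_clinical

genes = [GeneModel("ID3", 0.75, 0.30), GeneModel("BCL2", 0.01, 0.40),
         GeneModel("SMARCA4", 0.30, 0.10), GeneModel("MYC", 0.70, 0.70)]
cfg = CohortConfig(n_pediatric=300, n_adult=300, seed=3, gene_models=genes)
clin, status, _ = simulate_clinical(cfg)
ages = clin["age_years"].to_numpy()

curves = []
for g in genes:
    mutated = status.loc[g.gene].to_numpy()
    curves.append(gene_age_curve(ages, mutated, gene=g.gene))
    for tail in ("young", "old"):
        r = age_rank_enrichment(ages, mutated, tail=tail, n_perm=20_000, seed=1,
                                gene=g.gene)
        print(f"{g.gene:8s} {tail:5s} tail: ES {r.es:+.3f}, p = {r.p_perm:.4g}")
# ID3/SMARCA4 enrich in the young tail, BCL2 in the old tail; MYC (flat)
# is not significant in either direction.

ts = transition_summary(curves)
print("\ntransition intervals (years):")
for gene, iv in ts.intervals.items():
    print(f"  {gene:8s}", "no transition" if iv is None else f"{iv[0]:.0f}-{iv[1]:.0f}")
print(f"cohort median transition age: {ts.median_transition_age:.1f} y")

id3 = curves[0]
plateau = np.nanmean(id3.relative_to_children[id3.age_grid >= 55])
print(f"ID3 density relative to children beyond 55 y: {plateau:.0%}")
# The generator's logistic transitions are centered at 35; the recovered
# median falls in that range, and the ID3-like plateau sits near 40%.
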