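"""Competing-risks relapse incidence by TP53 status.

Relapse probability is estimated with the Kalbfleisch-Prentice cumulative
incidence function, treating death in remission and second malignancy as
competing events, and compared between carriers and non-carriers with
Gray's test (log-rank on overall survival shown for contrast).
"""

import numpy as np

from blcohort.simulate import CohortConfig, GeneModel, simulate_clinical
from blcohort.survival import (
    CENSORED,
    cumulative_incidence,
    gray_test,
    kaplan_meier,
    logrank_test,
)

cfg = CohortConfig(n_pediatric=1000, n_adult=0, seed=2,
                   gene_models=[GeneModel("TP53", 0.30, 0.30)])
clin, status, _ = simulate_clinical(cfg)
carrier = status.loc["TP53"].to_numpy()
time = clin["followup_years"].to_numpy()
event = np.where(clin["event"] == "none", CENSORED, clin["event"]).astype(object)
group = np.where(carrier, "TP53 mut", "TP53 wt")

for label in ("TP53 mut", "TP53 wt"):
    sel = group == label
    cif = cumulative_incidence(time[sel], event[sel], "relapse_progression",
                               group=label)
    print(f"{label}: 3-year relapse incidence "
          f"{cif.estimate_at(3):.1%} +/- {cif.se_at(3):.1%} (n = {sel.sum()})")
# The generator's truth is 25% vs 6% at 3 years; estimates land within ~2 SE.

gr = gray_test(time, event, group, "relapse_progression")
lr = logrank_test(time, event != CENSORED, group)
print(f"Gray's test:   chi2 = {gr.statistic:.1f}, p = {gr.p:.3g}")
print(f"log-rank (EFS): chi2 = {lr.statistic:.1f}, p = {lr.p:.3g}")

km = kaplan_meier(time, event != CENSORED)
print(f"overall event-free survival at 3 y: {km.estimate_at(3):.1%} "
      f"+/- {km.se_at(3):.1%}")
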