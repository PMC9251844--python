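"""Apparent monthly survival among primary periods (CJS, unequal intervals).

Presence/absence of marked animals across a summer's primary periods feeds a
Cormack-Jolly-Seber likelihood.  Intervals of 20 or 30 days are standardised
through phi_interval = phi_monthly^(dt/30), so early- and late-study years
are directly comparable.  Candidate survival structures are compared by AICc
with the simplest-adequate-model rule.
"""

import numpy as np

from cyclecmr import SurvivalDesign, fit_model_set, monthly_survival_table
from cyclecmr.datamodel import AnnualHistory

rng = np.random.default_rng(5)
phi = {"adult_female": 0.46, "adult_male": 0.29,
       "juvenile_female": 0.50, "juvenile_male": 0.22}
p = {"female": 0.88, "male": 1.0}

hists = []
for i in range(600):
    cls = list(phi)[i % 4]
    sex = cls.split("_")[1]
    pres = np.zeros(3, dtype=int)
    pres[0] = 1
    alive = True
    for t in (1, 2):
        alive = alive and rng.random() < phi[cls]
        if alive and rng.random() < p[sex]:
            pres[t] = 1
    hists.append(AnnualHistory(f"i{i}", 2010, "wet", pres, cls, "wet"))

designs = [SurvivalDesign(()), SurvivalDesign(("sexage",)),
           SurvivalDesign(("sexage", "primary"))]
models, sel = fit_model_set(hists, designs)
print("candidate models (AICc):")
for m in sorted(models, key=lambda m: m.aicc):
    mark = " <- selected" if m is models[sel] else ""
    print(f"  {m.name:<28} k={m.n_params:<3} AICc={m.aicc:8.2f}{mark}")

tab = monthly_survival_table(models[sel])
print("\nmonthly apparent survival (truth in parentheses):")
for cls, group in tab.groupby("sexage"):
    r = group.iloc[0]
    print(f"  {cls:<16} {r.phi_monthly:.3f} [{r.lo95:.3f}, {r.hi95:.3f}]"
          f"  ({phi[cls]:.2f})")
print("\nApparent survival confounds death with emigration off the grid;")
print("adult females survive the summer markedly better than adult males.")
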