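"""Simulate a screening cohort and run the association battery.

Generates 1,769 subjects under the multiplicative risk model (22 SNPs,
target prevalence 0.29), scores them, and prints detection rates by GRS
category with the trend test plus the adjusted GRS odds ratio.
"""

import numpy as np

from polygrs import simulate
from polygrs.association import compare_grs_means, trend_across_categories
from polygrs.grs import compute_grs
from polygrs.pipeline import build_table1

bundle = simulate.generate_study(simulate.SimulationConfig(n_subjects=1769, seed=7))
scores = compute_grs(bundle.genotypes, bundle.panel)

category = {s.subject_id: s.category for s in scores}
positives, totals, cats = [], [], []
for c in ("low", "average", "elevated"):
    members = [p for p in bundle.phenotypes if category[p.subject_id] == c]
    cats.append(c)
    positives.append(sum(p.outcome for p in members))
    totals.append(len(members))

trend = trend_across_categories(positives, totals, categories=cats)
print("Detection rate by GRS category:")
for c, p, t in zip(cats, positives, totals):
    print(f"  {c:<9} {p:>4}/{t:<4} = {100 * p / t:.1f}%")
print(f"  p-trend = {trend.p_trend:.2g}")

means = compare_grs_means(
    {
        "positive": [s.grs for s in scores
                     if any(p.subject_id == s.subject_id and p.outcome
                            for p in bundle.phenotypes)],
        "negative": [s.grs for s in scores
                     if any(p.subject_id == s.subject_id and not p.outcome
                            for p in bundle.phenotypes)],
    }
)
print("\nMean GRS by outcome:")
for g in means.groups:
    print(f"  {g.label:<9} {g.mean:.3f} ({g.ci_low:.3f}-{g.ci_high:.3f}), n={g.n}")

table1 = build_table1(scores, bundle.phenotypes)
row = table1.loc["grs"]
print(
    f"\nAdjusted GRS odds ratio (per unit GRS, controlling for age, sex, "
    f"BMI, family history):\n  OR = {row.multi_or:.2f} "
    f"({row.multi_ci_low:.2f}-{row.multi_ci_high:.2f}), p = {row.multi_p:.2g}"
)
print(
    "\nRising rates across categories and an adjusted OR above 1 show the\n"
    "simulated genetic effect is recovered end to end."
)
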