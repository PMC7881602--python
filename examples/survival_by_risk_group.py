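"""Kaplan-Meier age-at-first-adenoma analysis by GRS risk group.

Simulates a 2,000-subject cohort with a genetic effect, treats age at the
first screening colonoscopy as the observation time from birth (event =
adenoma found, otherwise censored), and compares diagnosis-free curves
across GRS categories with the log-rank test.
"""

from polygrs import simulate
from polygrs.grs import compute_grs
from polygrs.survival import (
    build_survival_records,
    km_estimate,
    logrank_test,
    mean_age_by_group,
)

bundle = simulate.generate_study(
    simulate.SimulationConfig(n_subjects=2000, genotype_effect_scale=2.0, seed=31)
)
scores = compute_grs(bundle.genotypes, bundle.panel)
records = build_survival_records(scores, bundle.phenotypes)

curves = km_estimate(records)
print("Adenoma-free probability at age 60 / 70 by GRS category:")
for group, df in curves.items():
    s60 = df.loc[df["age"] <= 60, "survival"].iloc[-1]
    s70 = df.loc[df["age"] <= 70, "survival"].iloc[-1]
    print(f"  {group:<9} S(60) = {s60:.3f}   S(70) = {s70:.3f}")

res = logrank_test(records)
print(f"\nLog-rank: chi2 = {res.statistic:.2f} (df = {res.df}), p = {res.p_value:.2g}")

ages = mean_age_by_group(records)
print("\nMean age at colonoscopy by group (checks the curves are not an")
print("artifact of screening age):")
for g, m in ages.means.items():
    print(f"  {g:<9} {m:.1f} y")
print(f"  one-way F-test p = {ages.p_value:.2g}")
print(
    "\nLower curves in higher GRS groups mean adenomas are diagnosed at\n"
    "younger ages when genetic risk is higher."
)
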