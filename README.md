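# polygrs

Population-standardized polygenic genetic risk scores (GRS) for colorectal
adenoma screening cohorts — scoring, risk stratification, and the full
downstream association battery, with a synthetic-cohort generator so every
stage can be exercised with known ground truth.

The package is aimed at statistical-genetics and clinical-epidemiology
groups studying whether germline risk panels predict findings at screening
colonoscopy: who develops adenomatous polyps, at what age, and whether the
genetic signal is independent of the usual clinical predictors (age, sex,
BMI, family history).

## The score

For a panel of `n` independent biallelic risk SNPs, a subject carrying
`g_i ∈ {0, 1, 2}` copies of the risk allele at SNP `i` gets

```
GRS = ∏ᵢ ORᵢ^gᵢ / Wᵢ
Wᵢ  = fᵢ² ORᵢ² + 2 fᵢ (1 − fᵢ) ORᵢ + (1 − fᵢ)²
```

where `ORᵢ` is the per-allele odds ratio and `fᵢ` the risk-allele frequency
in an external reference population (e.g. gnomAD non-Finnish Europeans).
`Wᵢ` is the mean multiplicative risk expected under Hardy–Weinberg
proportions at frequency `fᵢ` — that is, `E[OR^g]` for `g ~ Binomial(2, f)`
— so dividing by it standardizes the score: the population-mean GRS is 1,
and each subject's value reads directly as relative risk versus the general
population. Subjects are stratified as **low** (GRS < 0.5), **average**
(0.5–1.5) or **elevated** (> 1.5) risk.

Downstream, the package provides 2×2 odds ratios with Woolf confidence
intervals, univariable/multivariable logistic regression, the
Cochran–Armitage test for trend in detection rate across risk categories,
Welch comparison of group GRS means, per-subtype associations (polyp size,
number, location, advanced adenoma), and Kaplan–Meier
adenoma-diagnosis-free curves from birth with the log-rank test.

## Worked example

`examples/simulate_and_associate.py` simulates a 1,769-subject screening
cohort (22 SNPs, target adenoma prevalence 0.29), scores it, and runs the
association battery:

```
Detection rate by GRS category:
  low         33/210  = 15.7%
  average    368/1318 = 27.9%
  elevated    99/241  = 41.1%
  p-trend = 2.1e-09

Mean GRS by outcome:
  positive  1.138 (1.088-1.187), n=500
  negative  0.947 (0.920-0.974), n=1269

Adjusted GRS odds ratio (per unit GRS, controlling for age, sex, BMI, family history):
  OR = 2.02 (1.65-2.48), p = 1e-11
```

The detection rate rises monotonically with the risk category, subjects
with adenomas carry higher scores on average, and the adjusted odds ratio
shows the genetic effect survives adjustment for the clinical covariates —
exactly the behaviour injected by the generator. The other examples cover
VCF scoring (`score_cohort.py`), the Kaplan–Meier analysis
(`survival_by_risk_group.py`) and the one-shot pipeline
(`full_pipeline.py`).

Command-line equivalents:

```sh
polygrs simulate --n 1769 --seed 7 --out study/
polygrs score --panel study/panel.tsv --vcf study/genotypes.vcf --out scores.tsv
polygrs associate --scores scores.tsv --phenotypes study/phenotypes.csv --out report/
polygrs km --scores scores.tsv --phenotypes study/phenotypes.csv --out report/
polygrs run --config config.yaml      # simulate/load → score → report, one step
```

## Caveats

Survival curves treat all subjects as observed from birth with a single
observation time (the first screening colonoscopy); no left-truncation is
applied, so the curves describe the screened cohort, not population
incidence. The bundled panel generator is illustrative — real analyses
should supply a curated panel TSV with literature odds ratios and reference
frequencies.
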