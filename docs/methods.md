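# Methods

## Score model

The genetic risk score is multiplicative over a panel of biallelic SNPs
assumed independent (linkage equilibrium). Per SNP, a subject's factor is
`OR^g / W`, with `g` the risk-allele dosage, `OR` the per-allele odds ratio
taken from external association studies, and

    W = f² OR² + 2 f (1 − f) OR + (1 − f)²

the expectation of `OR^g` when `g ~ Binomial(2, f)` under Hardy–Weinberg
proportions at reference risk-allele frequency `f`. Standardizing by `W`
makes the population-mean score 1, so the GRS is interpretable as relative
risk versus the reference population. Frequencies always come from the
panel file (an external reference such as gnomAD NFE), never from the
cohort being scored — re-estimating them in the cohort would re-center the
score on the cohort itself and destroy the relative-risk reading.

Assumptions inherited from this construction: per-allele (log-additive)
effects within SNP, no SNP×SNP or SNP×covariate interaction, and
independence between panel SNPs. Panels are expected to be curated to low
pairwise LD (r² < 0.2 is the conventional threshold); the package documents
but does not verify this.

### Numerical choices

- Scores are accumulated as `Σ (gᵢ ln ORᵢ − ln Wᵢ)` and exponentiated once.
  At panel sizes in the tens this is bit-compatible with the direct
  product; for very large panels it avoids under/overflow.
- A missing dosage contributes factor 1 (population-average risk at that
  SNP) rather than being imputed; `n_snps_used` records how many SNPs
  actually informed each score, subjects missing more than 20% of the panel
  are flagged in the log, and subjects with no usable dosages are excluded
  rather than silently scored at 1.
- Risk bands: the middle interval is closed, `[0.5, 1.5]`; the outer bands
  are strict (`< 0.5`, `> 1.5`). Scores exactly at a cutpoint therefore
  fall in the average band.

## Genotype harmonization

VCF sites are matched to the panel by chromosome + position and the
unordered allele pair. If `{REF, ALT}` equals the panel pair the site is
used directly, with the dosage flipped when the risk allele is REF. If the
pair matches only after reverse-complementing both alleles, the site is
treated as reported on the opposite strand and flipped with a logged
warning — A/T and C/G pairs are their own reverse complement, so ambiguous
sites can never take this branch and are either used as-is (direct match)
or excluded. Any other configuration excludes the site with a warning;
exclusion produces missing dosages, never a silently wrong orientation.
Matching by VCF ID is available as an opt-in fallback because rsID
assignments drift across dbSNP builds.

## Association battery

- **2×2 odds ratios**: cross-product estimate with the Woolf (log) 95% CI
  and a Wald p-value; zero cells raise an error unless the
  Haldane–Anscombe +0.5 correction is explicitly enabled, and corrected
  results are flagged.
- **Logistic regression**: maximum likelihood via statsmodels, intercept
  always included. Runaway coefficients (|β| > 15) or non-convergence raise
  a diagnostic error naming the term instead of returning Wald intervals
  that would be meaningless under separation. The multivariable model is
  `outcome ~ age + male + family_history + bmi + grs` with GRS continuous;
  sex is coded male = 1.
- **Trend across risk categories**: Cochran–Armitage with equally spaced
  scores 0, 1, 2. The statistic is `Z = Σ sᵢ(rᵢ − nᵢ p̄) / √Var` with the
  margin-conditional variance; `Z²` is the 1-df trend chi-square. Because
  the statistic is lattice-valued on small tables, the asymptotic two-sided
  p sits between the exact permutation mid-p and strict p; the test suite
  checks it against that band rather than a single Monte-Carlo number.
- **Group means**: normal-theory 95% CIs and a Welch two-sample t-test
  (no equal-variance assumption).
- **Subtype table**: each polyp subtype (size < 0.5 / ≥ 0.5 cm, advanced
  adenoma, single / multiple, location CA / TD / RS) is compared with the
  shared no-polyp reference by a logistic fit on continuous GRS. Subtypes
  with no members are omitted; subtypes with fewer than 10 carry a
  wide-interval flag.

## Survival analysis

Time zero is birth; each subject contributes one observation at the age of
their first screening colonoscopy, an event if an adenoma was found and a
censoring otherwise. Product-limit curves (lifelines) use the standard
events-before-censorings tie convention; the group comparison is the
unweighted k-sample log-rank test with df = k − 1. No left-truncation is
applied — subjects are treated as under observation from birth — so the
curves are descriptive of the screened cohort rather than estimates of
population incidence; this is the main statistical caveat of the analysis.
Mean age at colonoscopy per group with a one-way F-test is provided as a
check that curve separation is not an artifact of differential screening
age.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
with every effect known:

- **Genotypes**: dosages drawn `Binomial(2, fᵢ)` independently per SNP —
  exact HWE and linkage equilibrium (the idealization of the r² < 0.2
  curation rule). Missingness is injected completely at random at a
  configurable rate.
- **Panel**: 22 SNPs by default, frequencies uniform on [0.1, 0.5] and
  odds ratios uniform on [1.05, 1.3] — the effect-size range typical of
  GWAS-confirmed colorectal-cancer loci. The generated panel is
  illustrative (identifiers `snp01`…), standing in for a curated panel
  whose exact composition is not redistributable.
- **Outcome model**: `P(positive) = expit(β₀ + s·Σ gᵢ ln ORᵢ + covariate
  terms)` where `s` is the genotype effect scale (1 by default, 0 gives a
  null cohort). Covariate effects default to log-odds per unit of
  OR 1.01/year of age, 1.8 for male sex, 1.14 for family history and
  1.04 per BMI unit. `β₀` is calibrated by bisection on the cohort's mean
  outcome probability so realized prevalence matches the target (0.29 by
  default); the covariate mixture has no closed-form prevalence, which is
  why calibration is numerical. Missing dosages enter the linear predictor
  at their population expectation `2 fᵢ ln ORᵢ` so missingness does not
  shift prevalence.
- **Covariates and marginals**: age truncated-normal with mean 60 y,
  SD 8 y, support > 45 y (the screening-eligibility floor); 37% male; 7%
  positive family history; BMI normal mean 28.5, SD 5 kg/m². These echo a
  typical US screening cohort so simulated summary tables are visually
  comparable to published ones; they are defaults, not fitting targets.
- **Subtypes among positives**: 61% of polyps ≥ 0.5 cm, 41.5% multiple,
  one location drawn from CA/TD/RS at 0.454/0.302/0.244, advanced adenoma
  at rate 0.4 among large polyps — proportions chosen to mirror the mix
  reported for screening-detected adenomas.

What the generator does **not** emulate: linkage disequilibrium, population
structure or admixture, genotyping error, informative missingness, age- or
subtype-dependent genetic effects, and multiple colonoscopies per subject.
Passing tests therefore demonstrate correctness of the scoring and
statistical machinery under the model's own assumptions, not robustness of
the scientific conclusions to real-data violations of them.

## Reproducibility and problem sizes

All randomness flows through a single integer seed per run;
`generate_study` derives component seeds with `numpy.random.SeedSequence`,
and identical config + seed reproduces every TSV/JSON artifact byte for
byte. The verification script uses a 50,000-subject null cohort — large
enough that the Monte-Carlo standard error of the mean GRS (≈0.001) is far
inside the ±0.02 acceptance band — and the replicate-based tests use 50
cohorts of 5,000 subjects, sized so that a true unit coefficient is
recovered within two standard errors in ~95% of draws while the whole
suite stays fast on a single core.
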