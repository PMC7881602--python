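"""Synthetic screening-cohort generator with known ground truth.

Emulates the statistical structure the analysis assumes: independent
biallelic SNPs in Hardy-Weinberg equilibrium (dosages Binomial(2, f_i),
linkage equilibrium between SNPs), a multiplicative per-allele odds-ratio
disease model, clinical covariates (age, sex, BMI, family history) with
specified log-odds effects, and single-timepoint observation — each subject
is seen once, at their first screening colonoscopy, and event-free subjects
are censored there.

The outcome model is

    P(positive) = expit(b0 + scale * sum_i g_i * ln OR_i
                        + b_age * (age - 60) + b_male * male
                        + b_fh * fh + b_bmi * (bmi - 28.5))

with the intercept b0 calibrated by bisection on the cohort's mean outcome
probability so the realized prevalence matches the target. Defaults echo
the marginals of a typical US screening cohort: prevalence 0.29, 37% male,
7% positive family history, mean age ~60 y (truncated at >45), mean BMI
~28.5 kg/m^2, and 22 SNPs with frequencies in [0.1, 0.5] and per-allele
odds ratios in [1.05, 1.3] (GWAS-scale colorectal-cancer effects).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import expit

from . import io as pio
from .errors import ConfigError
from .genotypes import MISSING, GenotypeMatrix
from .grs import normalization_constant
from .panel import SNPPanel, SNPPanelEntry
from .phenotypes import PhenotypeRecord

_BASES = ("A", "C", "G", "T")


@dataclass
class PanelSpec:
    """Random-panel parameters: sizes and uniform ranges for f and OR."""

    n_snps: int = 22
    or_range: tuple[float, float] = (1.05, 1.3)
    freq_range: tuple[float, float] = (0.1, 0.5)

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        lo, hi = self.or_range
        if not (0 < lo <= hi):
            raise ConfigError(f"invalid OR range {self.or_range}")
        flo, fhi = self.freq_range
        if not (0 < flo <= fhi < 1):
            raise ConfigError(f"invalid frequency range {self.freq_range}")


@dataclass
class CovariateEffects:
    """Log-odds per unit of each covariate in the outcome model.

    Defaults are the adjusted effects reported for screening cohorts of
    this kind: OR 1.01 per year of age, 1.8 for male sex, 1.14 for positive
    family history, 1.04 per BMI unit.
    """

    age_per_year: float = math.log(1.01)
    male: float = math.log(1.8)
    family_history: float = math.log(1.14)
    bmi_per_unit: float = math.log(1.04)


@dataclass
class SimulationConfig:
    n_subjects: int = 1769
    panel_spec: PanelSpec = field(default_factory=PanelSpec)
    panel: Optional[SNPPanel] = None  # explicit panel overrides panel_spec
    baseline_prevalence: float = 0.29
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    genotype_effect_scale: float = 1.0
    age_mean: float = 60.0
    age_sd: float = 8.0
    male_fraction: float = 0.37
    family_history_rate: float = 0.07
    bmi_mean: float = 28.5
    bmi_sd: float = 5.0
    missing_rate: float = 0.0
    # subtype frequencies among positives, echoing a real cohort's mix
    size_ge_probability: float = 0.61  # >= 0.5 cm among sized polyps
    multiple_probability: float = 0.415
    advanced_given_large: float = 0.4
    location_probs: tuple[float, float, float] = (0.454, 0.302, 0.244)  # CA/TD/RS
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        for name in (
            "baseline_prevalence", "male_fraction", "family_history_rate",
            "missing_rate", "size_ge_probability", "multiple_probability",
            "advanced_given_large",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.location_probs) - 1) > 1e-9:
            raise ConfigError("location_probs must sum to 1")
        if self.panel is None:
            self.panel_spec.validate()


def generate_panel(
    spec: PanelSpec = PanelSpec(), seed: int = 0
) -> SNPPanel:
    """Draw a synthetic SNP panel: frequencies and odds ratios uniform in
    the configured ranges, placed at arbitrary genomic coordinates.

    The panel stands in for a curated list of risk SNPs; its identifiers
    (``snp01``...) mark it as illustrative, not a published panel.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(spec.n_snps):
        f = float(rng.uniform(*spec.freq_range))
        or_ = float(rng.uniform(*spec.or_range))
        risk, other = rng.choice(_BASES, size=2, replace=False)
        entries.append(
            SNPPanelEntry(
                snp_id=f"snp{i + 1:02d}",
                chrom=str(i % 22 + 1),
                pos=int(rng.integers(1, 2_000_000) * 100 + 1),
                risk_allele=str(risk),
                other_allele=str(other),
                odds_ratio=round(or_, 4),
                risk_allele_freq=round(f, 4),
            )
        )
    return SNPPanel(entries)


def generate_genotypes(
    panel: SNPPanel,
    n_subjects: int,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw dosages g_i ~ Binomial(2, f_i) independently per SNP (HWE and
    linkage equilibrium), then knock out entries to MISSING at
    ``missing_rate``."""
    if not 0 <= missing_rate <= 1:
        raise ConfigError(f"missing_rate must be in [0, 1], got {missing_rate}")
    rng = np.random.default_rng(seed)
    freqs = np.array([e.risk_allele_freq for e in panel])
    dos = rng.binomial(2, freqs, size=(n_subjects, len(panel))).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(dos.shape) < missing_rate
        dos[mask] = MISSING
    subjects = [f"S{i + 1:05d}" for i in range(n_subjects)]
    return GenotypeMatrix(subjects, panel.snp_ids, dos)


def _calibrate_intercept(
    linear_no_intercept: np.ndarray, target: float, max_steps: int = 100
) -> float:
    """Bisect b0 so mean expit(b0 + eta) hits the target prevalence."""
    lo, hi = -30.0, 30.0
    f = lambda b0: float(np.mean(expit(b0 + linear_no_intercept))) - target

    if f(lo) > 0 or f(hi) < 0:
        raise ConfigError("prevalence target unreachable for this cohort")
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        if f(mid) <= 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    else:
        if abs(f(0.5 * (lo + hi))) > 1e-6:
            raise ConfigError("intercept calibration did not converge")
    return 0.5 * (lo + hi)


def generate_outcomes(
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    config: SimulationConfig,
    seed: int = 0,
) -> list[PhenotypeRecord]:
    """Draw covariates and outcomes under the multiplicative risk model.

    Missing dosages contribute their population expectation 2*f_i*ln OR_i
    to the linear predictor, so missingness does not shift prevalence.
    Subtype labels are assigned among positives: a size class (below /
    at-or-above 0.5 cm), a count class (one / multiple), one colon segment,
    and an advanced-adenoma flag restricted to large polyps.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = genotypes.n_subjects
    sub = panel.subset(genotypes.snp_ids)
    log_or = np.array([math.log(e.odds_ratio) for e in sub])
    freqs = np.array([e.risk_allele_freq for e in sub])
    d = genotypes.dosages.astype(float)
    d = np.where(genotypes.dosages == MISSING, 2 * freqs, d)
    genetic = config.genotype_effect_scale * (d @ log_or)

    # truncated-normal ages: resample until > 45 (cheap at these sizes)
    ages = rng.normal(config.age_mean, config.age_sd, size=n)
    while (bad := ages <= 45).any():
        ages[bad] = rng.normal(config.age_mean, config.age_sd, size=bad.sum())
    male = rng.random(n) < config.male_fraction
    fh = rng.random(n) < config.family_history_rate
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, size=n), 15, None)

    ce = config.covariate_effects
    eta = (
        genetic
        + ce.age_per_year * (ages - config.age_mean)
        + ce.male * male
        + ce.family_history * fh
        + ce.bmi_per_unit * (bmi - config.bmi_mean)
    )
    b0 = _calibrate_intercept(eta, config.baseline_prevalence)
    outcome = rng.random(n) < expit(b0 + eta)

    records = []
    for i, sid in enumerate(genotypes.subject_ids):
        pos = bool(outcome[i])
        size_cls = count_cls = "none"
        loc: frozenset = frozenset()
        adv: Optional[bool] = None
        if pos:
            large = rng.random() < config.size_ge_probability
            size_cls = "ge_0.5cm" if large else "lt_0.5cm"
            count_cls = (
                "multiple" if rng.random() < config.multiple_probability else "one"
            )
            loc = frozenset(
                [("CA", "TD", "RS")[rng.choice(3, p=config.location_probs)]]
            )
            adv = bool(large and rng.random() < config.advanced_given_large)
        records.append(
            PhenotypeRecord(
                subject_id=sid,
                age_at_colonoscopy=float(ages[i]),
                sex="male" if male[i] else "female",
                bmi=float(bmi[i]),
                family_history=bool(fh[i]),
                outcome=pos,
                polyp_size_class=size_cls,
                polyp_count_class=count_cls,
                polyp_location=loc,
                advanced_adenoma=adv,
            )
        )
    return records


@dataclass
class StudyBundle:
    panel: SNPPanel
    genotypes: GenotypeMatrix
    phenotypes: list[PhenotypeRecord]
    config: SimulationConfig


def generate_study(
    config: SimulationConfig, out_dir: Optional[Path] = None
) -> StudyBundle:
    """Compose panel, genotypes and phenotypes into one reproducible study.

    Component seeds are derived deterministically from ``config.seed``.
    When ``out_dir`` is given, writes panel TSV, genotype VCF + TSV,
    phenotype CSV, and a manifest JSON recording the full configuration.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss]
    panel = config.panel or generate_panel(config.panel_spec, seed=seeds[0])
    genotypes = generate_genotypes(
        panel, config.n_subjects, config.missing_rate, seed=seeds[1]
    )
    phenotypes = generate_outcomes(genotypes, panel, config, seed=seeds[2])
    bundle = StudyBundle(panel, genotypes, phenotypes, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pio.write_panel(panel, out_dir / "panel.tsv")
        pio.write_genotypes_tsv(genotypes, out_dir / "genotypes.tsv")
        pio.write_genotypes_vcf(genotypes, panel, out_dir / "genotypes.vcf")
        pio.write_phenotypes(phenotypes, out_dir / "phenotypes.csv")
        manifest = dataclasses.asdict(config)
        manifest["panel"] = None if config.panel is None else [
            dataclasses.asdict(e) for e in config.panel
        ]
        (out_dir / "manifest.json").write_text(
            json.dumps({"simulation": manifest}, indent=2, default=str) + "\n"
        )
    return bundle
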