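"""Population-standardized genetic risk score (GRS).

The score for a subject is the product over panel SNPs of the per-SNP risk
factor ``OR_i**g_i / W_i`` where ``g_i`` is the risk-allele dosage and

    W_i = f_i**2 * OR_i**2 + 2 * f_i * (1 - f_i) * OR_i + (1 - f_i)**2

is the mean multiplicative risk expected in a population in Hardy-Weinberg
equilibrium at risk-allele frequency ``f_i`` — i.e. E[OR**g] for
g ~ Binomial(2, f). Dividing by W_i makes the population-mean score 1, so a
subject's GRS reads as a relative risk versus the general population.

Scores are accumulated in log space and exponentiated once at the end; at
panel sizes in the tens this is bit-compatible with the direct product while
staying safe for much larger panels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import FlaggedSubjectError, InvalidDosageError, InvalidParameterError
from .genotypes import MISSING, GenotypeMatrix
from .panel import SNPPanel

logger = logging.getLogger(__name__)

Category = Literal["low", "average", "elevated"]

#: Default risk-band cutpoints: GRS < 0.5 low, 0.5-1.5 average, > 1.5 elevated.
LOW_CUT: float = 0.5
HIGH_CUT: float = 1.5

#: Subjects missing more than this fraction of panel SNPs are flagged.
MAX_MISSING_FRACTION: float = 0.2


@dataclass(frozen=True)
class GRSResult:
    """Per-subject score, risk category and number of SNPs actually used."""

    subject_id: str
    grs: float
    category: Category
    n_snps_used: int


def normalization_constant(f: float, odds_ratio: float) -> float:
    """Population-mean risk factor W = E[OR**g] under HWE at frequency f.

    Parameters
    ----------
    f
        Risk-allele frequency in the standardization population, in [0, 1].
    odds_ratio
        Per-allele odds ratio, > 0.
    """
    if not (math.isfinite(f) and 0 <= f <= 1):
        raise InvalidParameterError(f"frequency must be in [0, 1], got {f}")
    if not (math.isfinite(odds_ratio) and odds_ratio > 0):
        raise InvalidParameterError(f"odds_ratio must be > 0, got {odds_ratio}")
    return f * f * odds_ratio * odds_ratio + 2 * f * (1 - f) * odds_ratio + (1 - f) ** 2


def snp_risk_factor(dosage: int, odds_ratio: float, w: float) -> float:
    """Standardized single-SNP factor OR**g / W.

    A missing dosage contributes the neutral factor 1.0 — the subject is
    assigned the population-average risk at that SNP rather than imputed.
    """
    if w <= 0 or not math.isfinite(w):
        raise InvalidParameterError(f"normalization constant must be > 0, got {w}")
    if dosage == MISSING:
        return 1.0
    if dosage not in (0, 1, 2):
        raise InvalidDosageError(f"dosage must be 0, 1, 2 or missing, got {dosage}")
    return odds_ratio**dosage / w


def compute_grs(
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    *,
    low_cut: float = LOW_CUT,
    high_cut: float = HIGH_CUT,
    on_all_missing: Literal["raise", "drop"] = "drop",
) -> list[GRSResult]:
    """Score every subject in ``genotypes`` against ``panel``.

    SNPs present in the panel but absent from the genotype matrix contribute
    the neutral factor for every subject. Subjects with every panel dosage
    missing cannot be distinguished from the population mean and are either
    dropped with a warning (default) or raise :class:`FlaggedSubjectError`.
    Subjects missing more than 20% of panel SNPs are logged as flagged but
    still scored.
    """
    sub = panel.subset(genotypes.snp_ids)
    log_or = np.array([math.log(e.odds_ratio) for e in sub])
    log_w = np.array(
        [
            math.log(normalization_constant(e.risk_allele_freq, e.odds_ratio))
            for e in sub
        ]
    )
    d = genotypes.dosages
    miss = d == MISSING
    g = np.where(miss, 0, d).astype(float)
    # missing SNP -> factor 1: drop both the OR**g and the 1/W term
    log_grs = g @ log_or - (~miss) @ log_w
    n_used = (~miss).sum(axis=1)

    results: list[GRSResult] = []
    n_panel = len(panel)
    for i, sid in enumerate(genotypes.subject_ids):
        used = int(n_used[i])
        if used == 0:
            msg = f"subject {sid!r}: all {n_panel} panel dosages missing; not scored"
            if on_all_missing == "raise":
                raise FlaggedSubjectError(msg)
            logger.warning(msg)
            continue
        if n_panel - used > MAX_MISSING_FRACTION * n_panel:
            logger.warning(
                "subject %r: %d/%d panel SNPs missing (>%.0f%%); score uses "
                "population-average risk for missing SNPs",
                sid,
                n_panel - used,
                n_panel,
                100 * MAX_MISSING_FRACTION,
            )
        score = float(math.exp(log_grs[i]))
        results.append(
            GRSResult(sid, score, categorize_grs(score, low_cut, high_cut), used)
        )
    return results


def categorize_grs(
    grs: float, low_cut: float = LOW_CUT, high_cut: float = HIGH_CUT
) -> Category:
    """Risk band for a score: < low_cut -> low, [low_cut, high_cut] ->
    average, > high_cut -> elevated. The middle band is closed on both ends;
    the printed outer bands are strict inequalities."""
    if not (0 < low_cut < high_cut):
        raise InvalidParameterError(
            f"cutpoints must satisfy 0 < low < high, got {low_cut}, {high_cut}"
        )
    if not (math.isfinite(grs) and grs > 0):
        raise InvalidParameterError(f"GRS must be finite and > 0, got {grs}")
    if grs < low_cut:
        return "low"
    if grs > high_cut:
        return "elevated"
    return "average"
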