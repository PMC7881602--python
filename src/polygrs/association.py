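"""Association battery for scored screening cohorts.

Implements the statistics used to relate the GRS (and clinical covariates)
to colonoscopy outcome: 2x2 odds ratios with Woolf confidence intervals,
detection rates, maximum-likelihood logistic regression (univariable and
multivariable), Welch t comparison of group GRS means, the Cochran-Armitage
test for trend in detection rate across ordered risk categories, and the
polyp-subtype association table (each subtype vs the no-polyp reference on
continuous GRS).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import DegenerateStatisticError, SchemaError
from .grs import GRSResult
from .phenotypes import LOCATIONS, PhenotypeRecord

logger = logging.getLogger(__name__)

Z95 = st.norm.ppf(0.975)


# ------------------------------------------------------------- 2x2 odds ----


@dataclass(frozen=True)
class TwoByTwo:
    """Counts: a = exposed positive, b = unexposed positive,
    c = exposed negative, d = unexposed negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in counts):
            raise SchemaError(f"2x2 counts must be non-negative integers: {counts}")
        if sum(counts) == 0:
            raise SchemaError("empty 2x2 table")


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity_corrected: bool = False


def odds_ratio_2x2(
    table: TwoByTwo, *, continuity_correction: bool = False
) -> OddsRatioResult:
    """Cross-product odds ratio (a*d)/(b*c) with Woolf log-method 95% CI
    and a Wald p-value on the log odds ratio.

    A zero cell makes the OR or its variance undefined; with
    ``continuity_correction`` 0.5 is added to every cell (Haldane-Anscombe)
    and the result is flagged, otherwise an error is raised.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = False
    if 0 in (a, b, c, d):
        if not continuity_correction:
            raise DegenerateStatisticError(
                f"zero cell in 2x2 table {(a, b, c, d)}; odds ratio undefined "
                "(enable continuity correction to proceed)"
            )
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        corrected = True
        logger.warning("2x2 zero cell: applied Haldane-Anscombe correction")
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p_value=2 * st.norm.sf(abs(z)),
        continuity_corrected=corrected,
    )


def detection_rate(positives: int, total: int) -> float:
    """Fraction of screened subjects with >= 1 adenomatous polyp."""
    if total <= 0:
        raise DegenerateStatisticError("detection rate undefined for total = 0")
    if not 0 <= positives <= total:
        raise SchemaError(f"positives {positives} outside [0, {total}]")
    return positives / total


# ------------------------------------------------------------- logistic ----


@dataclass(frozen=True)
class LogisticModelFit:
    """Maximum-likelihood logistic fit with Wald inference per term."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_obs: int
    log_likelihood: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            },
            index=list(self.terms),
        )

    def term(self, name: str) -> pd.Series:
        return self.summary_frame().loc[name]


def fit_logistic(
    outcome: Sequence[int], covariates: pd.DataFrame, *, max_iter: int = 100
) -> LogisticModelFit:
    """Fit outcome ~ intercept + covariates by maximum likelihood.

    Perfect separation and non-convergence raise a diagnostic error naming
    the offending term rather than returning runaway estimates.
    """
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(covariates.astype(float), has_constant="add")
    if y.shape[0] != X.shape[0]:
        raise SchemaError("outcome and covariates have different lengths")
    if y.shape[0] <= 10 * (X.shape[1] - 1):
        logger.warning(
            "only %d observations for %d terms; estimates may be unstable",
            y.shape[0], X.shape[1] - 1,
        )
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, maxiter=max_iter, tol=1e-10)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise DegenerateStatisticError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    runaway = np.abs(params) > 15
    if runaway.any():
        bad = [X.columns[i] for i in np.where(runaway)[0]]
        raise DegenerateStatisticError(
            f"separation suspected: runaway coefficient(s) for {bad}"
        )
    if not res.mle_retvals.get("converged", False):
        raise DegenerateStatisticError("logistic fit did not converge")
    return LogisticModelFit(
        terms=tuple(X.columns),
        coefficients=params,
        standard_errors=bse,
        odds_ratios=np.exp(params),
        ci_low=np.exp(params - Z95 * bse),
        ci_high=np.exp(params + Z95 * bse),
        p_values=np.asarray(res.pvalues),
        converged=True,
        n_obs=int(res.nobs),
        log_likelihood=float(res.llf),
    )


# ---------------------------------------------------------------- trend ----


@dataclass(frozen=True)
class TrendResult:
    categories: tuple[str, ...]
    positives: tuple[int, ...]
    totals: tuple[int, ...]
    rates: tuple[float, ...]
    statistic: float  # signed Cochran-Armitage Z
    p_trend: float


def trend_across_categories(
    positives: Sequence[int],
    totals: Sequence[int],
    categories: Optional[Sequence[str]] = None,
    scores: Optional[Sequence[float]] = None,
) -> TrendResult:
    """Cochran-Armitage test for linear trend in proportions across ordered
    categories (default integer scores 0, 1, 2, ...).

    The statistic is Z = T / sqrt(Var T) with T = sum_i s_i (r_i - n_i pbar)
    under the pooled null proportion pbar; Z**2 is the usual 1-df trend
    chi-square and the p-value is two-sided.
    """
    r = np.asarray(positives, dtype=float)
    n = np.asarray(totals, dtype=float)
    if r.shape != n.shape or r.ndim != 1 or len(r) < 2:
        raise DegenerateStatisticError("trend requires >= 2 ordered categories")
    if (n <= 0).any() or ((r < 0) | (r > n)).any():
        raise SchemaError("invalid counts for trend test")
    s = np.asarray(scores, dtype=float) if scores is not None else np.arange(len(r))
    N, R = n.sum(), r.sum()
    pbar = R / N
    if pbar in (0.0, 1.0):
        raise DegenerateStatisticError("all outcomes identical; trend undefined")
    t = float(np.sum(s * (r - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(s**2 * n) - np.sum(s * n) ** 2 / N)
    z = t / math.sqrt(var)
    cats = tuple(categories) if categories is not None else tuple(
        f"cat{i}" for i in range(len(r))
    )
    return TrendResult(
        categories=cats,
        positives=tuple(int(x) for x in r),
        totals=tuple(int(x) for x in n),
        rates=tuple(r / n),
        statistic=z,
        p_trend=float(2 * st.norm.sf(abs(z))),
    )


# ------------------------------------------------------------ GRS means ----


@dataclass(frozen=True)
class GroupMean:
    label: str
    n: int
    mean: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class MeanComparison:
    groups: tuple[GroupMean, ...]
    t_statistic: float
    p_value: float


def compare_grs_means(
    values_by_group: dict[str, Sequence[float]]
) -> MeanComparison:
    """Per-group mean GRS with normal-theory 95% CI and a Welch two-sample
    t-test between the two groups (outcome-positive vs -negative)."""
    if len(values_by_group) != 2:
        raise DegenerateStatisticError("mean comparison requires exactly 2 groups")
    groups = []
    arrays = []
    for label, vals in values_by_group.items():
        x = np.asarray(vals, dtype=float)
        if len(x) < 2:
            raise DegenerateStatisticError(f"group {label!r} has < 2 observations")
        sem = x.std(ddof=1) / math.sqrt(len(x))
        groups.append(
            GroupMean(label, len(x), float(x.mean()),
                      float(x.mean() - Z95 * sem), float(x.mean() + Z95 * sem))
        )
        arrays.append(x)
    if arrays[0].std(ddof=1) == 0 and arrays[1].std(ddof=1) == 0:
        raise DegenerateStatisticError("zero variance in both groups")
    t, p = st.ttest_ind(arrays[0], arrays[1], equal_var=False)
    return MeanComparison(tuple(groups), float(t), float(p))


# ------------------------------------------------------------ subgroups ----

#: Minimum subtype size below which the estimate is flagged as unstable.
MIN_SUBTYPE_N = 10


@dataclass(frozen=True)
class SubgroupRow:
    subtype: str
    n: int
    grs_mean: float
    grs_ci_low: float
    grs_ci_high: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    wide_ci_warning: bool


def subgroup_associations(
    scores: Sequence[GRSResult], phenotypes: Sequence[PhenotypeRecord]
) -> pd.DataFrame:
    """Association of continuous GRS with each polyp subtype versus the
    no-polyp (or hyperplastic-only) reference.

    Rows: any adenomatous polyp; size < 0.5 / >= 0.5 cm; advanced adenoma;
    single / multiple polyps; location CA / TD / RS. Each row is a logistic
    fit of subtype membership vs the shared reference on GRS. Subtypes with
    no members are omitted with a log note; subtypes with < 10 members carry
    a wide-CI warning flag.
    """
    grs_by_id = {s.subject_id: s.grs for s in scores}
    ph = [p for p in phenotypes if p.subject_id in grs_by_id]
    dropped = len(phenotypes) - len(ph)
    if dropped:
        logger.warning("%d phenotype record(s) without a GRS were dropped", dropped)
    reference = [p for p in ph if not p.outcome]
    positives = [p for p in ph if p.outcome]
    if not reference:
        raise DegenerateStatisticError("no reference (outcome-negative) subjects")

    def members(pred) -> list[PhenotypeRecord]:
        return [p for p in positives if pred(p)]

    subtypes = [
        ("adenomatous_polyps", lambda p: True),
        ("size_lt_0.5cm", lambda p: p.polyp_size_class == "lt_0.5cm"),
        ("size_ge_0.5cm", lambda p: p.polyp_size_class == "ge_0.5cm"),
        ("advanced_adenoma", lambda p: bool(p.advanced_adenoma)),
        ("count_one", lambda p: p.polyp_count_class == "one"),
        ("count_multiple", lambda p: p.polyp_count_class == "multiple"),
    ] + [
        (f"location_{loc}", lambda p, loc=loc: loc in p.polyp_location)
        for loc in LOCATIONS
    ]

    ref_grs = np.array([grs_by_id[p.subject_id] for p in reference])
    rows: list[SubgroupRow] = []
    for name, pred in subtypes:
        mem = members(pred)
        if not mem:
            logger.info("subtype %s: no members; row omitted", name)
            continue
        sub_grs = np.array([grs_by_id[p.subject_id] for p in mem])
        y = np.concatenate([np.zeros(len(ref_grs)), np.ones(len(sub_grs))])
        x = pd.DataFrame({"grs": np.concatenate([ref_grs, sub_grs])})
        fit = fit_logistic(y, x)
        term = fit.term("grs")
        sem = sub_grs.std(ddof=1) / math.sqrt(len(sub_grs)) if len(sub_grs) > 1 else 0.0
        wide = len(mem) < MIN_SUBTYPE_N
        if wide:
            logger.warning("subtype %s: only %d members; CI unstable", name, len(mem))
        rows.append(
            SubgroupRow(
                subtype=name,
                n=len(mem),
                grs_mean=float(sub_grs.mean()),
                grs_ci_low=float(sub_grs.mean() - Z95 * sem),
                grs_ci_high=float(sub_grs.mean() + Z95 * sem),
                odds_ratio=float(term["odds_ratio"]),
                ci_low=float(term["ci_low"]),
                ci_high=float(term["ci_high"]),
                p_value=float(term["p"]),
                wide_ci_warning=wide,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("subtype")
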