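"""Kaplan-Meier adenoma-diagnosis-free analysis by GRS risk group.

Time zero is birth; the event is the first screening colonoscopy that finds
an adenomatous polyp, observed at the subject's age at that colonoscopy.
Event-free subjects are right-censored at the same age — each subject
contributes a single time point, so the product-limit curves describe the
age distribution of first adenoma diagnosis conditional on being screened.
No left-truncation is applied (all subjects are treated as observed from
birth); the resulting curves are descriptive of the screened cohort rather
than of population incidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import DegenerateStatisticError
from .grs import GRSResult
from .phenotypes import PhenotypeRecord

logger = logging.getLogger(__name__)

GROUP_ORDER = ("low", "average", "elevated")


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time: float  # age in years, from birth to first screening colonoscopy
    event: bool  # adenomatous polyp(s) found at that colonoscopy
    group: str  # GRS risk category

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.subject_id}: non-positive time {self.time}")


def build_survival_records(
    scores: Sequence[GRSResult], phenotypes: Sequence[PhenotypeRecord]
) -> list[SurvivalRecord]:
    """Join scores and phenotypes into survival records keyed by subject."""
    cat = {s.subject_id: s.category for s in scores}
    recs = []
    for p in phenotypes:
        if p.subject_id not in cat:
            continue
        recs.append(
            SurvivalRecord(p.subject_id, p.age_at_colonoscopy, p.outcome, cat[p.subject_id])
        )
    return recs


def km_estimate(records: Sequence[SurvivalRecord]) -> dict[str, pd.DataFrame]:
    """Product-limit diagnosis-free curves, one per group.

    Returns a DataFrame per group with columns ``age``, ``at_risk``,
    ``events``, ``censored``, ``survival`` — one row per distinct observed
    time (events processed before censorings at ties, the standard
    convention). Curves start at 1.0 and are monotone non-increasing.
    Empty groups are omitted with a warning.
    """
    if not records:
        raise DegenerateStatisticError("no survival records")
    if not any(r.event for r in records):
        logger.warning("no events in any group; curves are flat at 1.0")
    out: dict[str, pd.DataFrame] = {}
    groups = [g for g in GROUP_ORDER if any(r.group == g for r in records)]
    groups += sorted({r.group for r in records} - set(groups))
    for g in GROUP_ORDER:
        if g not in groups:
            logger.warning("group %r is empty; omitted from KM output", g)
    for g in groups:
        sub = [r for r in records if r.group == g]
        t = np.array([r.time for r in sub])
        e = np.array([r.event for r in sub], dtype=bool)
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=e)
        tbl = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        df = pd.DataFrame(
            {
                "age": tbl.index.to_numpy(dtype=float),
                "at_risk": tbl["at_risk"].to_numpy(dtype=int),
                "events": tbl["observed"].to_numpy(dtype=int),
                "censored": tbl["censored"].to_numpy(dtype=int),
                "survival": surv.reindex(tbl.index).to_numpy(dtype=float),
            }
        )
        out[g] = df.reset_index(drop=True)
    return out


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    groups: tuple[str, ...]


def logrank_test(records: Sequence[SurvivalRecord]) -> LogrankResult:
    """Unweighted k-sample log-rank test across GRS groups (df = k - 1)."""
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise DegenerateStatisticError("log-rank requires >= 2 non-empty groups")
    t = np.array([r.time for r in records])
    e = np.array([int(r.event) for r in records])
    g = np.array([r.group for r in records])
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
        groups=tuple(groups),
    )


@dataclass(frozen=True)
class GroupAges:
    means: dict[str, float]
    counts: dict[str, int]
    f_statistic: Optional[float]
    p_value: Optional[float]


def mean_age_by_group(records: Sequence[SurvivalRecord]) -> GroupAges:
    """Per-group mean age at colonoscopy with a one-way F-test.

    With zero variance everywhere (all ages equal) the F-test is undefined
    and both statistic and p are returned as None.
    """
    if not records:
        raise DegenerateStatisticError("no records")
    by_group: dict[str, list[float]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r.time)
    means = {g: float(np.mean(v)) for g, v in by_group.items()}
    counts = {g: len(v) for g, v in by_group.items()}
    arrays = [np.asarray(v) for v in by_group.values()]
    if len(arrays) < 2 or all(a.std() == 0 for a in arrays):
        logger.warning("age comparison degenerate (one group or zero variance)")
        return GroupAges(means, counts, None, None)
    f, p = st.f_oneway(*arrays)
    return GroupAges(means, counts, float(f), float(p))
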