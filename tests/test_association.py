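"""Association battery: 2x2 odds ratios, detection rates, logistic fits,
Cochran-Armitage trend (against a permutation oracle), group-mean
comparison, and the polyp-subtype table."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from polygrs import association as assoc
from polygrs.association import (
    TwoByTwo,
    compare_grs_means,
    detection_rate,
    fit_logistic,
    odds_ratio_2x2,
    subgroup_associations,
    trend_across_categories,
)
from polygrs.errors import DegenerateStatisticError, SchemaError
from polygrs.grs import GRSResult
from polygrs.phenotypes import PhenotypeRecord


class TestOddsRatio2x2:
    def test_male_vs_female_outcome_table(self):
        # 658 males (247 positive), 1111 females (273 positive)
        res = odds_ratio_2x2(TwoByTwo(a=247, b=273, c=411, d=838))
        assert res.odds_ratio == pytest.approx(1.84, abs=0.005)
        assert res.p_value < 0.001

    def test_family_history_table(self):
        res = odds_ratio_2x2(TwoByTwo(a=40, b=480, c=87, d=1162))
        assert res.odds_ratio == pytest.approx(1.11, abs=0.005)
        assert res.p_value > 0.05

    def test_symmetric_table_gives_unit_or(self):
        res = odds_ratio_2x2(TwoByTwo(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1 < res.ci_high

    def test_single_row_swap_inverts_or(self):
        t = TwoByTwo(30, 20, 15, 40)
        direct = odds_ratio_2x2(t)
        swapped = odds_ratio_2x2(TwoByTwo(20, 30, 40, 15))
        assert swapped.odds_ratio == pytest.approx(1 / direct.odds_ratio, rel=1e-12)
        # double swap restores the original
        double = odds_ratio_2x2(TwoByTwo(40, 15, 20, 30))
        assert double.odds_ratio == pytest.approx(direct.odds_ratio, rel=1e-12)

    def test_zero_cell_requires_continuity_correction(self):
        with pytest.raises(DegenerateStatisticError):
            odds_ratio_2x2(TwoByTwo(0, 10, 10, 10))
        res = odds_ratio_2x2(TwoByTwo(0, 10, 10, 10), continuity_correction=True)
        assert res.continuity_corrected
        assert res.odds_ratio > 0

    def test_negative_count_rejected(self):
        with pytest.raises(SchemaError):
            TwoByTwo(-1, 2, 3, 4)


class TestDetectionRate:
    @pytest.mark.parametrize(
        "positives, total, pct",
        [(520, 1769, 29.4), (247, 658, 37.5), (273, 1111, 24.6), (0, 100, 0.0)],
    )
    def test_rates_at_printed_precision(self, positives, total, pct):
        assert round(100 * detection_rate(positives, total), 1) == pct

    def test_zero_total_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            detection_rate(0, 0)


class TestFitLogistic:
    def _binary_cohort(self):
        """Expanded subject-level data for the male/female 2x2 table."""
        male = np.repeat([1.0, 1.0, 0.0, 0.0], [247, 411, 273, 838])
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [247, 411, 273, 838])
        return y, pd.DataFrame({"male": male})

    def test_single_binary_covariate_matches_cross_product_or(self):
        y, X = self._binary_cohort()
        fit = fit_logistic(y, X)
        closed = odds_ratio_2x2(TwoByTwo(247, 273, 411, 838))
        assert fit.term("male")["odds_ratio"] == pytest.approx(
            closed.odds_ratio, rel=1e-6
        )
        assert fit.term("male")["se"] == pytest.approx(
            np.sqrt(1 / 247 + 1 / 273 + 1 / 411 + 1 / 838), rel=1e-4
        )

    def test_permuted_outcome_gives_null_or(self):
        # each 95% CI misses 1 about 5% of the time, so require coverage in
        # a clear majority of independent permutations
        rng = np.random.default_rng(42)
        y, X = self._binary_cohort()
        covered = 0
        for _ in range(10):
            term = fit_logistic(rng.permutation(y), X).term("male")
            covered += term["ci_low"] < 1 < term["ci_high"]
        assert covered >= 8

    def test_multivariable_recovery_within_two_se(self):
        rng = np.random.default_rng(7)
        n = 5000
        truth = {"x1": 0.5, "x2": -0.3, "x3": 0.8}
        X = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "x3": (rng.random(n) < 0.4).astype(float),
            }
        )
        eta = -0.9 + sum(b * X[k] for k, b in truth.items())
        y = (rng.random(n) < expit(eta)).astype(float)
        fit = fit_logistic(y, X)
        for k, b in truth.items():
            t = fit.term(k)
            assert abs(t["coef"] - b) < 2 * t["se"]

    def test_perfect_separation_raises_diagnostic(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        with pytest.raises(DegenerateStatisticError):
            fit_logistic(y, pd.DataFrame({"x": x}))


def cochran_armitage_permutation_oracle(
    positives, totals, n_perm=100_000, seed=0
):
    """Monte-Carlo permutation distribution of the trend statistic,
    conditioning on both margins.

    Subject-level scores are the category indices; outcome labels are
    permuted across all subjects, which preserves both margins exactly.
    Because the statistic is lattice-valued, a single two-sided p is
    ambiguous at the observed point: returns ``(p_mid, p_strict, se)`` —
    the mid-p (half mass at the observed value) and the conventional
    strict p (full mass). A correct asymptotic p lies in this band up to
    Monte-Carlo error.
    """
    rng = np.random.default_rng(seed)
    scores = np.repeat(np.arange(len(totals), dtype=float), totals)
    y = np.concatenate(
        [
            np.repeat([1.0, 0.0], [p, t - p])
            for p, t in zip(positives, totals)
        ]
    )
    t_obs = scores @ y
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = scores @ rng.permutation(y)
    center = perms.mean()
    dev = np.abs(perms - center)
    d_obs = abs(t_obs - center)
    p_strict = float(np.mean(dev >= d_obs - 1e-9))
    at_obs = float(np.mean(np.abs(dev - d_obs) <= 1e-9))
    p_mid = p_strict - 0.5 * at_obs
    return p_mid, p_strict, np.sqrt(p_strict * (1 - p_strict) / n_perm)


class TestTrend:
    def test_increasing_rates_give_small_p(self):
        res = trend_across_categories([50, 150, 250], [500, 500, 500])
        assert res.statistic > 0
        assert res.p_trend < 1e-10

    def test_equal_rates_give_null_statistic(self):
        res = trend_across_categories([50, 50, 50], [200, 200, 200])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_permutation_oracle_on_small_table(self):
        positives, totals = [1, 5, 9], [10, 10, 10]
        res = trend_across_categories(positives, totals)
        p_mid, p_strict, se_mc = cochran_armitage_permutation_oracle(
            positives, totals, n_perm=100_000, seed=123
        )
        assert p_mid - 3 * se_mc <= res.p_trend <= p_strict + 3 * se_mc

    def test_rates_recompose_to_overall(self):
        positives, totals = [13, 208, 99], [210, 1318, 241]
        res = trend_across_categories(positives, totals)
        overall = sum(positives) / sum(totals)
        weighted = sum(r * t for r, t in zip(res.rates, res.totals)) / sum(res.totals)
        assert weighted == pytest.approx(overall, rel=1e-12)
        assert all(0 <= r <= 1 for r in res.rates)

    def test_single_category_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            trend_across_categories([5], [10])


class TestCompareGrsMeans:
    def test_identical_groups(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 0.3, size=400)
        res = compare_grs_means({"positive": x, "negative": x.copy()})
        assert res.p_value == pytest.approx(1.0)
        means = [g.mean for g in res.groups]
        assert means[0] == pytest.approx(means[1])

    def test_shifted_groups_detected(self):
        # delta = 0.05, sigma = 0.3, n = 500 / 1200: power ~ 0.88 at alpha 0.05;
        # a seeded draw near the mean shift rejects comfortably
        rng = np.random.default_rng(2)
        pos = rng.normal(1.02, 0.3, size=500)
        neg = rng.normal(0.97, 0.3, size=1200)
        res = compare_grs_means({"positive": pos, "negative": neg})
        assert res.p_value < 0.05
        by_label = {g.label: g for g in res.groups}
        assert by_label["positive"].ci_low < 1.02 < by_label["positive"].ci_high

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            compare_grs_means({"only": [1.0, 1.1, 0.9]})

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            compare_grs_means({"a": [1.0, 1.0], "b": [1.0, 1.0]})


def _cohort_for_subgroups(effect: float, seed: int, n: int = 3000):
    """Pool with P(positive) = expit(-1.6 + effect * grs); positives get a
    size class so the subtype rows are populated."""
    rng = np.random.default_rng(seed)
    grs = np.clip(rng.normal(1.0, 0.35, size=n), 0.05, None)
    y = rng.random(n) < expit(-1.6 + effect * grs)
    scores, phenos = [], []
    for i in range(n):
        sid = f"s{i}"
        scores.append(GRSResult(sid, float(grs[i]), "average", 22))
        large = bool(rng.random() < 0.6)
        phenos.append(
            PhenotypeRecord(
                subject_id=sid,
                age_at_colonoscopy=60.0,
                sex="female",
                family_history=False,
                outcome=bool(y[i]),
                polyp_size_class=(
                    "none" if not y[i] else ("ge_0.5cm" if large else "lt_0.5cm")
                ),
                polyp_count_class="none" if not y[i] else "one",
                advanced_adenoma=None if not y[i] else False,
            )
        )
    return scores, phenos


class TestSubgroupAssociations:
    def test_null_effect_gives_unit_or(self):
        scores, phenos = _cohort_for_subgroups(effect=0.0, seed=10)
        table = subgroup_associations(scores, phenos)
        row = table.loc["adenomatous_polyps"]
        assert row.ci_low < 1 < row.ci_high

    def test_injected_effect_recovered_within_two_se(self):
        effect = 0.8
        scores, phenos = _cohort_for_subgroups(effect=effect, seed=11)
        table = subgroup_associations(scores, phenos)
        row = table.loc["adenomatous_polyps"]
        log_or = np.log(row.odds_ratio)
        se = (np.log(row.ci_high) - np.log(row.ci_low)) / (2 * assoc.Z95)
        assert abs(log_or - effect) < 2 * se

    def test_empty_subtype_row_omitted(self):
        scores, phenos = _cohort_for_subgroups(effect=0.5, seed=12)
        table = subgroup_associations(scores, phenos)
        # no polyp_location was ever assigned, and no multiples
        assert "location_CA" not in table.index
        assert "count_multiple" not in table.index
        assert "count_one" in table.index

    def test_small_subtype_flagged(self):
        scores, phenos = _cohort_for_subgroups(effect=0.5, seed=13, n=300)
        # force advanced adenoma for a handful of positives
        n_adv = 0
        for p in phenos:
            if p.outcome and p.polyp_size_class == "ge_0.5cm" and n_adv < 5:
                p.advanced_adenoma = True
                n_adv += 1
        table = subgroup_associations(scores, phenos)
        assert bool(table.loc["advanced_adenoma", "wide_ci_warning"])
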