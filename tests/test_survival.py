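"""Kaplan-Meier curves and log-rank test, checked against hand-computed
product-limit and observed-minus-expected tables."""

import numpy as np
import pytest

from polygrs import simulate
from polygrs.errors import DegenerateStatisticError
from polygrs.grs import compute_grs
from polygrs.survival import (
    SurvivalRecord,
    build_survival_records,
    km_estimate,
    logrank_test,
    mean_age_by_group,
)


def rec(sid, time, event, group="average"):
    return SurvivalRecord(sid, time, event, group)


class TestKmEstimate:
    def test_no_censoring_matches_empirical_survival(self):
        records = [rec(f"s{i}", t, True) for i, t in enumerate((50, 60, 70))]
        df = km_estimate(records)["average"]
        by_age = dict(zip(df["age"], df["survival"]))
        assert by_age[50.0] == pytest.approx(2 / 3)
        assert by_age[60.0] == pytest.approx(1 / 3)
        assert by_age[70.0] == pytest.approx(0.0)

    def test_all_censored_gives_flat_curve(self):
        records = [rec(f"s{i}", 50 + i, False) for i in range(4)]
        df = km_estimate(records)["average"]
        assert (df["survival"] == 1.0).all()

    def test_hand_computed_product_limit_table(self):
        # at-risk 6, event at 50 -> 5/6; censored at 55; two events at 60
        # with 4 at risk -> 5/6 * 2/4 = 5/12; censored at 65; event at 70
        # with 1 at risk -> 0
        records = [
            rec("a", 50, True), rec("b", 55, False), rec("c", 60, True),
            rec("d", 60, True), rec("e", 65, False), rec("f", 70, True),
        ]
        df = km_estimate(records)["average"]
        by_age = dict(zip(df["age"], df["survival"]))
        assert by_age[50.0] == pytest.approx(5 / 6)
        assert by_age[55.0] == pytest.approx(5 / 6)  # censoring leaves S
        assert by_age[60.0] == pytest.approx(5 / 12)
        assert by_age[70.0] == pytest.approx(0.0)

    def test_curves_monotone_and_start_at_one(self):
        rng = np.random.default_rng(5)
        records = [
            rec(f"s{i}", float(t), bool(e), g)
            for i, (t, e, g) in enumerate(
                zip(
                    rng.uniform(46, 85, size=60),
                    rng.random(60) < 0.4,
                    rng.choice(["low", "average", "elevated"], size=60),
                )
            )
        ]
        for df in km_estimate(records).values():
            s = df["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)  # time-zero row
            assert (np.diff(s) <= 1e-12).all()

    def test_km_equals_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(6)
        times = rng.uniform(46, 90, size=40)
        records = [rec(f"s{i}", float(t), True) for i, t in enumerate(times)]
        df = km_estimate(records)["average"]
        for age, surv in zip(df["age"], df["survival"]):
            if age == 0:
                continue
            ecdf = np.mean(times <= age)
            assert surv == pytest.approx(1 - ecdf, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            km_estimate([])


def logrank_oracle(records):
    """Direct O-E/V computation for the unweighted k-sample log-rank test.

    Returns (chi2, per-group observed-minus-expected totals).
    """
    groups = sorted({r.group for r in records})
    times = sorted({r.time for r in records if r.event})
    o_minus_e = np.zeros(len(groups))
    var = np.zeros((len(groups), len(groups)))
    for t in times:
        at_risk = np.array(
            [sum(1 for r in records if r.group == g and r.time >= t) for g in groups],
            dtype=float,
        )
        deaths = np.array(
            [
                sum(1 for r in records if r.group == g and r.time == t and r.event)
                for g in groups
            ],
            dtype=float,
        )
        n, d = at_risk.sum(), deaths.sum()
        expected = d * at_risk / n
        o_minus_e += deaths - expected
        if n > 1:
            for i in range(len(groups)):
                for j in range(len(groups)):
                    delta = 1.0 if i == j else 0.0
                    var[i, j] += (
                        d * (at_risk[i] / n) * (delta - at_risk[j] / n)
                        * (n - d) / (n - 1)
                    )
    v = var[:-1, :-1]
    u = o_minus_e[:-1]
    chi2 = float(u @ np.linalg.solve(v, u))
    return chi2, o_minus_e


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        base = [(50, True), (55, False), (60, True), (70, True), (75, False)]
        records = [
            rec(f"{g}{i}", t, e, g)
            for g in ("low", "elevated")
            for i, (t, e) in enumerate(base)
        ]
        res = logrank_test(records)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.df == 1

    def test_matches_hand_computed_oe_table(self):
        records = [
            rec("a1", 50, True, "low"), rec("a2", 58, True, "low"),
            rec("a3", 66, False, "low"), rec("a4", 72, True, "low"),
            rec("b1", 52, True, "elevated"), rec("b2", 55, True, "elevated"),
            rec("b3", 60, True, "elevated"), rec("b4", 64, False, "elevated"),
        ]
        chi2, o_minus_e = logrank_oracle(records)
        res = logrank_test(records)
        assert res.statistic == pytest.approx(chi2, rel=1e-8)
        # observed-minus-expected sums to zero over groups
        assert o_minus_e.sum() == pytest.approx(0.0, abs=1e-10)

    def test_three_group_statistic_matches_oracle(self):
        rng = np.random.default_rng(8)
        records = [
            rec(
                f"s{i}",
                float(rng.uniform(46, 85)),
                bool(rng.random() < 0.5),
                ("low", "average", "elevated")[i % 3],
            )
            for i in range(45)
        ]
        chi2, _ = logrank_oracle(records)
        res = logrank_test(records)
        assert res.df == 2
        assert res.statistic == pytest.approx(chi2, rel=1e-6)

    def test_group_relabeling_invariance(self):
        records = [
            rec("a1", 50, True, "low"), rec("a2", 60, True, "low"),
            rec("b1", 55, True, "high"), rec("b2", 70, False, "high"),
        ]
        swapped = [
            SurvivalRecord(r.subject_id, r.time, r.event,
                           "high" if r.group == "low" else "low")
            for r in records
        ]
        assert logrank_test(records).statistic == pytest.approx(
            logrank_test(swapped).statistic, rel=1e-12
        )

    def test_single_group_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            logrank_test([rec("a", 50, True), rec("b", 60, False)])

    def test_injected_grs_effect_detected(self):
        # cohort where outcome risk rises with GRS: higher-risk groups
        # accumulate diagnoses earlier, so the curves separate
        bundle = simulate.generate_study(
            simulate.SimulationConfig(n_subjects=2000, genotype_effect_scale=2.0, seed=31)
        )
        scores = compute_grs(bundle.genotypes, bundle.panel)
        records = build_survival_records(scores, bundle.phenotypes)
        assert len({r.group for r in records}) == 3
        assert logrank_test(records).p_value < 0.01


class TestMeanAgeByGroup:
    def test_equal_ages_degenerate(self):
        records = [rec(f"s{i}", 60.0, False, g) for i, g in enumerate(
            ("low", "low", "average", "average")
        )]
        res = mean_age_by_group(records)
        assert res.p_value is None
        assert res.means == {"low": 60.0, "average": 60.0}

    def test_no_age_group_link_gives_uniformish_p(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(40):
            records = [
                rec(f"s{i}", float(rng.normal(60, 8)), False,
                    ("low", "average", "elevated")[i % 3])
                for i in range(90)
            ]
            ps.append(mean_age_by_group(records).p_value)
        ps = np.asarray(ps)
        # under the null p is Uniform(0,1): mean near 0.5, few tiny values
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.01).sum() <= 2

    def test_group_means_reported(self):
        records = [
            rec("a", 59.0, False, "low"), rec("b", 61.0, True, "low"),
            rec("c", 60.0, False, "average"), rec("d", 62.0, True, "average"),
        ]
        res = mean_age_by_group(records)
        assert res.means["low"] == pytest.approx(60.0)
        assert res.counts == {"low": 2, "average": 2}
        assert res.p_value is not None
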