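"""Statistical suite: oracle equivalences for each test and
planted-effect recovery on the synthetic cohort."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import immunodissect as im
from immunodissect.associations import (
    anova_test,
    km_logrank,
    rank_sum_test,
    signed_rank_test,
)


class TestRankSum:
    def test_extreme_separation_enumeration_oracle(self):
        # {1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 assignments,
        # two-sided p = 2/20 = 0.1 by literal enumeration
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        r = rank_sum_test(x, y)
        pooled = np.array(x + y)
        ranks = stats.rankdata(pooled)
        obs = ranks[:3].sum()
        mean = 3 * 7 / 2
        count = sum(
            abs(sum(ranks[list(c)]) - mean) >= abs(obs - mean) - 1e-9
            for c in itertools.combinations(range(6), 3)
        )
        assert r.p_value == pytest.approx(count / 20, abs=1e-12)
        assert r.p_value == pytest.approx(0.1, abs=1e-12)
        assert r.direction == -1

    def test_exact_matches_literal_enumeration_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.integers(0, 5, size=6).astype(float)
            y = rng.integers(0, 5, size=5).astype(float)
            r = rank_sum_test(x, y)
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            n1 = len(x)
            mean = n1 * (len(pooled) + 1) / 2
            obs = ranks[:n1].sum()
            combos = list(itertools.combinations(range(len(pooled)), n1))
            count = sum(
                abs(ranks[list(c)].sum() - mean) >= abs(obs - mean) - 1e-9
                for c in combos
            )
            assert r.p_value == pytest.approx(count / len(combos), abs=1e-12)

    def test_exact_agrees_with_normal_approximation(self):
        # at n = 10 + 10 the exact and tie-corrected normal p-values
        # agree within 0.02 over 100 seeded draws
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.normal(size=10)
            y = rng.normal(0.5, 1.0, size=10)
            exact = rank_sum_test(x, y).p_value
            approx = stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic").pvalue
            assert abs(exact - approx) < 0.02

    def test_large_groups_use_approximation(self):
        rng = np.random.default_rng(6)
        r = rank_sum_test(rng.normal(size=30), rng.normal(size=30))
        assert "approximation" in r.note


class TestSignedRankAndAnova:
    def test_identical_pairs_degenerate(self):
        r = signed_rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == 1.0 and r.statistic == 0.0

    def test_paired_orphans_listed(self):
        scores = np.array([1.0, 2.0, 3.0])
        labels = np.array(["pre", "day90", "pre"])
        with pytest.raises(ValueError, match="p2"):
            im.compare_groups(scores, labels, "signed_rank",
                              patient_ids=np.array(["p1", "p1", "p2"]))

    def test_identical_groups_anova_flat(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        r = anova_test([g, g.copy()])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0, abs=1e-9)


class TestOrdinalTrend:
    def test_perfect_concordance(self):
        cats = im.types.as_ordered_infiltration(
            ["absent", "mild", "moderate", "severe"]
        )
        assert im.ordinal_trend([1, 2, 3, 4], cats).statistic == pytest.approx(1.0)
        assert im.ordinal_trend([4, 3, 2, 1], cats).statistic == pytest.approx(-1.0)

    def test_tau_b_matches_pair_counting_oracle(self):
        # brute-force concordant/discordant counts with tie normalization
        scores = np.array([1.0, 2.0, 2.0, 3.0, 0.5, 3.0])
        codes = np.array([0, 1, 1, 2, 0, 3])
        conc = disc = 0
        for i, j in itertools.combinations(range(6), 2):
            s = np.sign(scores[i] - scores[j]) * np.sign(codes[i] - codes[j])
            conc += s > 0
            disc += s < 0
        n = 6
        n0 = n * (n - 1) / 2
        t_x = sum(
            c * (c - 1) / 2 for c in pd.Series(scores).value_counts() if c > 1
        )
        t_y = sum(c * (c - 1) / 2 for c in pd.Series(codes).value_counts() if c > 1)
        tau_oracle = (conc - disc) / np.sqrt((n0 - t_x) * (n0 - t_y))
        cats = im.types.as_ordered_infiltration(
            [im.INFILTRATION_LEVELS[c] for c in codes]
        )
        r = im.ordinal_trend(scores, cats)
        assert r.statistic == pytest.approx(tau_oracle, abs=1e-9)


class TestCorrelate:
    def test_perfect_lines(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert im.correlate(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert im.correlate(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_computation_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r_hand = cov / (x.std() * y.std())
        assert im.correlate(x, y).statistic == pytest.approx(r_hand, abs=1e-12)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            im.correlate([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])


class TestQuartileStratify:
    def test_percentile_arithmetic_1_to_8(self):
        # linear-interpolation 75th percentile of 1..8 is 6.25 -> {7, 8} high
        labels = im.quartile_stratify(np.arange(1.0, 9.0))
        assert labels.tolist() == ["low"] * 6 + ["high"] * 2

    def test_all_equal_scores_all_low(self):
        labels = im.quartile_stratify(np.ones(8))
        assert (labels == "low").all()

    def test_single_sample_above_threshold(self):
        labels = im.quartile_stratify(np.array([1.0, 1.0, 1.0, 1.0, 9.0]))
        assert (labels == "high").sum() == 1

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            im.quartile_stratify(np.array([1.0, 2.0, 3.0]))


class TestKMLogrank:
    def test_identical_groups_flat(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        labels = np.array(["A"] * 3 + ["B"] * 3)
        r = km_logrank(t, e, labels)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0, abs=1e-9)

    def test_six_subject_hand_table(self):
        # explicit observed-vs-expected log-rank table, computed in-line
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        obs_a = exp_a = var = 0.0
        for t in sorted(time[event == 1]):
            at_risk = time >= t
            d = ((time == t) & (event == 1)).sum()
            n = at_risk.sum()
            n_a = (at_risk & (labels == "A")).sum()
            obs_a += ((time == t) & (event == 1) & (labels == "A")).sum()
            exp_a += d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        chi2 = (obs_a - exp_a) ** 2 / var
        r = km_logrank(time, event, labels)
        assert r.statistic == pytest.approx(chi2, abs=1e-9)
        assert r.p_value == pytest.approx(1 - stats.chi2.cdf(chi2, 1), abs=1e-9)

    def test_extreme_separation_significant(self):
        time = np.concatenate([np.arange(1, 11), np.arange(20, 30)]).astype(float)
        event = np.ones(20)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        assert km_logrank(time, event, labels).p_value < 0.01

    def test_invariant_to_label_swap(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(5, 30)
        event = rng.integers(0, 2, 30)
        labels = np.array(["A"] * 15 + ["B"] * 15)
        swapped = np.where(labels == "A", "B", "A")
        a = km_logrank(time, event, labels)
        b = km_logrank(time, event, swapped)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_km_equals_empirical_survival_without_censoring(self):
        time = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        event = np.ones(5)
        r = km_logrank(
            np.concatenate([time, [9.0, 9.0]]),
            np.concatenate([event, [1, 1]]),
            np.array(["A"] * 5 + ["B"] * 2),
        )
        curve = r.curves["A"].set_index("time")["survival"]
        for t in [1.0, 2.0, 3.0, 5.0]:
            assert curve.loc[t] == pytest.approx((time > t).mean(), abs=1e-12)

    def test_zero_event_group_flagged(self):
        r = km_logrank(
            np.array([1.0, 2.0, 3.0, 4.0]),
            np.array([1, 1, 0, 0]),
            np.array(["A", "A", "B", "B"]),
        )
        assert not r.reliable


@pytest.fixture(scope="module")
def report(cohort_bundle, signatures):
    cohort, z = cohort_bundle
    return im.run_association_suite(
        z, cohort.annotations, signatures, er_signature=cohort.er_program
    )


class TestAssociationSuite:
    def _rows(self, report, analysis, signature=None):
        m = report["analysis"] == analysis
        if signature:
            m &= report["signature"] == signature
        return report[m]

    def test_er_negative_tumors_more_infiltrated(self, report):
        rows = self._rows(report, "er_status")
        assert len(rows) == 5
        # sorted group order is (ER+, ER-); -1 means ER- scores higher
        assert (rows["direction"] == -1).all()
        assert (rows["p_value"] < 0.05).all()

    def test_er_activity_negatively_correlated(self, report):
        rows = self._rows(report, "er_activity")
        assert (rows["statistic"] < 0).all()
        assert (rows["p_value"] < 0.05).all()

    def test_caai_positive_less_infiltrated(self, report):
        rows = self._rows(report, "caai[all]")
        # sorted group order is (negative, positive); +1 means CAAI- higher
        assert (rows["direction"] == 1).all()
        assert (rows["p_value"] < 0.05).all()

    def test_infiltration_trend_positive(self, report):
        rows = self._rows(report, "infiltration_trend")
        taus = rows[rows["test"] == "kendall_tau_b"]
        assert (taus["statistic"] > 0).all()
        assert (rows["p_value"] < 0.05).all()

    def test_treatment_increases_infiltration(self, report):
        rows = self._rows(report, "treatment")
        assert (rows["direction"] == 1).all()
        assert (rows["p_value"] < 0.05).sum() >= 4  # CTL may be borderline

    def test_survival_benefit_er_negative_only(self, report):
        neg = self._rows(report, "survival[ER-]", "total")
        pos = self._rows(report, "survival[ER+]", "total")
        assert neg["p_value"].iloc[0] < 0.05
        assert neg["direction"].iloc[0] == 1
        assert pos["p_value"].iloc[0] > 0.05

    def test_missing_columns_skip_analysis_not_suite(self, cohort_bundle, signatures):
        cohort, z = cohort_bundle
        ann = cohort.annotations.drop(columns=["caai_status", "survival_time"])
        report = im.run_association_suite(
            z, ann, signatures, er_signature=cohort.er_program
        )
        assert not report["analysis"].str.startswith("caai").any()
        assert not report["analysis"].str.startswith("survival").any()
        assert (report["analysis"] == "er_status").any()
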