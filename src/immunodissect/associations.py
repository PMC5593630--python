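"""The study's statistical suite: group comparisons, ordinal trends,
correlations, quartile-stratified Kaplan-Meier survival, and paired
treatment tests.

Two-group comparisons use the Wilcoxon rank-sum test — exact (full
permutation distribution of the rank sum, ties included) when both
groups have at most 10 samples, normal approximation with tie
correction otherwise. Ordinal trends use Kendall tau-b against the
ranked infiltration categories; correlations are Pearson; paired
comparisons use the Wilcoxon signed-rank test; category-wise score
comparisons use one-way ANOVA. Survival uses the product-limit
estimator and a two-group log-rank test. P-values are reported
unadjusted (per-test reporting at alpha = 0.05); a Bonferroni column
can be requested on the suite report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .types import ExpressionMatrix, ScoreTable
from . import scoring

logger = logging.getLogger(__name__)

EXACT_RANKSUM_MAX = 10


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    direction: int = 0
    note: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class SurvivalResult:
    """Kaplan-Meier curves per group plus the two-group log-rank test."""

    curves: dict[str, pd.DataFrame]  # columns: time, survival, at_risk
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    reliable: bool = True


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p for the rank-sum statistic of x.

    Enumerates the permutation distribution of the (tied) rank sum by
    dynamic programming over doubled midranks, which is exact and
    equivalent to enumerating all C(n1+n2, n1) group assignments.
    """
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(stats.rankdata(pooled) * 2).astype(int)
    n1 = len(x)
    obs = int(ranks2[:n1].sum())
    total = int(ranks2.sum())

    # dp[j, s] = number of size-j subsets of the ranks with doubled sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for j in range(n1 - 1, -1, -1):
            dp[j + 1, r:] += dp[j, : total + 1 - r]
    dist = dp[n1]
    n_subsets = dist.sum()

    mean2 = n1 * (len(pooled) + 1)  # doubled-rank mean of the rank sum
    dev = abs(obs - mean2)
    sums = np.arange(total + 1)
    extreme = np.abs(sums - mean2) >= dev - 1e-9
    return float(dist[extreme].sum() / n_subsets)


def rank_sum_test(x, y) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney), exact for small groups."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be non-empty")
    u_stat = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    if len(x) <= EXACT_RANKSUM_MAX and len(y) <= EXACT_RANKSUM_MAX:
        p = _exact_ranksum_p(x, y)
        note = "exact"
    else:
        p = float(u_stat.pvalue)
        note = "normal approximation, tie-corrected"
    direction = int(np.sign(np.median(x) - np.median(y)))
    return TestResult(
        test="rank_sum",
        statistic=float(u_stat.statistic),
        p_value=p,
        n=(len(x), len(y)),
        direction=direction,
        note=note,
    )


def signed_rank_test(before, after) -> TestResult:
    """Wilcoxon signed-rank on paired vectors (after - before)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if len(before) != len(after):
        raise ValueError("paired vectors must have equal length")
    diffs = after - before
    if np.all(diffs == 0):
        logger.warning("signed-rank: all paired differences are zero; p = 1")
        return TestResult(
            test="signed_rank", statistic=0.0, p_value=1.0,
            n=(len(before),), direction=0, note="degenerate: all differences zero",
        )
    res = stats.wilcoxon(after, before)
    direction = int(np.sign(np.median(diffs)))
    return TestResult(
        test="signed_rank", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=(len(before),), direction=direction,
    )


def anova_test(groups: list[np.ndarray]) -> TestResult:
    if len(groups) < 2:
        raise ValueError("ANOVA needs >=2 groups")
    f, p = stats.f_oneway(*groups)
    return TestResult(
        test="anova", statistic=float(f), p_value=float(p),
        n=tuple(len(g) for g in groups),
    )


def compare_groups(
    scores, labels, test: str, patient_ids=None
) -> TestResult:
    """Dispatch a two-group, paired, or multi-group score comparison.

    ``rank_sum``: exactly two label levels (groups taken in sorted label
    order, direction = sign(median(first) - median(second))).
    ``signed_rank``: two label levels paired by ``patient_ids``; patients
    lacking either member raise an error listing the orphans.
    ``anova``: one-way across all label levels.
    """
    scores = pd.Series(np.asarray(scores, dtype=float))
    labels = pd.Series(np.asarray(labels, dtype=object), index=scores.index)
    levels = sorted(labels.dropna().unique())

    if test == "rank_sum":
        if len(levels) != 2:
            raise ValueError(f"rank_sum needs exactly 2 groups, got {levels}")
        a = scores[labels == levels[0]]
        b = scores[labels == levels[1]]
        r = rank_sum_test(a, b)
        r.note = (r.note + f"; groups {levels[0]} vs {levels[1]}").strip("; ")
        return r
    if test == "signed_rank":
        if patient_ids is None:
            raise ValueError("signed_rank requires patient_ids")
        if len(levels) != 2:
            raise ValueError(f"signed_rank needs exactly 2 timepoints, got {levels}")
        df = pd.DataFrame(
            {"score": scores.values, "label": labels.values,
             "patient": np.asarray(patient_ids, dtype=object)}
        )
        wide = df.pivot_table(index="patient", columns="label", values="score",
                              aggfunc="first")
        orphans = sorted(wide.index[wide.isna().any(axis=1)])
        if orphans:
            raise ValueError(f"unmatched patient(s) in paired test: {orphans[:10]}")
        return signed_rank_test(wide[levels[0]], wide[levels[1]])
    if test == "anova":
        return anova_test([scores[labels == lv].to_numpy() for lv in levels])
    raise ValueError(f"unknown test {test!r}")


def ordinal_trend(scores, ordered_categories) -> TestResult:
    """Kendall tau-b between scores and ranked ordinal categories."""
    mask, codes = scoring._category_ranks(ordered_categories)
    s = np.asarray(scores, dtype=float)
    tau, p = stats.kendalltau(s[mask], codes[mask])
    return TestResult(
        test="kendall_tau_b", statistic=float(tau), p_value=float(p),
        n=(int(mask.sum()),), direction=int(np.sign(tau)) if tau == tau else 0,
    )


def correlate(x_scores, y_scores) -> TestResult:
    """Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x_scores, dtype=float)
    y = np.asarray(y_scores, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with >=3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    r, p = stats.pearsonr(x, y)
    return TestResult(
        test="pearson", statistic=float(r), p_value=float(p),
        n=(len(x),), direction=int(np.sign(r)) if r == r else 0,
    )


def quartile_stratify(scores) -> pd.Series:
    """Label scores strictly above the 75th percentile as high, rest low.

    Uses the linear-interpolation percentile; ties at the threshold go
    to low, so "high" is strictly the upper tail.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 4:
        raise ValueError("quartile stratification needs >=4 samples")
    threshold = float(np.percentile(s.to_numpy(), 75))
    labels = pd.Series(np.where(s > threshold, "high", "low"), index=s.index,
                       name="infiltration_class")
    if (labels == "high").sum() == 0:
        logger.warning("quartile_stratify: no sample above the 75th percentile; all low")
    return labels


def km_logrank(time, event, labels) -> SurvivalResult:
    """Product-limit curves per group and a two-group log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if np.any(time < 0):
        raise ValueError("survival times must be non-negative")
    groups = sorted(pd.unique(labels))
    if len(groups) != 2:
        raise ValueError(f"log-rank implemented for exactly 2 groups, got {groups}")

    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    reliable = True
    for g in groups:
        m = labels == g
        sizes[g] = int(m.sum())
        if event[m].sum() == 0:
            reliable = False
            logger.warning("group %r has zero events; log-rank flagged unreliable", g)
        kmf = KaplanMeierFitter()
        kmf.fit(time[m], event_observed=event[m], label=str(g))
        surv = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": kmf.event_table["at_risk"].reindex(surv.index).to_numpy(dtype=float),
            }
        )

    m0 = labels == groups[0]
    res = logrank_test(time[m0], time[~m0], event_observed_A=event[m0],
                       event_observed_B=event[~m0])
    return SurvivalResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes=sizes,
        reliable=reliable,
    )


#: analyses run by default in the suite, in report order
DEFAULT_ANALYSES: tuple[str, ...] = (
    "infiltration_trend", "er_status", "er_activity", "subtype",
    "caai", "survival", "treatment",
)

LUMINAL = {"luminal A", "luminal B"}
NON_LUMINAL = {"basal", "HER2", "normal-like"}


@dataclass
class SuiteConfig:
    analyses: tuple[str, ...] = DEFAULT_ANALYSES
    alpha: float = 0.05
    bonferroni: bool = False
    signature_columns: tuple[str, ...] = ()  # default: all non-ER score columns
    min_group: int = 3
    min_survival_group: int = 8
    extra: dict = field(default_factory=dict)


def _row(analysis: str, signature: str, r: TestResult, **extra) -> dict:
    d = {
        "analysis": analysis,
        "signature": signature,
        "test": r.test,
        "statistic": r.statistic,
        "p_value": r.p_value,
        "n": "/".join(str(v) for v in r.n),
        "direction": r.direction,
        "note": r.note,
    }
    d.update(extra)
    return d


def run_association_suite(
    z: ExpressionMatrix,
    annotations: pd.DataFrame,
    signatures: dict,
    er_signature=None,
    config: SuiteConfig | None = None,
) -> pd.DataFrame:
    """Run the full battery of association analyses on one cohort.

    Per signature and for the total lymphocyte score: the infiltration-
    category trend (one-way ANOVA + Kendall tau-b), ER-status rank-sum
    and ER-activity Pearson correlation, luminal-vs-non-luminal subtype
    comparison, CAAI comparisons overall and within ER strata,
    upper-quartile Kaplan-Meier / log-rank within ER strata, and the
    paired pre/day-90 signed-rank test. Analyses whose annotation
    columns are absent are skipped with a logged reason.
    """
    config = config or SuiteConfig()
    ann = annotations.set_index("sample_id") if "sample_id" in annotations.columns else annotations
    common = [s for s in z.sample_ids if s in ann.index]
    if not common:
        raise ValueError("no overlap between matrix samples and annotations")
    ann = ann.loc[common]
    zc = z.subset_samples(common)

    table = scoring.score_table(zc, signatures, er_signature=er_signature)
    sig_cols = list(config.signature_columns) or [
        c for c in table.scores.columns if c != "ER"
    ]

    timepoint = ann["timepoint"] if "timepoint" in ann.columns else pd.Series(
        "none", index=ann.index
    )
    cross = timepoint == "none"
    rows: list[dict] = []

    def have(col: str, analysis: str) -> bool:
        if col not in ann.columns:
            logger.info("skipping %s: annotation column %r absent", analysis, col)
            return False
        return True

    for analysis in config.analyses:
        if analysis == "infiltration_trend" and have("infiltration_category", analysis):
            cats = ann.loc[cross, "infiltration_category"]
            if cats.notna().sum() < 4 or cats.dropna().nunique() < 2:
                logger.info("skipping infiltration_trend: <2 category levels")
                continue
            for sig in sig_cols:
                sc = table.scores.loc[cross, sig]
                valid = cats.notna()
                groups = [
                    sc[valid][cats[valid] == lv].to_numpy()
                    for lv in cats.cat.categories
                    if (cats[valid] == lv).sum() >= 1
                ]
                rows.append(_row(analysis, sig, anova_test(groups)))
                rows.append(_row(analysis, sig, ordinal_trend(sc[valid], cats[valid])))

        elif analysis == "er_status" and have("er_status", analysis):
            m = cross & ann["er_status"].isin(["ER+", "ER-"]).reindex(ann.index, fill_value=False)
            if ann.loc[m, "er_status"].nunique() < 2:
                logger.info("skipping er_status: only one ER level present")
                continue
            for sig in sig_cols:
                r = compare_groups(
                    table.scores.loc[m, sig].to_numpy(),
                    ann.loc[m, "er_status"].to_numpy(),
                    "rank_sum",
                )
                rows.append(_row(analysis, sig, r))

        elif analysis == "er_activity":
            if "ER" not in table.scores.columns:
                logger.info("skipping er_activity: no ER signature supplied")
                continue
            er_sc = table.scores.loc[cross, "ER"]
            for sig in sig_cols:
                rows.append(_row(analysis, sig, correlate(table.scores.loc[cross, sig], er_sc)))

        elif analysis == "subtype" and have("subtype", analysis):
            st = ann["subtype"]
            grp = np.where(st.isin(LUMINAL), "luminal",
                           np.where(st.isin(NON_LUMINAL), "non-luminal", None))
            m = cross & pd.Series(grp, index=ann.index).notna()
            sub_labels = pd.Series(grp, index=ann.index)[m]
            if sub_labels.nunique() < 2 or sub_labels.value_counts().min() < config.min_group:
                logger.info("skipping subtype: insufficient group sizes")
                continue
            for sig in sig_cols:
                r = compare_groups(table.scores.loc[m, sig].to_numpy(),
                                   sub_labels.to_numpy(), "rank_sum")
                rows.append(_row(analysis, sig, r))

        elif analysis == "caai" and have("caai_status", analysis):
            strata: list[tuple[str, pd.Series]] = [("all", cross)]
            if "er_status" in ann.columns:
                for er_level in ("ER-", "ER+"):
                    strata.append((er_level, cross & (ann["er_status"] == er_level)))
            for stratum, m_base in strata:
                m = m_base & ann["caai_status"].isin(["positive", "negative"])
                caai = ann.loc[m, "caai_status"]
                if caai.nunique() < 2 or caai.value_counts().min() < config.min_group:
                    logger.info("skipping caai[%s]: insufficient group sizes", stratum)
                    continue
                for sig in sig_cols:
                    r = compare_groups(table.scores.loc[m, sig].to_numpy(),
                                       caai.to_numpy(), "rank_sum")
                    rows.append(_row(f"caai[{stratum}]", sig, r))

        elif analysis == "survival":
            if not ("survival_time" in ann.columns and "event" in ann.columns):
                logger.info("skipping survival: time/event columns absent")
                continue
            strata = [("all", cross)]
            if "er_status" in ann.columns:
                strata = [
                    (lv, cross & (ann["er_status"] == lv)) for lv in ("ER-", "ER+")
                ]
            for stratum, m_base in strata:
                m = m_base & ann["survival_time"].notna() & ann["event"].notna()
                if m.sum() < config.min_survival_group:
                    logger.info("skipping survival[%s]: too few samples", stratum)
                    continue
                for sig in sig_cols:
                    sc = table.scores.loc[m, sig]
                    labels = quartile_stratify(sc)
                    if labels.nunique() < 2:
                        logger.info("skipping survival[%s] %s: degenerate quartiles",
                                    stratum, sig)
                        continue
                    sr = km_logrank(ann.loc[m, "survival_time"], ann.loc[m, "event"],
                                    labels)
                    ev = ann.loc[m, "event"]
                    high_rate = ev[labels == "high"].mean()
                    low_rate = ev[labels == "low"].mean()
                    # +1 = high-infiltration group has the lower event rate
                    rows.append({
                        "analysis": f"survival[{stratum}]",
                        "signature": sig,
                        "test": "logrank",
                        "statistic": sr.statistic,
                        "p_value": sr.p_value,
                        "n": f"{sr.group_sizes.get('high', 0)}/{sr.group_sizes.get('low', 0)}",
                        "direction": int(np.sign(low_rate - high_rate)),
                        "note": "" if sr.reliable else "unreliable: a group has zero events",
                    })

        elif analysis == "treatment":
            if "timepoint" not in ann.columns or "patient_id" not in ann.columns:
                logger.info("skipping treatment: timepoint/patient_id absent")
                continue
            m = timepoint.isin(["pre", "day90"])
            if m.sum() < 4:
                logger.info("skipping treatment: too few paired samples")
                continue
            for sig in sig_cols:
                r = compare_groups(
                    table.scores.loc[m, sig].to_numpy(),
                    timepoint[m].to_numpy(),
                    "signed_rank",
                    patient_ids=ann.loc[m, "patient_id"].to_numpy(),
                )
                # sorted label order is (day90, pre); flip so + means increase
                r.direction = -r.direction
                rows.append(_row(analysis, sig, r))

        elif analysis not in DEFAULT_ANALYSES:
            raise ValueError(f"unknown analysis {analysis!r}")

    report = pd.DataFrame(rows)
    if config.bonferroni and len(report):
        report["p_adjusted"] = np.minimum(report["p_value"] * len(report), 1.0)
    return report
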