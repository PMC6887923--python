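"""Two-group cohort comparison producing a Table-2-style report.

Continuous metrics are compared with an independent-samples t-test
(pooled by default, Welch available) or a Mann-Whitney U-test; binary
completeness metrics with a Pearson chi-square on the 2x2 table (no
continuity correction by default, Fisher's exact available).  The
default metric-to-test map sends scar burden to Mann-Whitney, widths to
the t-test and completeness to chi-square; it is configurable because
real analyses choose per-variable based on normality.  All p-values are
two-sided; significance is flagged at 0.05.

The statistical engines are scipy.stats; this module fixes the variants,
conventions (e.g. p = 1 for two identical zero-variance samples) and the
report schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

CONTINUOUS_METRICS = ("burden_percent", "width_total", "width_left", "width_right")
BINARY_METRICS = ("complete_bilateral", "complete_left", "complete_right")
DEFAULT_TEST_MAP = {
    "burden_percent": "mann_whitney",
    "width_total": "t_test",
    "width_left": "t_test",
    "width_right": "t_test",
    "complete_bilateral": "chi_square",
    "complete_left": "chi_square",
    "complete_right": "chi_square",
}


@dataclass
class CohortRecord:
    """One subject's measured metrics."""

    subject_id: str
    group: str
    burden_percent: float
    width_total: float
    width_left: float
    width_right: float
    complete_left: bool
    complete_right: bool
    complete_bilateral: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.burden_percent <= 100.0):
            raise ValueError("burden_percent must lie in [0, 100]")
        if min(self.width_total, self.width_left, self.width_right) < 0:
            raise ValueError("widths must be non-negative")


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def t_test_independent(sample_a=None, sample_b=None, *, variant: str = "pooled",
                       summary_a=None, summary_b=None) -> TTestResult:
    """Two-sided independent-samples t-test, raw or summary form.

    Summary form takes ``(mean, sd, n)`` per group and is algebraically
    identical to the raw form on data with matching summaries.  Two
    zero-variance samples with equal means give t = 0, p = 1 by
    convention; zero variance with unequal means is undefined and raises.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if summary_a is not None or summary_b is not None:
        m1, s1, n1 = summary_a
        m2, s2, n2 = summary_b
    else:
        a = np.asarray(sample_a, dtype=float)
        b = np.asarray(sample_b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs n >= 2")
        m1, s1, n1 = a.mean(), a.std(ddof=1), len(a)
        m2, s2, n2 = b.mean(), b.std(ddof=1), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            df = n1 + n2 - 2 if variant == "pooled" else float(min(n1, n2) - 1)
            return TTestResult(0.0, float(df), 1.0)
        raise ValueError("t statistic undefined: zero variance, unequal means")
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                     equal_var=(variant == "pooled"))
    return TTestResult(float(res.statistic), float(df), float(res.pvalue))


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample).

    Exact null distribution when the combined sample is small (n <= 20)
    and tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs n >= 1")
    combined = np.concatenate([a, b])
    if len(np.unique(combined)) == 1:
        # every observation tied: no evidence either way
        return len(a) * len(b) / 2.0, 1.0
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (not ties and len(combined) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table, continuity_correction: bool = False
                   ) -> tuple[float, float]:
    """Pearson chi-square with 1 df on a 2x2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total; use Fisher's exact test instead")
    res = stats.chi2_contingency(t, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> tuple[float, float]:
    res = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

@dataclass
class MetricComparison:
    metric: str
    group1: str
    group2: str
    group1_summary: str
    group2_summary: str
    test: str
    statistic: float
    p_value: float
    significant: bool


@dataclass
class GroupComparison:
    """Table-2-style report: one row per metric."""

    group1: str
    group2: str
    n1: int
    n2: int
    rows: list[MetricComparison] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([asdict(r) for r in records])
    required = ["subject_id", "group", *CONTINUOUS_METRICS, *BINARY_METRICS]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"records missing column '{col}'")
        bad = df.loc[df[col].isna(), "subject_id"].tolist()
        if bad:
            raise ValueError(f"metric '{col}' missing for subjects {bad}")
    return df


def compare_cohorts(records, test_map: dict | None = None,
                    t_variant: str = "pooled", alpha: float = 0.05,
                    continuity_correction: bool = False) -> GroupComparison:
    """Compare the two groups metric by metric.

    ``records`` is a list of :class:`CohortRecord` (or an equivalent
    DataFrame).  Exactly two group labels must be present; the first
    label in order of appearance is reported first.
    """
    df = _records_frame(records)
    groups = list(dict.fromkeys(df["group"]))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {groups}")
    g1, g2 = groups
    d1, d2 = df[df["group"] == g1], df[df["group"] == g2]
    tmap = dict(DEFAULT_TEST_MAP)
    if test_map:
        tmap.update(test_map)
    report = GroupComparison(g1, g2, len(d1), len(d2))

    for metric in CONTINUOUS_METRICS:
        a, b = d1[metric].to_numpy(float), d2[metric].to_numpy(float)
        test = tmap[metric]
        if test == "t_test":
            r = t_test_independent(a, b, variant=t_variant)
            stat, p = r.t, r.p
            name = f"t_test_{t_variant}"
        elif test == "mann_whitney":
            stat, p = mann_whitney_u(a, b)
            name = "mann_whitney"
        else:
            raise ValueError(f"unknown test '{test}' for metric '{metric}'")
        report.rows.append(MetricComparison(
            metric, g1, g2,
            f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
            f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
            name, stat, p, p < alpha))

    for metric in BINARY_METRICS:
        a, b = d1[metric].astype(bool), d2[metric].astype(bool)
        k1, k2 = int(a.sum()), int(b.sum())
        table = [[k1, len(a) - k1], [k2, len(b) - k2]]
        if tmap[metric] == "fisher_exact":
            stat, p = fisher_exact_2x2(table)
            name = "fisher_exact"
        else:
            try:
                stat, p = chi_square_2x2(table, continuity_correction)
                name = "chi_square"
            except ValueError:
                stat, p = fisher_exact_2x2(table)
                name = "fisher_exact"
        report.rows.append(MetricComparison(
            metric, g1, g2,
            f"{k1} ({100 * k1 / len(a):.0f}%)",
            f"{k2} ({100 * k2 / len(b):.0f}%)",
            name, stat, p, p < alpha))
    return report
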