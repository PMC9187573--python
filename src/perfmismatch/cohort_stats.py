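"""Two-arm group statistics and the summary comparison table.

Imaging features are compared between treatment arms the way small
two-arm trials report them: parameter *levels* at each timepoint with
the two-sample Wilcoxon rank-sum (Mann-Whitney) test, baseline-to-
follow-up *changes* with the equal-variance two-sample t-test, and
categorical outcomes (recanalization, clinical improvement) with
Fisher's exact test.  All tests are two-sided at alpha 0.05 and, by
default, deliberately uncorrected for multiplicity (exploratory
analysis); a Holm adjustment is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "rank_sum_test",
    "t_test_two_sample",
    "t_test_from_summary",
    "fisher_exact_2x2",
    "clinical_improvement",
    "build_group_table",
    "delta_t_test_power",
]

TestName = Literal["rank_sum", "t_equal_var", "fisher"]


@dataclass
class GroupComparison:
    """Result of one between-arm comparison."""

    variable: str
    test: TestName
    statistic: float
    p: float
    mean_x: float = float("nan")
    sd_x: float = float("nan")
    n_x: int = 0
    mean_y: float = float("nan")
    sd_y: float = float("nan")
    n_y: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _summaries(x: np.ndarray, y: np.ndarray) -> dict:
    return dict(
        mean_x=float(np.mean(x)),
        sd_x=float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
        n_x=len(x),
        mean_y=float(np.mean(y)),
        sd_y=float(np.std(y, ddof=1)) if len(y) > 1 else float("nan"),
        n_y=len(y),
    )


def rank_sum_test(x: Sequence[float], y: Sequence[float], variable: str = "") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Small samples (n_x + n_y <= 16) without ties use the exact null
    distribution (full enumeration); otherwise the normal approximation
    with tie and continuity correction.  Fully tied data (zero rank
    variance) carry no evidence: p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 16 and not has_ties) else "asymptotic"
    if np.ptp(np.concatenate([x, y])) == 0:
        u = len(x) * len(y) / 2.0
        return GroupComparison(variable, "rank_sum", u, 1.0, **_summaries(x, y))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    if not np.isfinite(p):  # degenerate tie structure
        p = 1.0
    return GroupComparison(variable, "rank_sum", float(res.statistic), p, **_summaries(x, y))


def t_test_two_sample(x: Sequence[float], y: Sequence[float], variable: str = "") -> GroupComparison:
    """Two-sided pooled-variance (equal-variance) two-sample t-test."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    s = _summaries(x, y)
    if _pooled_sd(s["sd_x"], s["n_x"], s["sd_y"], s["n_y"]) == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=True)
    return GroupComparison(variable, "t_equal_var", float(res.statistic), float(res.pvalue), **s)


def _pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    return float(np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)))


def t_test_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, variable: str = ""
) -> GroupComparison:
    """Pooled t-test from printed summary statistics (mean, SD, n).

    Identical formula to :func:`t_test_two_sample`, enabling
    recomputation of published comparisons from tabulated summaries.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    res = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return GroupComparison(
        variable,
        "t_equal_var",
        float(res.statistic),
        float(res.pvalue),
        mean_x=m1,
        sd_x=sd1,
        n_x=n1,
        mean_y=m2,
        sd_y=sd2,
        n_y=n2,
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]], variable: str = "") -> GroupComparison:
    """Fisher's exact test on a 2x2 contingency table.

    Two-sided p by the standard convention: the sum of hypergeometric
    probabilities of all tables (at fixed margins) no more probable
    than the observed one.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return GroupComparison(variable, "fisher", float(odds), float(p))


def clinical_improvement(nihss_baseline: int, nihss_3h: int) -> bool:
    """Early clinical response: NIHSS improvement by >= 4 points."""
    for v in (nihss_baseline, nihss_3h):
        if not 0 <= v <= 42:
            raise ValueError(f"NIHSS {v} outside [0, 42]")
    return nihss_baseline - nihss_3h >= 4


DEFAULT_ROIS = ("core", "penumbra", "unaffected")
DEFAULT_PARAMS = ("rcbf", "rcbv", "rmtt", "adc")


def default_test_plan(
    rois: Sequence[str] = DEFAULT_ROIS, params: Sequence[str] = DEFAULT_PARAMS
) -> dict[str, TestName]:
    """Variable -> test assignment for the summary table.

    Levels (baseline, follow-up) get the rank-sum test; changes
    (deltas) the equal-variance t-test.
    """
    plan: dict[str, TestName] = {}
    for roi in rois:
        for p in params:
            plan[f"{roi}_{p}_baseline"] = "rank_sum"
            plan[f"{roi}_{p}_followup"] = "rank_sum"
            plan[f"{roi}_{p}_delta"] = "t_equal_var"
    return plan


def build_group_table(
    cohort: pd.DataFrame,
    test_plan: dict[str, TestName] | None = None,
    arm_column: str = "arm",
    arms: tuple[str, str] = ("theophylline", "control"),
    holm: bool = False,
) -> pd.DataFrame:
    """Between-arm comparison of every planned variable.

    Returns a tidy DataFrame (one row per variable) with group means,
    SDs, ns, the test used, its statistic and two-sided p.  The output
    carries ``multiplicity_adjusted`` metadata: False by default
    (uncorrected exploratory alpha 0.05), True when Holm is requested.
    """
    plan = test_plan if test_plan is not None else default_test_plan()
    missing = [v for v in plan if v not in cohort.columns]
    if missing:
        raise KeyError(f"unknown variables in test plan: {missing}")
    gx = cohort[cohort[arm_column] == arms[0]]
    gy = cohort[cohort[arm_column] == arms[1]]
    rows = []
    for var, test in plan.items():
        x = gx[var].dropna().to_numpy()
        y = gy[var].dropna().to_numpy()
        if test == "rank_sum":
            comp = rank_sum_test(x, y, var)
        elif test == "t_equal_var":
            comp = t_test_two_sample(x, y, var)
        else:
            raise ValueError(f"test {test!r} not applicable to continuous variable {var!r}")
        rows.append(vars(comp))
    out = pd.DataFrame(rows)
    if holm:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_holm"] = adj
    out.attrs["multiplicity_adjusted"] = holm
    out.attrs["alpha"] = 0.05
    return out


def delta_t_test_power(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, alpha: float = 0.05
) -> float:
    """Analytic power of the pooled t-test at given group summaries.

    Noncentral-t formulation: with pooled SD s_p and noncentrality
    ncp = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2)), power is the
    probability that |T| exceeds the two-sided critical value under
    the noncentral distribution with n1 + n2 - 2 df.
    """
    df = n1 + n2 - 2
    sp = _pooled_sd(sd1, n1, sd2, n2)
    ncp = (m1 - m2) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
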