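"""Group-level inferential statistics, from raw samples or printed summaries.

Summary-statistics mode reproduces published one-way ANOVAs and independent
t tests from nothing but per-group means, dispersions and sample sizes —
useful when the underlying data are unavailable. Raw mode is algebraically
identical (the ANOVA decomposition depends on the data only through the
per-group mean, SD and n).

A caution on published dispersions: tables sometimes label standard
deviations as "SE". Both functions take the numbers at face value as SDs;
callers reading a summary table must decide which the printed values are.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TTestResult",
    "summarize",
    "anova_from_summary",
    "anova_raw",
    "ttest_from_summary",
    "bonferroni_posthoc",
]


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_p2: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d: float  # Cohen's d with pooled SD


def summarize(samples: np.ndarray | list[float], label: str = "") -> GroupSummary:
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples per group")
    return GroupSummary(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size), label=label)


def anova_from_summary(groups: list[GroupSummary]) -> AnovaResult:
    """One-way fixed-effects ANOVA from per-group (mean, sd, n).

    SSB = sum n_i (m_i - grand)^2 with the n-weighted grand mean;
    SSW = sum (n_i - 1) sd_i^2; eta_p2 = SSB / (SSB + SSW).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    grand = float((ns * means).sum() / ns.sum())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1 = len(groups) - 1
    df2 = int(ns.sum()) - len(groups)
    if ssw == 0:
        F = np.inf if ssb > 0 else 0.0
    else:
        F = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    eta = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    return AnovaResult(F=float(F), df_between=df1, df_within=df2, p=p, eta_p2=float(eta))


def anova_raw(samples_per_group: list[np.ndarray | list[float]]) -> AnovaResult:
    """One-way ANOVA on raw samples; identical to summary mode by identity."""
    return anova_from_summary([summarize(g) for g in samples_per_group])


def ttest_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> TTestResult:
    """Pooled-variance (Student) two-sample t with Cohen's d."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = m1 - m2
    if pooled_var == 0:
        if diff != 0:
            t = np.inf if diff > 0 else -np.inf
            return TTestResult(t=float(t), df=df, p=0.0, d=float(t))
        return TTestResult(t=0.0, df=df, p=1.0, d=0.0)
    pooled_sd = np.sqrt(pooled_var)
    t = diff / (pooled_sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p, d=float(diff / pooled_sd))


def bonferroni_posthoc(groups: list[GroupSummary], alpha: float = 0.05) -> list[dict]:
    """All pairwise pooled t tests, Bonferroni-adjusted.

    Adjusted p = min(1, raw p x number of pairs). Returns one record per
    pair with labels, t, df, d, raw and adjusted p, and significance at
    ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("post hoc comparisons need at least 2 groups")
    pairs = list(combinations(range(len(groups)), 2))
    out = []
    for a, b in pairs:
        g1, g2 = groups[a], groups[b]
        res = ttest_from_summary(g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n)
        p_adj = min(1.0, res.p * len(pairs))
        out.append(
            {
                "group_1": g1.label or str(a),
                "group_2": g2.label or str(b),
                "t": res.t,
                "df": res.df,
                "d": res.d,
                "p_raw": res.p,
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return out
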