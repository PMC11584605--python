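"""Group summaries, grader aggregation and thin ANOVA/Tukey wrappers.

Groups are reported as mean with t-based 95 % confidence intervals
(degenerate point interval at n = 1). Semi-quantitative histopathology
scores (Krenn, OARSI CDS) are aggregated as the plain average over blinded
graders — the rubric content itself is human judgment and stays out of
scope. ANOVA (one- to three-way) and Tukey post-hoc tests delegate to
statsmodels; re-implementing routine statistics would add nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "summarize",
    "aggregate_graders",
    "run_anova",
    "tukey_posthoc",
    "significance_stars",
]


@dataclass
class GroupSummary:
    mean: float
    ci95_low: float
    ci95_high: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.ci95_low <= self.mean <= self.ci95_high:
            raise ValueError("CI must bracket the mean")


def summarize(values, confidence: float = 0.95, label: str = "") -> GroupSummary:
    """Mean with a t-based confidence interval; a single value gets a
    degenerate point interval."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    mean = float(arr.mean())
    if arr.size == 1:
        return GroupSummary(mean=mean, ci95_low=mean, ci95_high=mean, n=1, label=label)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, arr.size - 1))
    half = tcrit * se
    return GroupSummary(
        mean=mean, ci95_low=mean - half, ci95_high=mean + half,
        n=int(arr.size), label=label,
    )


def aggregate_graders(scores) -> float:
    """Arithmetic mean over blinded graders' scores."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("no grader scores")
    return float(arr.mean())


def run_anova(table: pd.DataFrame, response: str, factors: list[str]) -> pd.DataFrame:
    """One- to three-way ANOVA over a long-format table (statsmodels OLS).

    Factors are treated as categorical and crossed with interactions.
    Returns the standard ANOVA table (sum_sq, df, F, PR(>F)) with one row
    per effect.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if not 1 <= len(factors) <= 3:
        raise ValueError("1 to 3 factors supported")
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"factor {f!r} not in table")
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    if response not in table.columns:
        raise ValueError(f"response {response!r} not in table")
    df = table.rename(columns={response: "_y"})
    formula = "_y ~ " + " * ".join(f"C({f})" for f in factors)
    model = ols(formula, data=df).fit()
    return sm.stats.anova_lm(model, typ=2)


def tukey_posthoc(table: pd.DataFrame, response: str, factor: str,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for one factor (statsmodels)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if table[factor].nunique() < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    res = pairwise_tukeyhsd(table[response], table[factor], alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return frame


def significance_stars(p: float) -> str:
    """Report-style stars at the 0.05 / 0.01 / 0.001 / 0.0001 thresholds."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
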