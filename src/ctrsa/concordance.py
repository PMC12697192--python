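"""Planned-vs-actual implant size agreement with exact binomial CIs.

The accuracy of a preoperative 3D planning tool is summarised as the
proportion of cases where the planned implant matched the one actually
used, with a Clopper–Pearson (exact binomial) 95% confidence interval.
Three categories are reported: cup size match, stem size match, and
exact stem match (size and variant — standard, varus, or high-offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .precision import round_half_up

__all__ = ["ConcordanceResult", "clopper_pearson", "plan_vs_actual"]


@dataclass(frozen=True)
class ConcordanceResult:
    """An agreement proportion with its exact 95% confidence interval.

    Percentages are exact (unrounded); use :meth:`rounded` for the
    integer-percent presentation used in clinical reports.
    """

    category: str
    k: int
    n: int
    proportion_pct: float
    ci_low_pct: float
    ci_high_pct: float
    level: float = 0.95

    def rounded(self) -> tuple[int, int, int]:
        """(proportion, ci_low, ci_high) as half-up integer percents."""
        return (
            int(round_half_up(self.proportion_pct)),
            int(round_half_up(self.ci_low_pct)),
            int(round_half_up(self.ci_high_pct)),
        )

    def as_dict(self) -> dict:
        return {
            "category": self.category, "k": self.k, "n": self.n,
            "proportion_pct": self.proportion_pct,
            "ci_low_pct": self.ci_low_pct, "ci_high_pct": self.ci_high_pct,
            "level": self.level,
        }


def clopper_pearson(k: int, n: int, level: float = 0.95, category: str = "") -> ConcordanceResult:
    """Exact (Clopper–Pearson) binomial confidence interval.

    The bounds come from beta-distribution quantiles: with alpha = 1 -
    level, the lower bound is the alpha/2 quantile of Beta(k, n - k + 1)
    (zero when k = 0) and the upper bound the 1 - alpha/2 quantile of
    Beta(k + 1, n - k) (one when k = n). Equivalently the bounds solve
    the binomial tail equations P(X >= k | p_low) = alpha/2 and
    P(X <= k | p_high) = alpha/2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return ConcordanceResult(
        category=category, k=int(k), n=int(n),
        proportion_pct=100.0 * k / n,
        ci_low_pct=100.0 * low, ci_high_pct=100.0 * high,
        level=level,
    )


def plan_vs_actual(plan_table: pd.DataFrame, level: float = 0.95) -> list[ConcordanceResult]:
    """Agreement between planned and used implants.

    `plan_table` is tidy with columns (subject, component, planned_size,
    planned_variant, used_size, used_variant), one cup and one stem row
    per subject. Returns three categories: cup size match, stem size
    match, and exact stem match (size and variant).
    """
    required = {"subject", "component", "planned_size", "used_size"}
    if not required <= set(plan_table.columns):
        raise ValueError(f"plan table missing columns {required - set(plan_table.columns)}")
    results = []
    for component in ("cup", "stem"):
        sub = plan_table[plan_table["component"] == component]
        if sub.empty:
            raise ValueError(f"no {component} rows in plan table")
        if sub["subject"].duplicated().any():
            raise ValueError(f"duplicate {component} rows for a subject")
        size_match = (sub["planned_size"] == sub["used_size"]).to_numpy()
        results.append(
            clopper_pearson(
                int(size_match.sum()), len(sub), level, category=f"{component}_size"
            )
        )
        if component == "stem":
            variant_match = (sub["planned_variant"] == sub["used_variant"]).to_numpy()
            exact = size_match & variant_match
            results.append(
                clopper_pearson(int(exact.sum()), len(sub), level, category="stem_exact")
            )
    return results
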