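"""Double-examination precision, Bland–Altman agreement, and
least-square-means method comparisons.

Precision of an RSA-type system is estimated from double examinations:
two scans of the same patient at one visit with repositioning in
between. Under the no-true-motion assumption their signed difference is
pure measurement error, and the precision for each DOF is

    precision = SD(differences) * t_crit

with t_crit the two-sided Student-t critical value at the 5% level and
degrees of freedom determined by the number of double-exam pairs
(df = n - 1 by default; df = n available as an option since conventions
differ between labs).

Agreement between two measurement methods uses Bland–Altman limits of
agreement (bias ± 1.96 SD of the paired differences, each follow-up of
each patient contributing one comparison) and, model-based, least-square
means per timepoint from a repeated-measures mixed model with method,
timepoint and their interaction as fixed effects and subject as a
random effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _mixed

__all__ = [
    "PrecisionRow",
    "BAResult",
    "double_exam_diffs",
    "precision_table",
    "precision_from_sd",
    "bland_altman_pairs",
    "plot_bland_altman",
    "bland_altman",
    "lsmeans_by_timepoint",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal round-half-up (0.5 -> 1), matching how printed clinical
    tables are rounded; applied only at report time."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrecisionRow:
    """Per-DOF double-examination summary."""

    segment: str
    dof: str
    n_pairs: int
    mean_diff: float
    sd_diff: float
    df: int
    t_crit: float
    precision: float


@dataclass(frozen=True)
class BAResult:
    """Bland–Altman bias and limits of agreement for one DOF."""

    dof: str
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_comparisons: int


def double_exam_diffs(table: pd.DataFrame) -> pd.DataFrame:
    """Signed per-subject differences between double examinations.

    `table` is a tidy migration table (columns subject, segment, dof,
    timepoint_months, replicate, value) restricted or restrictable to
    the duplicated visit. Returns one row per (subject, segment, dof)
    with the difference replicate 2 - replicate 1.

    Raises if any subject does not have exactly two replicates.
    """
    reps = sorted(table["replicate"].unique())
    if reps != [1, 2]:
        raise ValueError(f"expected replicates [1, 2] at the double-exam visit, got {reps}")
    keys = ["subject", "segment", "dof"]
    extra = [c for c in ("method", "timepoint_months", "side") if c in table.columns]
    wide = table.pivot_table(
        index=keys + extra, columns="replicate", values="value", aggfunc="first"
    )
    if wide[[1, 2]].isna().any().any():
        missing = wide[wide[[1, 2]].isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing replicate for {missing[:5]}")
    out = wide.reset_index()
    out["diff"] = out[2] - out[1]
    return out.drop(columns=[1, 2])


def precision_table(
    diffs: pd.DataFrame,
    alpha: float = 0.05,
    df_rule: str = "n-1",
) -> list[PrecisionRow]:
    """Precision per segment and DOF from double-exam differences.

    `diffs` is the output of :func:`double_exam_diffs` (or any frame
    with segment, dof, diff columns). Precision is the SD of the
    differences times the two-sided t critical value at level `alpha`
    with df = n-1 (or df = n under the alternative convention).
    """
    if df_rule not in ("n-1", "n"):
        raise ValueError(f"unknown df rule {df_rule!r}")
    rows = []
    for (segment, dof), grp in diffs.groupby(["segment", "dof"], sort=False):
        d = grp["diff"].to_numpy(dtype=float)
        n = len(d)
        if n < 2:
            raise ValueError(f"need >= 2 double-exam pairs for {segment}/{dof}, got {n}")
        df = n - 1 if df_rule == "n-1" else n
        t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
        sd = float(np.std(d, ddof=1))
        rows.append(
            PrecisionRow(
                segment=segment, dof=dof, n_pairs=n,
                mean_diff=float(np.mean(d)), sd_diff=sd,
                df=df, t_crit=t_crit, precision=sd * t_crit,
            )
        )
    return rows


def precision_from_sd(sd: float, n_pairs: int, alpha: float = 0.05, df_rule: str = "n-1") -> float:
    """Precision from an already-summarised SD of double-exam
    differences (as printed in a results table)."""
    if n_pairs < 2:
        raise ValueError("need >= 2 pairs")
    if sd < 0:
        raise ValueError("negative SD")
    df = n_pairs - 1 if df_rule == "n-1" else n_pairs
    return float(sd * stats.t.ppf(1.0 - alpha / 2.0, df))


def bland_altman(table: pd.DataFrame, method_a: str, method_b: str) -> dict[str, BAResult]:
    """Bland–Altman agreement between two methods, per DOF.

    `table` is a tidy migration table containing both methods
    (replicate-1 follow-ups). Records are paired by (subject, segment,
    dof, timepoint); every follow-up timepoint of every subject
    contributes one comparison. The difference is method_a - method_b.

    Returns a dict keyed by "segment/dof"; each value carries the bias
    (mean difference), the SD of the differences, and the 1.96-SD limits
    of agreement. The plot-ready (average, difference) pairs are
    available via :func:`bland_altman_pairs`.
    """
    pairs = bland_altman_pairs(table, method_a, method_b)
    out: dict[str, BAResult] = {}
    for (segment, dof), grp in pairs.groupby(["segment", "dof"], sort=False):
        d = grp["difference"].to_numpy(dtype=float)
        bias = float(np.mean(d))
        sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
        out[f"{segment}/{dof}"] = BAResult(
            dof=dof, bias=bias, sd_diff=sd,
            loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
            n_comparisons=len(d),
        )
    return out


def bland_altman_pairs(table: pd.DataFrame, method_a: str, method_b: str) -> pd.DataFrame:
    """Paired (average, difference) records feeding a Bland–Altman plot."""
    sub = table[(table.get("replicate", 1) == 1) & (table["timepoint_months"] > 0)]
    keys = ["subject", "segment", "dof", "timepoint_months"]
    wide = sub.pivot_table(index=keys, columns="method", values="value", aggfunc="first")
    for m in (method_a, method_b):
        if m not in wide.columns:
            raise ValueError(f"method {m!r} absent from table")
    wide = wide.dropna(subset=[method_a, method_b])
    if wide.empty:
        raise ValueError("no paired records between the two methods")
    out = wide.reset_index()
    out["average"] = (out[method_a] + out[method_b]) / 2.0
    out["difference"] = out[method_a] - out[method_b]
    return out[keys + ["average", "difference"]]


def plot_bland_altman(ba: BAResult, pairs: pd.DataFrame, path) -> None:
    """Render one Bland–Altman panel (scatter of average vs difference
    with bias and limit-of-agreement lines) to `path`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pairs["average"], pairs["difference"], s=18, alpha=0.8)
    ax.axhline(ba.bias, color="red", label=f"bias {ba.bias:.2f}")
    for v in (ba.loa_low, ba.loa_high):
        ax.axhline(v, color="green", linestyle=":")
    ax.set_xlabel("average of methods")
    ax.set_ylabel("difference between methods")
    ax.set_title(ba.dof)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def lsmeans_by_timepoint(
    table: pd.DataFrame,
    timepoints: tuple[float, ...] = (3.0, 12.0, 24.0),
    level: float = 0.95,
) -> pd.DataFrame:
    """Least-square means per method and timepoint, and their difference.

    Fits a repeated-measures mixed model value ~ method * timepoint with
    a random subject intercept (REML), on the subjects measured with
    both methods, and returns the model-based (least-square) mean per
    method and timepoint plus the between-method difference with a
    Wald confidence interval at `level`.
    """
    import statsmodels.formula.api as smf

    methods = sorted(table["method"].unique())
    if len(methods) < 2:
        raise ValueError("least-square means need both methods in the table")
    sub = table[
        (table["timepoint_months"].isin(timepoints)) & (table.get("replicate", 1) == 1)
    ].copy()
    sub["timepoint_months"] = sub["timepoint_months"].astype(float)

    model = smf.mixedlm(
        "value ~ C(method) * C(timepoint_months)", data=sub, groups=sub["subject"]
    )
    fit = _mixed.fit_mixedlm_reml(model)
    design_info = model.data.design_info
    import patsy

    z = stats.norm.ppf(0.5 + level / 2.0)
    fe = fit.fe_params.to_numpy()
    cov = _mixed.fixed_effects_covariance(
        fit,
        np.asarray(model.exog),
        np.ones((len(sub), 1)),
        sub["subject"].to_numpy(),
    )

    rows = []
    for t in timepoints:
        X = {}
        for m in methods:
            (row,) = patsy.build_design_matrices(
                [design_info], {"method": [m], "timepoint_months": [float(t)]}
            )
            X[m] = np.asarray(row)[0]
            est = float(X[m] @ fe)
            se = float(np.sqrt(X[m] @ cov @ X[m]))
            rows.append(
                {
                    "timepoint_months": t, "method": m, "quantity": "lsmean",
                    "estimate": est, "ci_low": est - z * se, "ci_high": est + z * se,
                }
            )
        c = X[methods[0]] - X[methods[1]]
        est = float(c @ fe)
        se = float(np.sqrt(c @ cov @ c))
        rows.append(
            {
                "timepoint_months": t,
                "method": f"{methods[0]}-{methods[1]}",
                "quantity": "difference",
                "estimate": est, "ci_low": est - z * se, "ci_high": est + z * se,
            }
        )
    return pd.DataFrame(rows)
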