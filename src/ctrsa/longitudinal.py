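"""Piecewise linear mixed-effects model of migration over time.

Implant migration after THA typically settles fast during the first
months and then plateaus. The model captures this with two fixed-effect
time covariates — time since surgery t, and a hinge term max(0, t - b)
that switches on after the breakpoint b (3 months by default) — so that
the mean trajectory is continuous and piecewise linear:

    value_ij = beta0 + beta1 * t_ij + beta2 * max(0, t_ij - b) + u_i + e_ij

with a random intercept u_i per subject. The slope before the
breakpoint is beta1; after the breakpoint it is beta1 + beta2.
Estimation is by REML; Wald tests for the two slopes use a Student-t
reference with within-subject residual degrees of freedom
(n_obs - n_subjects - 2), a standard within-between approximation.

The subject random intercept has a physical reading here: every
follow-up migration is measured against the same baseline examination,
so the baseline's measurement error is shared by all of a subject's
follow-ups and appears as a subject-level offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _mixed

__all__ = ["PiecewiseFit", "build_design", "fit_piecewise_lme"]


@dataclass(frozen=True)
class PiecewiseFit:
    """REML fit of the piecewise linear mixed model for one DOF."""

    dof: str
    breakpoint_months: float
    beta0: float
    beta1: float  # slope before the breakpoint (units/month)
    beta2: float  # slope increment after the breakpoint
    se_beta1: float
    se_beta2: float
    se_slope_late: float
    p_early: float
    p_late: float
    ci_beta1: tuple[float, float]
    ci_slope_late: tuple[float, float]
    subject_variance: float
    residual_variance: float
    n_subjects: int
    n_obs: int
    df_resid: int
    converged: bool

    @property
    def slope_late(self) -> float:
        return self.beta1 + self.beta2

    def predict(self, timepoints) -> np.ndarray:
        """Fitted mean trajectory at the given timepoints (months)."""
        t, hinge = build_design(timepoints, self.breakpoint_months)
        return self.beta0 + self.beta1 * t + self.beta2 * hinge


def build_design(timepoints, breakpoint_months: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect time covariates (t, hinge) of the piecewise model.

    t is time since surgery in months; hinge = max(0, t - breakpoint) is
    time since the breakpoint, zero before it.
    """
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    return t, np.maximum(0.0, t - breakpoint_months)


def fit_piecewise_lme(
    table: pd.DataFrame,
    dof: str,
    breakpoint_months: float = 3.0,
    random_slopes: bool = False,
    level: float = 0.95,
    add_baseline_zeros: bool = True,
) -> PiecewiseFit:
    """Fit the piecewise linear mixed model for one DOF.

    `table` is a tidy migration table (subject, dof, timepoint_months,
    value; replicate-1 rows are used). Time runs from surgery, so the
    baseline (t = 0) observations — identically zero, since migration is
    measured against the baseline examination itself — anchor the model;
    they are added automatically when the table only holds follow-ups
    (`add_baseline_zeros`). Without an observation below the breakpoint
    the two time covariates are collinear (hinge = t - b for every
    t >= b) and the early slope is not identifiable.

    `random_slopes` additionally gives each subject a random slope on t
    (off by default: the intercept-only model is the standard choice
    for three-follow-up designs).
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    sub = table[(table["dof"] == dof) & (table.get("replicate", 1) == 1)].copy()
    sub = sub[sub["timepoint_months"] >= 0]
    if sub.empty:
        raise ValueError(f"no rows for dof {dof!r}")
    if add_baseline_zeros and not (sub["timepoint_months"] == 0).any():
        zeros = pd.DataFrame(
            {"subject": sub["subject"].unique(), "timepoint_months": 0.0, "value": 0.0}
        )
        sub = pd.concat([zeros, sub[["subject", "timepoint_months", "value"]]], ignore_index=True)
    tps = np.sort(sub["timepoint_months"].unique())
    if (tps < breakpoint_months).sum() < 1 or (tps > breakpoint_months).sum() < 2:
        raise ValueError(
            "need a timepoint before and two after the breakpoint to separate "
            f"the two slopes, got {tps.tolist()}"
        )
    t, hinge = build_design(sub["timepoint_months"].to_numpy(), breakpoint_months)
    X = pd.DataFrame({"const": 1.0, "t": t, "hinge": hinge}, index=sub.index)
    if np.linalg.matrix_rank(X.to_numpy()) < 3:
        raise ValueError("singular design: timepoints do not separate the two slopes")
    y = sub["value"].astype(float)
    groups = sub["subject"].to_numpy()
    exog_re = X[["const", "t"]] if random_slopes else X[["const"]]

    model = MixedLM(y, X, groups=groups, exog_re=exog_re)
    fit = _mixed.fit_mixedlm_reml(model)

    beta = fit.fe_params
    cov = pd.DataFrame(
        _mixed.fixed_effects_covariance(fit, X.to_numpy(), exog_re.to_numpy(), groups),
        index=["const", "t", "hinge"],
        columns=["const", "t", "hinge"],
    )
    n_subjects = len(np.unique(groups))
    n_obs = len(sub)
    df_resid = max(n_obs - n_subjects - 2, 1)
    tq = stats.t.ppf(0.5 + level / 2.0, df_resid)

    se1 = float(np.sqrt(cov.loc["t", "t"]))
    # slope after the breakpoint is the sum beta1 + beta2
    c = np.array([0.0, 1.0, 1.0])
    slope_late = float(beta["t"] + beta["hinge"])
    se_late = float(np.sqrt(c @ cov.to_numpy() @ c))
    se2 = float(np.sqrt(cov.loc["hinge", "hinge"]))

    def p_value(est: float, se: float) -> float:
        if se == 0:
            return 1.0 if est == 0 else 0.0
        return float(2.0 * stats.t.sf(abs(est) / se, df_resid))

    return PiecewiseFit(
        dof=dof,
        breakpoint_months=breakpoint_months,
        beta0=float(beta["const"]),
        beta1=float(beta["t"]),
        beta2=float(beta["hinge"]),
        se_beta1=se1,
        se_beta2=se2,
        se_slope_late=se_late,
        p_early=p_value(float(beta["t"]), se1),
        p_late=p_value(slope_late, se_late),
        ci_beta1=(float(beta["t"]) - tq * se1, float(beta["t"]) + tq * se1),
        ci_slope_late=(slope_late - tq * se_late, slope_late + tq * se_late),
        subject_variance=float(np.asarray(fit.cov_re)[0, 0]),
        residual_variance=float(fit.scale),
        n_subjects=n_subjects,
        n_obs=n_obs,
        df_resid=df_resid,
        converged=bool(fit.converged),
    )
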