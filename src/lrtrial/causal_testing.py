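"""Within-stratum and pooled treatment contrasts under closed testing.

The effect model is ordinary least squares of the change outcome on a
treatment indicator, the centered baseline drinking count (shared slope),
stratum factor, and treatment-by-stratum interactions.  The contrast for
stratum s is the treatment effect evaluated in that stratum; pooled effects
are weighted combinations of the stratum contrasts with delta-method
intervals.  Family-wise error across the two primary hypotheses (responder
subgroup first, whole sample second) is controlled by closed testing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import (ARM_COL, BASELINE_HDD_COL, DELTA_HDD_COL, ID_COL,
                         Arm, TrialDataset)
from .responder_stratification import StratumAssignment
from .response_model import r_to_pct_variance


class TestingError(ValueError):
    pass


class Scope(str, enum.Enum):
    STRATUM = "STRATUM"
    POOLED = "POOLED"


class PoolWeights(str, enum.Enum):
    EQUAL = "EQUAL"
    BY_N = "BY_N"


@dataclass(frozen=True)
class EffectEstimate:
    scope: Scope
    stratum: Optional[int]  # None for pooled
    estimate: float         # ACTIVE - PLACEBO on the change scale, in days
    se: float
    ci95: tuple[float, float]
    p: float
    n_active: int
    n_placebo: int
    mean_active: float
    mean_placebo: float


@dataclass(frozen=True)
class ClosedTestResult:
    alpha: float
    p_lr: float
    p_full: Optional[float]
    h1_lr: str        # "reject" | "retain"
    h2_full: str      # "reject" | "retain" | "not_tested"


@dataclass(frozen=True)
class ModelFitStats:
    r_obs_fitted: float
    pct_variance: float


@dataclass
class StratifiedFit:
    """OLS fit with everything needed for contrasts."""

    params: np.ndarray
    cov: np.ndarray
    df_resid: int
    col_names: list[str]
    k: int
    y: np.ndarray
    fitted: np.ndarray
    treat: np.ndarray          # 0/1
    stratum: np.ndarray        # 1..k
    stratum_n: dict[int, int]

    def contrast(self, c: np.ndarray) -> tuple[float, float, float,
                                               tuple[float, float]]:
        """Estimate, se, two-sided p and 95% CI for c'beta."""
        est = float(c @ self.params)
        se = float(np.sqrt(c @ self.cov @ c))
        if se == 0:
            p = 0.0 if est != 0 else 1.0
            return est, se, p, (est, est)
        t = est / se
        p = float(2 * stats.t.sf(abs(t), self.df_resid))
        q = stats.t.ppf(0.975, self.df_resid)
        return est, se, p, (est - q * se, est + q * se)

    def stratum_contrast_vector(self, s: int) -> np.ndarray:
        c = np.zeros(len(self.col_names))
        c[self.col_names.index("treat")] = 1.0
        if s > 1:
            c[self.col_names.index(f"treat:stratum_{s}")] = 1.0
        return c


def fit_stratified_model(dataset: TrialDataset,
                         assignment: StratumAssignment) -> StratifiedFit:
    """OLS of change on treatment, centered baseline count, stratum factor
    and treatment-by-stratum interactions, restricted to the assigned ids.

    With k = 1 the model degenerates to a covariate-adjusted two-sample
    comparison.  Raises if any arm-by-stratum cell is empty (singular design).
    """
    df = dataset.df.merge(assignment.frame[[ID_COL, "stratum"]], on=ID_COL)
    if df[DELTA_HDD_COL].isna().any():
        raise TestingError("missing outcomes in the analysis set")
    k = assignment.k
    for s in range(1, k + 1):
        block = df[df["stratum"] == s]
        for arm in Arm:
            if (block[ARM_COL] == arm.value).sum() == 0:
                raise TestingError(
                    f"empty cell: stratum {s} has no {arm.value} subjects")

    y = df[DELTA_HDD_COL].to_numpy(float)
    treat = (df[ARM_COL] == Arm.ACTIVE.value).to_numpy(float)
    bhdd = df[BASELINE_HDD_COL].to_numpy(float)
    bhdd_c = bhdd - bhdd.mean()
    stratum = df["stratum"].to_numpy(int)

    cols = [np.ones(len(df)), treat, bhdd_c]
    names = ["intercept", "treat", "baseline_hdd_c"]
    for s in range(2, k + 1):
        d = (stratum == s).astype(float)
        cols.append(d)
        names.append(f"stratum_{s}")
    for s in range(2, k + 1):
        d = (stratum == s).astype(float) * treat
        cols.append(d)
        names.append(f"treat:stratum_{s}")
    X = np.column_stack(cols)

    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise TestingError(f"singular design: {exc}") from exc
    beta = XtX_inv @ (X.T @ y)
    fitted = X @ beta
    resid = y - fitted
    df_resid = len(y) - X.shape[1]
    if df_resid <= 0:
        raise TestingError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df_resid
    cov = sigma2 * XtX_inv

    stratum_n = {s: int((stratum == s).sum()) for s in range(1, k + 1)}
    return StratifiedFit(params=beta, cov=cov, df_resid=df_resid,
                         col_names=names, k=k, y=y, fitted=fitted,
                         treat=treat, stratum=stratum, stratum_n=stratum_n)


def _arm_summary(fit: StratifiedFit, mask: np.ndarray
                 ) -> tuple[int, int, float, float]:
    a = (fit.treat == 1) & mask
    p = (fit.treat == 0) & mask
    return (int(a.sum()), int(p.sum()),
            float(fit.y[a].mean()) if a.any() else np.nan,
            float(fit.y[p].mean()) if p.any() else np.nan)


def stratum_effects(fit: StratifiedFit) -> list[EffectEstimate]:
    """Per-stratum treatment contrast with Wald t interval and p-value."""
    out = []
    for s in range(1, fit.k + 1):
        est, se, p, ci = fit.contrast(fit.stratum_contrast_vector(s))
        na, npl, ma, mp = _arm_summary(fit, fit.stratum == s)
        out.append(EffectEstimate(Scope.STRATUM, s, est, se, ci, p,
                                  na, npl, ma, mp))
    return out


def pooled_effect(fit: StratifiedFit,
                  weights: PoolWeights = PoolWeights.BY_N) -> EffectEstimate:
    """Weighted combination of stratum contrasts (delta-method interval)."""
    if weights is PoolWeights.BY_N:
        w = np.array([fit.stratum_n[s] for s in range(1, fit.k + 1)], float)
    else:
        w = np.ones(fit.k)
    w = w / w.sum()
    c = np.zeros(len(fit.col_names))
    for s, ws in zip(range(1, fit.k + 1), w):
        c += ws * fit.stratum_contrast_vector(s)
    est, se, p, ci = fit.contrast(c)
    na, npl, ma, mp = _arm_summary(fit, np.ones_like(fit.treat, bool))
    return EffectEstimate(Scope.POOLED, None, est, se, ci, p, na, npl, ma, mp)


def closed_test(p_lr: float, p_full: Optional[float],
                alpha: float = 0.05) -> ClosedTestResult:
    """Gatekeeping: the subgroup hypothesis is tested at alpha; only on
    rejection is the whole-sample hypothesis tested (at alpha)."""
    for p in (p_lr, p_full):
        if p is not None and not 0 <= p <= 1:
            raise TestingError(f"p-value {p} outside [0, 1]")
    if p_lr <= alpha:
        h1 = "reject"
        if p_full is None:
            h2 = "not_tested"
        else:
            h2 = "reject" if p_full <= alpha else "retain"
    else:
        h1, h2 = "retain", "not_tested"
    return ClosedTestResult(alpha=alpha, p_lr=p_lr,
                            p_full=p_full if h1 == "reject" else None,
                            h1_lr=h1, h2_full=h2)


def model_fit_stats(fit: StratifiedFit) -> ModelFitStats:
    """Observed-vs-fitted correlation and the implied percent of variance."""
    scale = 1.0 + float(np.abs(fit.fitted).max(initial=0.0))
    if np.std(fit.fitted) <= 1e-10 * scale or np.std(fit.y) <= 1e-10 * scale:
        raise TestingError("zero-variance fitted values")
    r = float(np.corrcoef(fit.y, fit.fitted)[0, 1])
    return ModelFitStats(r_obs_fitted=r, pct_variance=r_to_pct_variance(r))


def effects_table(fit: StratifiedFit,
                  weights: PoolWeights = PoolWeights.BY_N) -> pd.DataFrame:
    """Publication-shaped table: one row per stratum plus the pooled row."""
    rows = []
    for e in stratum_effects(fit) + [pooled_effect(fit, weights)]:
        rows.append({
            "stratum": e.stratum if e.stratum is not None else "pooled",
            "n_active": e.n_active, "n_placebo": e.n_placebo,
            "mean_active": e.mean_active, "mean_placebo": e.mean_placebo,
            "observed_difference": e.mean_active - e.mean_placebo,
            "model_difference": e.estimate, "se": e.se,
            "ci_low": e.ci95[0], "ci_high": e.ci95[1], "p": e.p,
        })
    return pd.DataFrame(rows)
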