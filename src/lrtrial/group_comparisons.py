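"""Baseline responder-group comparisons and end-of-study outcome contrasts.

Baseline: one row per variable, rank-sum test for continuous/ordinal
variables and a chi-square test for categorical ones, no multiplicity
correction.  End of study: per secondary outcome, a two-factor (arm x
responder group) cell-means model with four pairwise contrasts on the
pooled residual variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import (ARM_COL, BASELINE_HDD_COL, ID_COL, Arm, FeatureKind,
                         TrialDataset)
from .responder_stratification import LR, UR


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonRow:
    variable: str
    test: str                  # "wilcoxon" | "chi-square" | "anova-contrast"
    statistic: float
    p: float
    summaries: dict            # per-group mean/sd/% and n
    flag: str = ""             # e.g. "untestable: single level"


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample rank-sum test (Mann-Whitney form of the statistic).

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def chi_square_test(table: np.ndarray,
                    yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a contingency table (no Yates by default)."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table),
                                           correction=yates)
    return float(stat), float(p)


def _group_summary(v: pd.Series) -> dict:
    return {"n": int(v.notna().sum()), "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.notna().sum() > 1 else np.nan}


def baseline_compare(dataset: TrialDataset,
                     labels: pd.DataFrame) -> list[ComparisonRow]:
    """LR-vs-UR comparison of every baseline variable (baseline count first).

    ``labels`` must carry subject_id and label columns covering the dataset.
    """
    df = dataset.df.merge(labels[[ID_COL, "label"]], on=ID_COL)
    if len(df) != dataset.n:
        raise ComparisonError("labels do not cover the dataset")
    is_lr = (df["label"] == LR).to_numpy()
    rows: list[ComparisonRow] = []

    def numeric_row(name: str, v: pd.Series) -> ComparisonRow:
        x = v[is_lr].dropna().to_numpy(float)
        y = v[~is_lr].dropna().to_numpy(float)
        summ = {LR: _group_summary(v[is_lr]), UR: _group_summary(v[~is_lr])}
        if len(x) == 0 or len(y) == 0 or (len(np.unique(
                np.concatenate([x, y]))) < 2):
            return ComparisonRow(name, "wilcoxon", np.nan, np.nan, summ,
                                 flag="untestable: single level")
        stat, p = wilcoxon_rank_sum(x, y)
        return ComparisonRow(name, "wilcoxon", stat, p, summ)

    def categorical_row(name: str, v: pd.Series) -> ComparisonRow:
        tab = pd.crosstab(df["label"], v)
        summ = {g: {"n": int((df["label"] == g).sum()),
                    "pct": {str(lvl): round(100 * float(c) / max(t, 1), 2)
                            for lvl, c, t in zip(
                                tab.columns, tab.loc[g],
                                [tab.loc[g].sum()] * len(tab.columns))}}
                for g in tab.index}
        if tab.shape[1] < 2 or tab.shape[0] < 2:
            return ComparisonRow(name, "chi-square", np.nan, np.nan, summ,
                                 flag="untestable: single level")
        stat, p = chi_square_test(tab.to_numpy())
        return ComparisonRow(name, "chi-square", stat, p, summ)

    rows.append(numeric_row(BASELINE_HDD_COL, df[BASELINE_HDD_COL]))
    for f in dataset.schema:
        if f.kind is FeatureKind.CATEGORICAL:
            rows.append(categorical_row(f.name, df[f.name]))
        elif f.kind is FeatureKind.BINARY:
            rows.append(categorical_row(f.name, df[f.name].round().astype(
                "Int64")))
        else:
            rows.append(numeric_row(f.name, df[f.name]))
    return rows


CONTRAST_NAMES = ("active_vs_placebo_in_UR", "active_vs_placebo_in_LR",
                  "UR_vs_LR_in_active", "UR_vs_LR_in_placebo")


def outcome_contrasts(dataset: TrialDataset,
                      labels: pd.DataFrame,
                      outcomes: Optional[list[str]] = None
                      ) -> list[ComparisonRow]:
    """Four pairwise contrasts per secondary outcome from the arm x responder
    cell-means model: treatment within each responder group and responder
    group within each treatment, t-tests on the pooled residual variance.
    """
    outcomes = outcomes or list(dataset.schema.secondary)
    df = dataset.df.merge(labels[[ID_COL, "label"]], on=ID_COL)
    rows: list[ComparisonRow] = []
    cells = {(g, a): ((df["label"] == g)
                      & (df[ARM_COL] == a)).to_numpy()
             for g in (UR, LR) for a in (Arm.ACTIVE.value, Arm.PLACEBO.value)}
    for var in outcomes:
        if var not in df.columns:
            rows.append(ComparisonRow(var, "anova-contrast", np.nan, np.nan,
                                      {}, flag="missing column"))
            continue
        v = df[var]
        stats_by_cell = {}
        sse, n_tot = 0.0, 0
        empty = False
        for key, mask in cells.items():
            vals = v[mask].dropna().to_numpy(float)
            stats_by_cell[key] = vals
            if len(vals) == 0:
                empty = True
                continue
            sse += float(((vals - vals.mean()) ** 2).sum())
            n_tot += len(vals)
        df_resid = n_tot - 4
        s2 = sse / df_resid if df_resid > 0 else np.nan
        pairs = {
            CONTRAST_NAMES[0]: ((UR, Arm.ACTIVE.value),
                                (UR, Arm.PLACEBO.value)),
            CONTRAST_NAMES[1]: ((LR, Arm.ACTIVE.value),
                                (LR, Arm.PLACEBO.value)),
            CONTRAST_NAMES[2]: ((UR, Arm.ACTIVE.value),
                                (LR, Arm.ACTIVE.value)),
            CONTRAST_NAMES[3]: ((UR, Arm.PLACEBO.value),
                                (LR, Arm.PLACEBO.value)),
        }
        summ = {f"{g}/{a}": {"n": len(stats_by_cell[(g, a)]),
                             "mean": (float(stats_by_cell[(g, a)].mean())
                                      if len(stats_by_cell[(g, a)])
                                      else np.nan),
                             "sd": (float(stats_by_cell[(g, a)].std(ddof=1))
                                    if len(stats_by_cell[(g, a)]) > 1
                                    else np.nan)}
                for (g, a) in cells}
        for cname, (k1, k2) in pairs.items():
            v1, v2 = stats_by_cell[k1], stats_by_cell[k2]
            if len(v1) == 0 or len(v2) == 0 or not np.isfinite(s2):
                rows.append(ComparisonRow(f"{var}:{cname}", "anova-contrast",
                                          np.nan, np.nan, summ,
                                          flag="empty cell"))
                continue
            diff = v1.mean() - v2.mean()
            se = np.sqrt(s2 * (1 / len(v1) + 1 / len(v2)))
            t = diff / se if se > 0 else np.inf
            p = float(2 * stats.t.sf(abs(t), df_resid))
            rows.append(ComparisonRow(f"{var}:{cname}", "anova-contrast",
                                      float(t), p, summ,
                                      flag="empty cell" if empty else ""))
    return rows


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    import json
    return pd.DataFrame([{
        "variable": r.variable, "test": r.test, "statistic": r.statistic,
        "p": r.p, "flag": r.flag,
        "summaries": json.dumps(r.summaries, sort_keys=True, default=float),
    } for r in rows])
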