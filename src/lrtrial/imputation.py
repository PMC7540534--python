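"""Chained-equations imputation of missing baseline items.

Iterated conditional modelling: each partially observed feature is regressed
on all other features (current working values), columns visited in ascending
order of missingness.  Continuous draws come from predictive mean matching
(default) or a normal linear model; ordinal/binary draws are rounded and
clipped to the declared scale bounds.  Observed cells are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .trial_data import (DELTA_HDD_COL, OUTCOME_HDD_COL, FeatureKind,
                         TrialDataset)


class ImputationError(ValueError):
    pass


@dataclass(frozen=True)
class ImputationConfig:
    n_iterations: int = 10
    n_imputations: int = 1
    seed: int = 0
    continuous_method: str = "pmm"  # "pmm" | "norm"
    pmm_donors: int = 5
    noise: bool = True  # False: deterministic conditional-mean fill ("norm")
    include_outcome: bool = False  # let delta_hdd enter the predictor set
    include_arm: bool = False      # let treatment assignment enter

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ImputationError("n_iterations must be >= 1")
        if self.pmm_donors < 1:
            raise ImputationError("pmm_donors must be >= 1")
        if self.continuous_method not in ("pmm", "norm"):
            raise ImputationError(
                f"unknown continuous method {self.continuous_method!r}")


def _ridge_lstsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS with a whisper of ridge for collinear item blocks."""
    lam = 1e-8 * X.shape[0]
    A = X.T @ X + lam * np.eye(X.shape[1])
    return np.linalg.solve(A, X.T @ y)


def _predictor_matrix(work: pd.DataFrame, cols: list[str],
                      target: str) -> np.ndarray:
    others = [c for c in cols if c != target]
    X = work[others].to_numpy(float)
    return np.column_stack([np.ones(len(X)), X])


def impute_chained(dataset: TrialDataset,
                   config: Optional[ImputationConfig] = None) -> TrialDataset:
    """Return a copy of ``dataset`` with every missing feature item filled.

    Deterministic given ``config.seed``; a dataset with no missing items is
    returned unchanged (same cell values).  Raises for any all-missing
    feature column.
    """
    config = config or ImputationConfig()
    rng = np.random.default_rng(config.seed)
    df = dataset.df.copy()
    schema = dataset.schema

    numeric_feats = [f for f in schema
                     if f.kind is not FeatureKind.CATEGORICAL]
    model_cols = [f.name for f in numeric_feats]
    if config.include_outcome and DELTA_HDD_COL in df.columns:
        model_cols.append(DELTA_HDD_COL)
    if config.include_arm:
        df["_arm_num"] = (df["arm"] == "ACTIVE").astype(float)
        model_cols.append("_arm_num")

    target_feats = [f for f in numeric_feats if df[f.name].isna().any()]
    for f in target_feats:
        if df[f.name].isna().all():
            raise ImputationError(
                f"column {f.name!r} has no observed values; cannot impute")
    if not target_feats:
        return TrialDataset(df.drop(columns=["_arm_num"], errors="ignore"),
                            schema)

    work = df[model_cols].astype(float).copy()
    miss_masks = {f.name: work[f.name].isna().to_numpy()
                  for f in target_feats}
    # auxiliary model columns with missing cells get a mean start but are
    # never treated as imputation targets
    for c in model_cols:
        col = work[c]
        if col.isna().any():
            work[c] = col.fillna(col.mean())

    # visit order: ascending missingness count
    order = sorted(target_feats, key=lambda f: int(miss_masks[f.name].sum()))

    for _ in range(config.n_iterations):
        for f in order:
            name = f.name
            miss = miss_masks[name]
            obs = ~miss
            X = _predictor_matrix(work, model_cols, name)
            y_obs = df[name].to_numpy(float)[obs]
            beta = _ridge_lstsq(X[obs], y_obs)
            pred_obs = X[obs] @ beta
            pred_mis = X[miss] @ beta
            if config.continuous_method == "pmm" and config.noise:
                # nearest observed predictions donate their observed values
                k = min(config.pmm_donors, obs.sum())
                dist = np.abs(pred_mis[:, None] - pred_obs[None, :])
                part = np.argpartition(dist, k - 1, axis=1)[:, :k]
                pick = rng.integers(0, k, size=len(pred_mis))
                draws = y_obs[part[np.arange(len(pred_mis)), pick]]
            else:
                resid_sd = float(np.std(y_obs - pred_obs, ddof=1)) \
                    if obs.sum() > X.shape[1] else 0.0
                noise = (rng.normal(0, resid_sd, size=miss.sum())
                         if config.noise and resid_sd > 0 else 0.0)
                draws = pred_mis + noise
            if f.kind in (FeatureKind.ORDINAL, FeatureKind.BINARY):
                lo, hi = f.bounds
                draws = np.clip(np.round(draws), lo, hi)
            elif f.lo is not None or f.hi is not None:
                draws = np.clip(draws, *f.bounds)
            work.loc[miss, name] = draws

    for f in target_feats:
        filled = work[f.name].to_numpy()
        col = df[f.name].to_numpy(float)
        col[miss_masks[f.name]] = filled[miss_masks[f.name]]
        df[f.name] = col
    df = df.drop(columns=["_arm_num"], errors="ignore")
    return TrialDataset(df, schema)


def missingness_summary(dataset: TrialDataset) -> pd.DataFrame:
    """Per-column missing counts plus the per-subject missing-item histogram."""
    feats = dataset.schema.names
    per_col = dataset.df[feats].isna().sum()
    rows = [{"column": c, "n_missing": int(per_col[c])} for c in feats
            if per_col[c] > 0]
    return pd.DataFrame(rows, columns=["column", "n_missing"])


def subjects_missing_items(dataset: TrialDataset) -> pd.Series:
    """Histogram: number of subjects missing exactly k baseline items."""
    k = dataset.df[dataset.schema.names].isna().sum(axis=1)
    return k[k > 0].value_counts().sort_index()
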