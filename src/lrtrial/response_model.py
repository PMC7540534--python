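"""Counterfactual response predictor: a regression forest fit on the
active arm only, scored for every subject regardless of assignment.

The forest predicts the primary change outcome from baseline features (items
entered individually, categorical features one-hot expanded, baseline
drinking count included).  Out-of-bag predictions back the fit diagnostics;
full-forest predictions back likely-responder classification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .trial_data import (ARM_COL, BASELINE_HDD_COL, DELTA_HDD_COL, ID_COL,
                         Arm, FeatureKind, FeatureSchema, TrialDataset)

MIN_ACTIVE_ARM = 30


class ModelError(ValueError):
    pass


class ScoreMode(str, enum.Enum):
    FULL_FOREST = "FULL_FOREST"
    OOB = "OOB"


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 1000
    mtry: Optional[float] = None  # int count or fraction; None -> p/3
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ModelError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ModelError("min_leaf must be >= 1")

    def max_features(self, p: int) -> int:
        if self.mtry is None:
            return max(1, p // 3)
        if 0 < self.mtry < 1:
            return max(1, int(self.mtry * p))
        m = int(self.mtry)
        if not 1 <= m <= p:
            raise ModelError(f"mtry {m} outside [1, {p}]")
        return m


@dataclass(frozen=True)
class PredictionScore:
    subject_id: str
    score: float
    provenance: ScoreMode
    counterfactual: bool  # True iff the subject was randomized to placebo


@dataclass(frozen=True)
class FitDiagnostics:
    r: float
    r_squared_pct: float
    ci95_r: tuple[float, float]
    n: int
    qq_pairs: tuple[tuple[float, float], ...]  # (observed, predicted) sorted


def r_to_pct_variance(r: float) -> float:
    """Percent of variance explained implied by a correlation: 100·r²."""
    return 100.0 * r * r


def fisher_z_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z confidence interval for a Pearson correlation."""
    if n < 4:
        raise ModelError("need n >= 4 for a Fisher z interval")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - q * se)), float(np.tanh(z + q * se)))


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def design_columns(schema: FeatureSchema) -> list[str]:
    cols = [BASELINE_HDD_COL]
    for f in schema:
        if f.kind is FeatureKind.CATEGORICAL:
            cols += [f"{f.name}={lvl}" for lvl in f.levels]
        else:
            cols.append(f.name)
    return cols


def design_matrix(dataset: TrialDataset) -> tuple[np.ndarray, list[str]]:
    """Numeric predictor matrix: baseline count + features, one row/subject.

    Categorical features are one-hot expanded at model time (storage keeps
    the raw level strings).  Raises if any feature cell is still missing.
    """
    df, schema = dataset.df, dataset.schema
    cols: list[np.ndarray] = [df[BASELINE_HDD_COL].to_numpy(float)]
    names = [BASELINE_HDD_COL]
    for f in schema:
        if f.kind is FeatureKind.CATEGORICAL:
            for lvl in f.levels:
                cols.append((df[f.name].astype(str) == lvl).to_numpy(float))
                names.append(f"{f.name}={lvl}")
        else:
            v = df[f.name].to_numpy(float)
            if np.isnan(v).any():
                raise ModelError(
                    f"feature {f.name!r} has missing values; run imputation "
                    "before model fitting")
            cols.append(v)
            names.append(f.name)
    return np.column_stack(cols), names


@dataclass
class ResponseModel:
    """Fitted forest plus everything needed for scoring and diagnostics."""

    forest: RandomForestRegressor
    feature_names: list[str]
    schema: FeatureSchema
    train_ids: list[str]
    y_train: np.ndarray
    oob_pred: np.ndarray
    config: ForestConfig

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict(X)


def fit_treated_model(dataset: TrialDataset,
                      config: Optional[ForestConfig] = None,
                      allow_small: bool = False) -> ResponseModel:
    """Fit the regression forest on ACTIVE-arm subjects with observed outcome.

    Bootstrap resampling is always on so out-of-bag predictions exist for
    every training subject; the fit is deterministic given the config seed.
    """
    config = config or ForestConfig()
    df = dataset.df
    if DELTA_HDD_COL not in df.columns:
        raise ModelError("dataset has no derived outcome column; "
                         "run derive_outcomes first")
    mask = dataset.arm_mask(Arm.ACTIVE) & df[DELTA_HDD_COL].notna().to_numpy()
    n_active = int(mask.sum())
    if n_active < MIN_ACTIVE_ARM and not allow_small:
        raise ModelError(
            f"active arm has {n_active} usable subjects (< {MIN_ACTIVE_ARM}); "
            "pass allow_small=True to override")
    sub = TrialDataset(df.loc[mask].reset_index(drop=True), dataset.schema)
    X, names = design_matrix(sub)
    y = sub.df[DELTA_HDD_COL].to_numpy(float)
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=config.max_features(X.shape[1]),
        min_samples_leaf=config.min_leaf,
        bootstrap=True,
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    oob = np.asarray(forest.oob_prediction_, dtype=float)
    return ResponseModel(forest=forest, feature_names=names,
                         schema=dataset.schema,
                         train_ids=list(sub.df[ID_COL]),
                         y_train=y, oob_pred=oob, config=config)


def score_all(model: ResponseModel, dataset: TrialDataset,
              mode: ScoreMode = ScoreMode.FULL_FOREST
              ) -> list[PredictionScore]:
    """Predicted active-arm change for every subject.

    Placebo-arm scores are counterfactual and always come from the full
    forest.  Active-arm scores use ``mode``: FULL_FOREST (default) or OOB
    (leakage-averse; training subjects get their out-of-bag prediction).
    """
    X, names = design_matrix(dataset)
    if names != model.feature_names:
        extra = sorted(set(names) ^ set(model.feature_names))
        raise ModelError(f"feature mismatch with fitted model: {extra}")
    full = model.predict_matrix(X)
    df = dataset.df
    placebo = dataset.arm_mask(Arm.PLACEBO)
    scores: list[PredictionScore] = []
    oob_by_id = dict(zip(model.train_ids, model.oob_pred))
    for i, sid in enumerate(df[ID_COL].astype(str)):
        is_cf = bool(placebo[i])
        if mode is ScoreMode.OOB and not is_cf and sid in oob_by_id:
            scores.append(PredictionScore(sid, float(oob_by_id[sid]),
                                          ScoreMode.OOB, is_cf))
        else:
            scores.append(PredictionScore(sid, float(full[i]),
                                          ScoreMode.FULL_FOREST, is_cf))
    return scores


def scores_frame(scores: list[PredictionScore]) -> pd.DataFrame:
    return pd.DataFrame({
        ID_COL: [s.subject_id for s in scores],
        "score": [s.score for s in scores],
        "provenance": [s.provenance.value for s in scores],
        "counterfactual": [s.counterfactual for s in scores],
    })


def fit_diagnostics(model: ResponseModel, n_quantiles: int = 50
                    ) -> FitDiagnostics:
    """Goodness of fit from out-of-bag predictions on the training arm.

    Pearson correlation of observed vs OOB-predicted change, the implied
    percent of variance (100·r²), a Fisher z interval, and paired sorted
    quantiles for a Q-Q display.
    """
    y, pred = model.y_train, model.oob_pred
    if np.std(pred) == 0 or np.std(y) == 0:
        raise ModelError("degenerate (zero-variance) predictions; "
                         "correlation undefined")
    r = float(np.corrcoef(y, pred)[0, 1])
    qs = np.linspace(0, 1, min(n_quantiles, len(y)))
    qq = tuple(zip(np.quantile(y, qs), np.quantile(pred, qs)))
    return FitDiagnostics(r=r, r_squared_pct=r_to_pct_variance(r),
                          ci95_r=fisher_z_ci(r, len(y)),
                          n=len(y), qq_pairs=qq)
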