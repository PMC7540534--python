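"""Likely-responder classification and prognostic-score quantile strata."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import ARM_COL, ID_COL, Arm, TrialDataset
from .response_model import PredictionScore

LR, UR = "LR", "UR"


class StratificationError(ValueError):
    pass


@dataclass(frozen=True)
class ResponderConfig:
    threshold: float = 14.0       # predicted change >= threshold -> LR
    n_strata_lr: int = 2
    n_strata_full: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 28:
            raise StratificationError("threshold must be in (0, 28]")
        if min(self.n_strata_lr, self.n_strata_full) < 2:
            raise StratificationError("strata counts must be >= 2")


@dataclass
class StratumAssignment:
    """Contiguous quantile stratum per subject; 1 = lowest scores."""

    frame: pd.DataFrame  # subject_id, score, stratum
    k: int

    def sizes(self) -> list[int]:
        return [int((self.frame["stratum"] == s).sum())
                for s in range(1, self.k + 1)]

    def ids_in(self, stratum: int) -> list[str]:
        return list(self.frame.loc[self.frame["stratum"] == stratum,
                                   ID_COL])


def classify_responders(scores: list[PredictionScore],
                        config: Optional[ResponderConfig] = None
                        ) -> pd.DataFrame:
    """Label each subject LR iff predicted change >= threshold (closed bound).

    Returns a frame with subject_id, score, label.
    """
    config = config or ResponderConfig()
    return pd.DataFrame({
        ID_COL: [s.subject_id for s in scores],
        "score": [s.score for s in scores],
        "label": [LR if s.score >= config.threshold else UR for s in scores],
    })


def responder_counts(labels: pd.DataFrame,
                     dataset: TrialDataset) -> pd.DataFrame:
    """LR/UR counts by arm (n accounting for the run log)."""
    merged = labels.merge(dataset.df[[ID_COL, ARM_COL]], on=ID_COL)
    return (merged.groupby(["label", ARM_COL]).size()
            .rename("n").reset_index())


def guaranteed_percent_reduction(threshold: float,
                                 max_baseline: float) -> float:
    """Minimum percent-of-baseline reduction implied by a change threshold.

    A change of at least ``threshold`` days against any baseline of at most
    ``max_baseline`` days is at least ``100*threshold/max_baseline`` percent
    of that baseline.
    """
    if threshold <= 0 or max_baseline <= 0:
        raise StratificationError("threshold and max_baseline must be > 0")
    if threshold > max_baseline:
        raise StratificationError(
            f"threshold {threshold} exceeds max feasible baseline "
            f"{max_baseline}")
    return 100.0 * threshold / max_baseline


def partition_quantiles(scores: list[PredictionScore],
                        k: int) -> StratumAssignment:
    """Split score-rank-ordered subjects into k contiguous blocks.

    Block sizes are ``floor(n/k)`` or ``ceil(n/k)``, the remainder going to
    the highest-score blocks; ties broken by subject_id so the partition is a
    deterministic function of the (score, id) multiset.
    """
    n = len(scores)
    if n < k:
        raise StratificationError(f"cannot split {n} subjects into {k} strata")
    order = sorted(scores, key=lambda s: (s.score, s.subject_id))
    base, rem = divmod(n, k)
    sizes = [base] * (k - rem) + [base + 1] * rem
    strata = np.repeat(np.arange(1, k + 1), sizes)
    frame = pd.DataFrame({
        ID_COL: [s.subject_id for s in order],
        "score": [s.score for s in order],
        "stratum": strata,
    })
    return StratumAssignment(frame=frame, k=k)


def balance_check(assignment: StratumAssignment, dataset: TrialDataset,
                  require_both_arms: bool = False) -> pd.DataFrame:
    """Per-stratum arm counts, arm-wise score means, and the two-sample
    Kolmogorov–Smirnov distance between arms' scores.

    An empty arm inside a stratum is flagged (or raised when
    ``require_both_arms``): the within-stratum contrast is undefined there.
    """
    merged = assignment.frame.merge(dataset.df[[ID_COL, ARM_COL]], on=ID_COL)
    rows = []
    for s in range(1, assignment.k + 1):
        block = merged[merged["stratum"] == s]
        a = block.loc[block[ARM_COL] == Arm.ACTIVE.value, "score"]
        p = block.loc[block[ARM_COL] == Arm.PLACEBO.value, "score"]
        degenerate = len(a) == 0 or len(p) == 0
        if degenerate and require_both_arms:
            raise StratificationError(
                f"stratum {s} has an empty arm "
                f"(active n={len(a)}, placebo n={len(p)})")
        ks = (float(stats.ks_2samp(a, p).statistic)
              if not degenerate else np.nan)
        rows.append({
            "stratum": s,
            "n_active": len(a), "n_placebo": len(p),
            "mean_score_active": float(a.mean()) if len(a) else np.nan,
            "mean_score_placebo": float(p.mean()) if len(p) else np.nan,
            "ks_statistic": ks,
            "flag_empty_arm": degenerate,
        })
    return pd.DataFrame(rows)
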