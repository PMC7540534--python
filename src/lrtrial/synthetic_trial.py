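"""Randomized two-arm trial simulator with known heterogeneous effects.

Generates block-correlated baseline scale items via a Gaussian copula,
potential outcomes with a configurable arm-independent prognosis ``h(f)`` and
a feature-dependent treatment effect ``g(f)``, MAR missingness, daily outcome
statuses, monthly summaries, and a set of secondary end-of-study measures.
Oracle access to each subject's true effect and both potential outcomes is
returned alongside the observable dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .trial_data import (ARM_COL, BASELINE_HDD_COL, DELTA_HDD_COL, ID_COL,
                         OUTCOME_HDD_COL, Arm, FeatureKind, FeatureSchema,
                         FeatureSpec, TrialDataset, day_columns)

SECONDARY_OUTCOMES = (
    "sec_percent_hdd", "sec_drinks_per_week", "sec_drinks_per_drinking_day",
    "sec_percent_days_abstinent", "sec_craving", "sec_consequences",
    "sec_depression", "sec_anxiety", "sec_mood",
)
MONTHLY_COLS = tuple(f"month{i}_hdd" for i in range(1, 7))


class SimulationError(ValueError):
    """Config produces an infeasible trial."""


@dataclass(frozen=True)
class FeatureBlock:
    """A scale of ``n_items`` ordinal items with equicorrelation ``rho``."""

    name: str
    n_items: int
    lo: int
    hi: int
    rho: float
    mean_quantile: float = 0.5  # copula location, as a marginal quantile

    def item_names(self) -> list[str]:
        return [f"{self.name}_q{i:02d}" for i in range(1, self.n_items + 1)]


@dataclass(frozen=True)
class EffectSpec:
    """Named functional form mapping baseline features to days of effect.

    kind "zero": identically 0.  kind "constant": ``intercept`` everywhere.
    kind "linear": ``intercept + sum coef[name] * (value - center[name])``.
    kind "threshold": ``magnitude * 1[feature > cut]``.
    """

    kind: str = "zero"
    intercept: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)
    centers: dict[str, float] = field(default_factory=dict)
    feature: str = ""
    cut: float = 0.0
    magnitude: float = 0.0

    def __call__(self, frame: pd.DataFrame) -> np.ndarray:
        n = len(frame)
        if self.kind == "zero":
            return np.zeros(n)
        if self.kind == "constant":
            return np.full(n, float(self.intercept))
        if self.kind == "linear":
            out = np.full(n, float(self.intercept))
            for name, coef in self.coefficients.items():
                x = frame[name].to_numpy(float)
                out += coef * (x - self.centers.get(name, 0.0))
            return out
        if self.kind == "threshold":
            x = frame[self.feature].to_numpy(float)
            return self.magnitude * (x > self.cut)
        raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 338
    allocation: float = 0.5
    feature_blocks: tuple[FeatureBlock, ...] = ()
    effect: EffectSpec = field(default_factory=EffectSpec)
    prognosis: EffectSpec = field(default_factory=EffectSpec)
    noise_sd: float = 8.0
    missing_rate_items: float = 0.0
    missing_rate_outcome: float = 0.0
    baseline_hdd_min: int = 4
    baseline_hdd_mean: float = 21.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.allocation < 1:
            raise SimulationError("allocation must be in (0, 1)")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        for r in (self.missing_rate_items, self.missing_rate_outcome):
            if not 0 <= r < 1:
                raise SimulationError("missing rates must be in [0, 1)")
        for b in self.feature_blocks:
            if not 0 <= b.rho < 1:
                raise SimulationError(f"block {b.name}: rho must be in [0,1)")

    def schema(self) -> FeatureSchema:
        feats = [
            FeatureSpec("age", FeatureKind.CONTINUOUS, lo=21, hi=90),
            FeatureSpec("male", FeatureKind.BINARY),
            FeatureSpec("education_years", FeatureKind.CONTINUOUS, lo=0, hi=30),
        ]
        for b in self.feature_blocks:
            for item in b.item_names():
                feats.append(FeatureSpec(item, FeatureKind.ORDINAL,
                                         lo=b.lo, hi=b.hi,
                                         label=f"{b.name} item"))
        return FeatureSchema(features=tuple(feats),
                             secondary=SECONDARY_OUTCOMES,
                             monthly=MONTHLY_COLS)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["feature_blocks"] = [dataclasses.asdict(b)
                               for b in self.feature_blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["feature_blocks"] = tuple(FeatureBlock(**b)
                                    for b in d.get("feature_blocks", ()))
        for key in ("effect", "prognosis"):
            if key in d and isinstance(d[key], dict):
                d[key] = EffectSpec(**d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class OracleEffects:
    """Ground truth per subject: effect, prognosis and potential outcomes.

    ``y_active``/``y_placebo`` are the feasibility-truncated potential
    outcomes on the change scale; ``*_raw`` are pre-truncation.
    """

    df: pd.DataFrame  # subject_id, g, h, y_active_raw, y_placebo_raw,
    #                   y_active, y_placebo

    def true_effects(self) -> np.ndarray:
        return self.df["g"].to_numpy(float)

    def expected_active_change(self) -> np.ndarray:
        """h + g: the expected change under active treatment (noise-free)."""
        return (self.df["h"] + self.df["g"]).to_numpy(float)


def true_subgroup_labels(oracle: OracleEffects, threshold: float,
                         window_days: int = 28) -> np.ndarray:
    """Boolean ground-truth responder labels: ``h(f) + g(f) >= threshold``.

    The expected change is clipped to the feasible change range of the
    outcome window, so thresholds above ``window_days`` label nobody.
    """
    expected = np.clip(oracle.expected_active_change(),
                       -window_days, window_days)
    return expected >= threshold


# ---------------------------------------------------------------------------
# Default configuration
# ---------------------------------------------------------------------------

def default_blocks() -> tuple[FeatureBlock, ...]:
    return (
        FeatureBlock("impulsivity", 6, 1, 4, 0.55),
        FeatureBlock("anxiety", 5, 0, 3, 0.60, mean_quantile=0.35),
        FeatureBlock("depression", 5, 0, 3, 0.60, mean_quantile=0.35),
        FeatureBlock("mood", 6, 0, 4, 0.50),
        FeatureBlock("craving", 3, 0, 6, 0.50),
        FeatureBlock("consequences", 4, 0, 4, 0.40),
        FeatureBlock("withdrawal", 3, 0, 7, 0.45, mean_quantile=0.25),
    )


def default_config(n_subjects: int = 338, seed: int = 0,
                   **overrides) -> SimulationConfig:
    """Default heterogeneous-effect trial.

    The effect rises with baseline drinking and impulsivity and falls with
    anxiety/depression/mood, calibrated so that roughly 40% of subjects have
    an expected active-arm change of at least 14 days; pooled over everyone
    the effect nearly cancels.
    """
    prognosis = EffectSpec(
        kind="linear", intercept=11.0,
        coefficients={"baseline_hdd": 0.45, "mood_q01": -0.5,
                      "craving_q01": -0.4},
        centers={"baseline_hdd": 21.5, "mood_q01": 2.0, "craving_q01": 3.0},
    )
    effect = EffectSpec(
        kind="linear", intercept=2.0,
        coefficients={
            "baseline_hdd": 0.35,
            "impulsivity_q01": 1.6, "impulsivity_q02": 1.2,
            "anxiety_q01": -1.2, "depression_q01": -1.2,
            "mood_q01": -0.8, "mood_q02": -0.6,
        },
        centers={"baseline_hdd": 21.5, "impulsivity_q01": 2.5,
                 "impulsivity_q02": 2.5, "anxiety_q01": 1.2,
                 "depression_q01": 1.2, "mood_q01": 2.0, "mood_q02": 2.0},
    )
    base = dict(n_subjects=n_subjects, seed=seed,
                feature_blocks=default_blocks(), effect=effect,
                prognosis=prognosis, noise_sd=8.0,
                missing_rate_items=0.03, missing_rate_outcome=0.05)
    base.update(overrides)
    return SimulationConfig(**base)


def null_config(n_subjects: int = 200, seed: int = 0,
                **overrides) -> SimulationConfig:
    """Global-null trial (g = 0) with prognosis centred near the responder
    threshold so both responder classes are well populated."""
    prognosis = EffectSpec(
        kind="linear", intercept=14.0,
        coefficients={"baseline_hdd": 0.45, "impulsivity_q01": 1.5,
                      "anxiety_q01": -1.0, "mood_q01": -0.7},
        centers={"baseline_hdd": 21.5, "impulsivity_q01": 2.5,
                 "anxiety_q01": 1.2, "mood_q01": 2.0},
    )
    base = dict(n_subjects=n_subjects, seed=seed,
                feature_blocks=default_blocks(), effect=EffectSpec("zero"),
                prognosis=prognosis, noise_sd=8.0)
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _draw_block(rng: np.random.Generator, block: FeatureBlock,
                n: int) -> np.ndarray:
    """Equicorrelated Gaussian copula discretised to the item scale."""
    shared = rng.standard_normal(n)
    uniq = rng.standard_normal((n, block.n_items))
    z = (np.sqrt(block.rho) * shared[:, None]
         + np.sqrt(1 - block.rho) * uniq)
    # shift so that the marginal median sits at the requested quantile
    z = z + stats.norm.ppf(block.mean_quantile)
    u = stats.norm.cdf(z)
    n_levels = block.hi - block.lo + 1
    return block.lo + np.minimum((u * n_levels).astype(int), n_levels - 1)


def _draw_baseline_hdd(rng: np.random.Generator, cfg: SimulationConfig,
                       n: int) -> np.ndarray:
    lo, hi = cfg.baseline_hdd_min, cfg.schema().window_days
    span = hi - lo
    p = np.clip((cfg.baseline_hdd_mean - lo) / span, 0.01, 0.99)
    return lo + rng.binomial(span, p, size=n)


def simulate_trial(config: SimulationConfig
                   ) -> tuple[TrialDataset, OracleEffects]:
    """Simulate one randomized trial; reproducible bit-for-bit given seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    schema = config.schema()
    w = schema.window_days

    frame = pd.DataFrame({
        ID_COL: [f"S{i:05d}" for i in range(n)],
        "age": np.round(np.clip(rng.normal(50, 10, n), 21, 90), 1),
        "male": rng.binomial(1, 0.66, n),
        "education_years": np.round(np.clip(rng.normal(15, 2.6, n), 6, 24), 1),
    })
    for block in config.feature_blocks:
        vals = _draw_block(rng, block, n)
        for j, item in enumerate(block.item_names()):
            frame[item] = vals[:, j]
    frame[BASELINE_HDD_COL] = _draw_baseline_hdd(rng, config, n)

    arm = np.where(rng.random(n) < config.allocation,
                   Arm.ACTIVE.value, Arm.PLACEBO.value)
    frame[ARM_COL] = arm

    h = config.prognosis(frame)
    g = config.effect(frame)
    eps_p = rng.normal(0, config.noise_sd, n) if config.noise_sd else np.zeros(n)
    eps_a = rng.normal(0, config.noise_sd, n) if config.noise_sd else np.zeros(n)
    y_placebo_raw = h + eps_p
    y_active_raw = h + g + eps_a

    bhdd = frame[BASELINE_HDD_COL].to_numpy(float)
    # truncation acts on the count scale: outcome_hdd must land in [0, w]
    out_active = np.clip(np.round(bhdd - y_active_raw), 0, w)
    out_placebo = np.clip(np.round(bhdd - y_placebo_raw), 0, w)
    y_active = bhdd - out_active
    y_placebo = bhdd - out_placebo
    if np.all(out_active == 0) or np.all(out_active == w):
        raise SimulationError(
            "effect/prognosis pushes every active outcome to the boundary; "
            "rescale the config")

    observed_out = np.where(arm == Arm.ACTIVE.value, out_active, out_placebo)
    frame[OUTCOME_HDD_COL] = observed_out.astype(int)
    frame[DELTA_HDD_COL] = (bhdd - observed_out).astype(int)

    # daily statuses consistent with outcome_hdd
    day_cols = day_columns(w)
    day_mat = np.full((n, w), "N", dtype=object)
    for i in range(n):
        k = int(observed_out[i])
        idx = rng.permutation(w)[:k]
        day_mat[i, idx] = "H"
    # monthly trajectory: linear drift from baseline toward the outcome level
    months = np.linspace(1 / 6, 1, 6)
    base_mo = bhdd[:, None] * (1 - months[None, :]) \
        + observed_out[:, None] * months[None, :]
    mo_noise = rng.normal(0, 1.5, (n, 6))
    monthly = np.clip(np.round(base_mo + mo_noise), 0, w).astype(int)
    for j, c in enumerate(MONTHLY_COLS):
        frame[c] = monthly[:, j]

    delta = frame[DELTA_HDD_COL].to_numpy(float)
    sec_noise = rng.normal(0, 1, (n, len(SECONDARY_OUTCOMES)))
    frame["sec_percent_hdd"] = np.clip(
        100 * observed_out / w + 5 * sec_noise[:, 0], 0, 100).round(2)
    frame["sec_drinks_per_week"] = np.clip(
        55 - 1.2 * delta + 8 * sec_noise[:, 1], 0, None).round(2)
    frame["sec_drinks_per_drinking_day"] = np.clip(
        9 - 0.15 * delta + 2 * sec_noise[:, 2], 0, None).round(2)
    frame["sec_percent_days_abstinent"] = np.clip(
        100 * (1 - observed_out / w) * 0.6 + 10 * sec_noise[:, 3],
        0, 100).round(2)
    frame["sec_craving"] = np.clip(
        2.7 - 0.02 * delta + 0.8 * sec_noise[:, 4], 0, 6).round(2)
    frame["sec_consequences"] = np.clip(
        10 - 0.1 * delta + 5 * sec_noise[:, 5], 0, 40).round(2)
    frame["sec_depression"] = np.clip(
        6 - 0.08 * delta + 4 * sec_noise[:, 6], 0, 40).round(2)
    frame["sec_anxiety"] = np.clip(
        5 - 0.07 * delta + 4 * sec_noise[:, 7], 0, 40).round(2)
    frame["sec_mood"] = np.clip(
        58 - 0.2 * delta + 12 * sec_noise[:, 8], 0, 120).round(2)

    # --- missingness -------------------------------------------------------
    # MAR given fully observed demographics: older and less-educated subjects
    # are more likely to skip items / the final window.
    age_z = (frame["age"].to_numpy(float) - 50) / 10
    if config.missing_rate_items > 0:
        item_cols = [c for c in schema.names
                     if c not in ("age", "male", "education_years")]
        p_item = np.clip(config.missing_rate_items * np.exp(0.5 * age_z),
                         0, 0.8)
        for c in item_cols:
            mask = rng.random(n) < p_item
            if mask.all():  # keep every column partially observed
                mask[rng.integers(n)] = False
            frame.loc[mask, c] = np.nan
    outcome_missing = np.zeros(n, dtype=bool)
    if config.missing_rate_outcome > 0:
        p_out = np.clip(config.missing_rate_outcome * np.exp(0.4 * age_z),
                        0, 0.8)
        outcome_missing = rng.random(n) < p_out
    for j, c in enumerate(day_cols):
        col = day_mat[:, j].astype(object)
        col[outcome_missing] = np.nan
        frame[c] = col
    frame.loc[outcome_missing, OUTCOME_HDD_COL] = np.nan
    frame.loc[outcome_missing, DELTA_HDD_COL] = np.nan

    oracle = OracleEffects(pd.DataFrame({
        ID_COL: frame[ID_COL],
        "g": g, "h": h,
        "y_active_raw": y_active_raw, "y_placebo_raw": y_placebo_raw,
        "y_active": y_active, "y_placebo": y_placebo,
    }))
    dataset = TrialDataset(frame, schema)
    return dataset, oracle


def write_oracle(oracle: OracleEffects, path) -> None:
    oracle.df.to_csv(path, index=False)
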