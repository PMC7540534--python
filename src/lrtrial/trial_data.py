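"""Subject-level trial data model, validation, CSV I/O and outcome derivation.

The single currency of the pipeline is :class:`TrialDataset`: a pandas
DataFrame of one row per subject plus a :class:`FeatureSchema` describing the
baseline feature columns.  Reserved (non-feature) columns are::

    subject_id   opaque string, unique
    arm          "ACTIVE" or "PLACEBO"
    baseline_hdd heavy-drinking-day count in the 28-day pre-consent window
    day_01..     optional daily drinking statuses for the final outcome
                 window ("H" heavy, "N" non-heavy, empty = missing)
    outcome_hdd  optional heavy-drinking-day count in the outcome window
    delta_hdd    derived primary outcome, baseline_hdd - outcome_hdd

Secondary-outcome and monthly-summary columns are declared in the schema and
carried through verbatim; they are never recomputed from daily data.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

ID_COL = "subject_id"
ARM_COL = "arm"
BASELINE_HDD_COL = "baseline_hdd"
OUTCOME_HDD_COL = "outcome_hdd"
DELTA_HDD_COL = "delta_hdd"

#: Length of both the baseline and the final maintenance window, in days.
#: A config constant rather than a literal so alternative windows can be
#: analysed; every bound below derives from it.
DEFAULT_WINDOW_DAYS = 28


def day_columns(window_days: int = DEFAULT_WINDOW_DAYS) -> list[str]:
    """Names of the daily outcome-status columns, ``day_01 .. day_NN``."""
    return [f"day_{i:02d}" for i in range(1, window_days + 1)]


class Arm(str, enum.Enum):
    ACTIVE = "ACTIVE"
    PLACEBO = "PLACEBO"


class DayStatus(str, enum.Enum):
    HEAVY = "H"
    NON_HEAVY = "N"
    MISSING = "M"


class ValidationError(ValueError):
    """A dataset cell or structural invariant was violated."""


class MissingOutcomeError(ValueError):
    """Neither daily statuses nor an outcome count are available."""


# ---------------------------------------------------------------------------
# Feature schema
# ---------------------------------------------------------------------------

class FeatureKind(str, enum.Enum):
    CONTINUOUS = "continuous"
    ORDINAL = "ordinal"
    BINARY = "binary"
    CATEGORICAL = "categorical"


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one baseline feature column."""

    name: str
    kind: FeatureKind
    lo: Optional[float] = None
    hi: Optional[float] = None
    levels: Optional[tuple[str, ...]] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind in (FeatureKind.ORDINAL,):
            if self.lo is None or self.hi is None:
                raise ValueError(f"ordinal feature {self.name!r} needs bounds")
        if self.kind is FeatureKind.CATEGORICAL and not self.levels:
            raise ValueError(f"categorical feature {self.name!r} needs levels")

    @property
    def bounds(self) -> tuple[float, float]:
        if self.kind is FeatureKind.BINARY:
            return (0.0, 1.0)
        return (self.lo if self.lo is not None else -np.inf,
                self.hi if self.hi is not None else np.inf)

    def check_value(self, value) -> Optional[str]:
        """Return an error message for an out-of-range value, else None."""
        if pd.isna(value):
            return None
        if self.kind is FeatureKind.CATEGORICAL:
            if str(value) not in self.levels:
                return f"value {value!r} not in levels {self.levels}"
            return None
        lo, hi = self.bounds
        try:
            v = float(value)
        except (TypeError, ValueError):
            return f"non-numeric value {value!r}"
        if not (lo <= v <= hi):
            return f"value {v} outside [{lo}, {hi}]"
        return None


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered declaration of the feature columns of a dataset.

    ``secondary`` and ``monthly`` name pass-through outcome columns
    (end-of-study measures and per-month HDD summaries).
    """

    features: tuple[FeatureSpec, ...]
    secondary: tuple[str, ...] = ()
    monthly: tuple[str, ...] = ()
    window_days: int = DEFAULT_WINDOW_DAYS

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def __iter__(self) -> Iterator[FeatureSpec]:
        return iter(self.features)

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        feats = []
        for f in self.features:
            d: dict = {"name": f.name, "kind": f.kind.value}
            if f.lo is not None:
                d["lo"] = f.lo
            if f.hi is not None:
                d["hi"] = f.hi
            if f.levels:
                d["levels"] = list(f.levels)
            if f.label:
                d["label"] = f.label
            feats.append(d)
        return {
            "features": feats,
            "secondary": list(self.secondary),
            "monthly": list(self.monthly),
            "window_days": self.window_days,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        feats = tuple(
            FeatureSpec(
                name=f["name"],
                kind=FeatureKind(f["kind"]),
                lo=f.get("lo"),
                hi=f.get("hi"),
                levels=tuple(f["levels"]) if f.get("levels") else None,
                label=f.get("label", ""),
            )
            for f in d["features"]
        )
        return cls(
            features=feats,
            secondary=tuple(d.get("secondary", ())),
            monthly=tuple(d.get("monthly", ())),
            window_days=int(d.get("window_days", DEFAULT_WINDOW_DAYS)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One subject, as needed for record-level outcome derivation."""

    subject_id: str
    arm: Arm
    baseline_hdd: int
    outcome_days: Optional[Sequence[DayStatus]] = None
    outcome_hdd: Optional[int] = None


@dataclass(frozen=True)
class OutcomeRecord:
    """Derived primary outcome for one subject."""

    subject_id: str
    outcome_hdd: int
    delta_hdd: int


def derive_outcome(record: SubjectRecord,
                   window_days: int = DEFAULT_WINDOW_DAYS) -> OutcomeRecord:
    """Derive the primary outcome (change in heavy-drinking days).

    When daily statuses are present, days with missing data are counted as
    heavy, so ``outcome_hdd = #HEAVY + #MISSING``.  Otherwise a pre-computed
    ``outcome_hdd`` is used as-is.
    """
    if record.outcome_days is not None:
        days = list(record.outcome_days)
        if len(days) != window_days:
            raise ValidationError(
                f"subject {record.subject_id}: expected {window_days} daily "
                f"statuses, got {len(days)}")
        ohdd = sum(1 for d in days
                   if d in (DayStatus.HEAVY, DayStatus.MISSING))
    elif record.outcome_hdd is not None:
        ohdd = int(record.outcome_hdd)
    else:
        raise MissingOutcomeError(
            f"subject {record.subject_id}: no daily data and no outcome "
            "count; request imputation or drop the subject")
    if not 0 <= ohdd <= window_days:
        raise ValidationError(
            f"subject {record.subject_id}: outcome_hdd {ohdd} outside "
            f"[0, {window_days}]")
    return OutcomeRecord(record.subject_id, ohdd,
                         int(record.baseline_hdd) - ohdd)


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class TrialDataset:
    """Validated subject-level table plus its feature schema."""

    df: pd.DataFrame
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.validate()

    # -- convenience --------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> pd.Series:
        return self.df[ID_COL]

    def arm_mask(self, arm: Arm | str) -> np.ndarray:
        return (self.df[ARM_COL] == Arm(arm).value).to_numpy()

    def features_frame(self) -> pd.DataFrame:
        return self.df[self.schema.names]

    def has_day_columns(self) -> bool:
        return all(c in self.df.columns
                   for c in day_columns(self.schema.window_days))

    def record(self, i: int) -> SubjectRecord:
        row = self.df.iloc[i]
        days = None
        if self.has_day_columns():
            days = []
            for c in day_columns(self.schema.window_days):
                v = row[c]
                if pd.isna(v) or v == "":
                    days.append(DayStatus.MISSING)
                else:
                    days.append(DayStatus(str(v)))
        ohdd = None
        if OUTCOME_HDD_COL in self.df.columns and pd.notna(row.get(OUTCOME_HDD_COL)):
            ohdd = int(row[OUTCOME_HDD_COL])
        return SubjectRecord(
            subject_id=str(row[ID_COL]),
            arm=Arm(row[ARM_COL]),
            baseline_hdd=int(row[BASELINE_HDD_COL]),
            outcome_days=days,
            outcome_hdd=ohdd,
        )

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.df.copy(), self.schema)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df, schema = self.df, self.schema
        w = schema.window_days
        for col in (ID_COL, ARM_COL, BASELINE_HDD_COL):
            if col not in df.columns:
                raise ValidationError(f"missing required column {col!r}")
        dup = df[ID_COL][df[ID_COL].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate subject_id {dup.iloc[0]!r} "
                f"(row {int(dup.index[0])})")
        bad_arm = ~df[ARM_COL].isin([a.value for a in Arm])
        if bad_arm.any():
            i = int(np.flatnonzero(bad_arm.to_numpy())[0])
            raise ValidationError(
                f"row {i}, column {ARM_COL!r}: invalid arm "
                f"{df[ARM_COL].iloc[i]!r}")
        for col, lo, hi in ((BASELINE_HDD_COL, 0, w), (OUTCOME_HDD_COL, 0, w),
                            (DELTA_HDD_COL, -w, w)):
            if col not in df.columns:
                continue
            v = pd.to_numeric(df[col], errors="coerce")
            bad = v.notna() & ((v < lo) | (v > hi))
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"row {i}, column {col!r}: value {v.iloc[i]} outside "
                    f"[{lo}, {hi}]")
        if col_missing := [f for f in schema.names if f not in df.columns]:
            raise ValidationError(f"schema features absent: {col_missing}")
        known = set([ID_COL, ARM_COL, BASELINE_HDD_COL, OUTCOME_HDD_COL,
                     DELTA_HDD_COL] + day_columns(w) + schema.names
                    + list(schema.secondary) + list(schema.monthly))
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise ValidationError(f"unknown columns: {unknown}")
        for spec in schema:
            col = df[spec.name]
            for i, v in enumerate(col):
                msg = spec.check_value(v)
                if msg is not None:
                    raise ValidationError(
                        f"row {i}, column {spec.name!r}: {msg}")

    # -- outcome derivation -------------------------------------------------
    def derive_outcomes(self, policy: str = "all_heavy") -> "TrialDataset":
        """Fill ``outcome_hdd`` and ``delta_hdd`` for every subject.

        policy "all_heavy": subjects with daily data (including fully missing
        windows) have missing days counted as heavy.  policy "defer": subjects
        with no observed daily data keep a missing outcome (for downstream
        imputation); partially observed windows still use the all-heavy rule.
        """
        if policy not in ("all_heavy", "defer"):
            raise ValueError(f"unknown outcome policy {policy!r}")
        df = self.df.copy()
        w = self.schema.window_days
        out = np.full(len(df), np.nan)
        have_days = self.has_day_columns()
        for i in range(len(df)):
            rec = self.record(i)
            if (policy == "defer" and rec.outcome_days is not None
                    and all(d is DayStatus.MISSING for d in rec.outcome_days)
                    and rec.outcome_hdd is None):
                continue
            try:
                out[i] = derive_outcome(rec, w).outcome_hdd
            except MissingOutcomeError:
                if policy == "all_heavy":
                    raise
        df[OUTCOME_HDD_COL] = out
        df[DELTA_HDD_COL] = df[BASELINE_HDD_COL].to_numpy(float) - out
        ds = TrialDataset(df, self.schema)
        del have_days
        return ds


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _ordered_columns(df: pd.DataFrame, schema: FeatureSchema) -> list[str]:
    order = [ID_COL, ARM_COL, BASELINE_HDD_COL]
    for c in [OUTCOME_HDD_COL, DELTA_HDD_COL]:
        if c in df.columns:
            order.append(c)
    order += [c for c in day_columns(schema.window_days) if c in df.columns]
    order += [c for c in schema.monthly if c in df.columns]
    order += [c for c in schema.secondary if c in df.columns]
    order += schema.names
    return order


def write_trial(dataset: TrialDataset, path) -> None:
    """Write a dataset as UTF-8 CSV; missing cells are written empty."""
    df = dataset.df[_ordered_columns(dataset.df, dataset.schema)]
    df.to_csv(path, index=False)


def load_trial(path, schema: FeatureSchema) -> TrialDataset:
    """Load and validate a trial CSV against ``schema``.

    Missing cells stay missing (NaN); they are never silently zero-filled.
    """
    str_cols = {ID_COL: str, ARM_COL: str}
    for c in day_columns(schema.window_days):
        str_cols[c] = str
    for f in schema:
        if f.kind is FeatureKind.CATEGORICAL:
            str_cols[f.name] = str
    df = pd.read_csv(path, dtype=str_cols, keep_default_na=True)
    # integer-valued columns read as float when NaN present; normalise ints
    for col in (BASELINE_HDD_COL, OUTCOME_HDD_COL, DELTA_HDD_COL):
        if col in df.columns and df[col].notna().all():
            as_num = pd.to_numeric(df[col])
            if (as_num == as_num.round()).all():
                df[col] = as_num.astype(int)
    return TrialDataset(df, schema)


def datasets_equal(a: TrialDataset, b: TrialDataset, tol: float = 0.0) -> bool:
    """Cell-level equality ignoring dtype; missing must match missing."""
    ca = _ordered_columns(a.df, a.schema)
    cb = _ordered_columns(b.df, b.schema)
    if ca != cb or len(a.df) != len(b.df):
        return False
    for c in ca:
        xa, xb = a.df[c], b.df[c]
        na, nb = xa.isna(), xb.isna()
        if not (na == nb).all():
            return False
        xa, xb = xa[~na], xb[~nb]
        try:
            fa = pd.to_numeric(xa)
            fb = pd.to_numeric(xb)
            if not np.allclose(fa, fb, rtol=0, atol=tol):
                return False
        except (ValueError, TypeError):
            if not (xa.astype(str) == xb.astype(str)).all():
                return False
    return True
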