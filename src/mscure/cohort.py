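"""Subject-level cohort container and delimited-text I/O.

The canonical table has one row per subject::

    id,age,sex,stage,metastasis,chemotherapy,bmi,t_rec,d_rec,t_death,d_death

All times are months since resection, on a single shared follow-up clock:
recurrence and death share one censoring time, so a subject censored for
recurrence (``d_rec = 0``) carries ``t_rec`` equal to the death/censoring
time ``t_death``.  BMI may be missing (empty field); every modelled
covariate must be present.

Categorical covariates are dummy-encoded against fixed reference levels
(female, stage II, no chemotherapy, no metastasis), yielding the design
columns ``age, sex_male, stage_III, stage_IV, chemotherapy, metastasis``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "COVARIATES",
    "CovariateSpec",
    "DEFAULT_SPEC",
    "Cohort",
    "CohortSchemaError",
    "CohortParseError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]

COLUMNS = (
    "id", "age", "sex", "stage", "metastasis", "chemotherapy",
    "bmi", "t_rec", "d_rec", "t_death", "d_death",
)

#: design-matrix covariate columns produced by :meth:`Cohort.design`
COVARIATES = ("age", "sex_male", "stage_III", "stage_IV", "chemotherapy", "metastasis")


class CohortSchemaError(ValueError):
    """A required column is missing from the input table."""


class CohortParseError(ValueError):
    """A field could not be parsed; the message names the offending row id."""


class CohortValidationError(ValueError):
    """One or more rows violate a cohort invariant.

    Attributes
    ----------
    ids : list of str
        Identifiers of the offending subjects.
    """

    def __init__(self, message: str, ids: Sequence[str]):
        super().__init__(f"{message}: {list(ids)}")
        self.ids = list(ids)


@dataclass(frozen=True)
class CovariateSpec:
    """Categorical levels and reference coding for the modelled covariates."""

    sex_levels: tuple[str, str] = ("female", "male")          # reference first
    stage_levels: tuple[str, ...] = ("II", "III", "IV")       # reference first
    yesno_levels: tuple[str, str] = ("no", "yes")             # reference first

    @property
    def covariates(self) -> tuple[str, ...]:
        return COVARIATES


DEFAULT_SPEC = CovariateSpec()

_NUMERIC = {"age": False, "bmi": True, "t_rec": False, "t_death": False}
_INDICATOR = ("d_rec", "d_death")


def _parse_numeric(raw: pd.Series, name: str, ids: pd.Series, allow_missing: bool) -> pd.Series:
    stripped = raw.astype(str).str.strip()
    vals = np.empty(len(stripped))
    for i, (s, rid) in enumerate(zip(stripped, ids)):
        if s == "":
            if not allow_missing:
                raise CohortParseError(
                    f"missing value in column {name!r} (row id={rid!r})")
            vals[i] = np.nan
            continue
        try:
            vals[i] = float(s)  # exact strtod: repr round-trips
        except ValueError:
            raise CohortParseError(
                f"non-numeric value {s!r} in column {name!r} (row id={rid!r})"
            ) from None
    return pd.Series(vals, index=raw.index)


class Cohort:
    """An immutable, validated collection of subject records.

    Parameters
    ----------
    frame : pandas.DataFrame
        Typed table with the canonical columns (see module docstring).
    spec : CovariateSpec, optional
        Categorical coding; the default matches the reference levels used
        throughout (female / stage II / no / no).
    validate : bool
        Skip invariant checks when False (used by diagnostics that must
        accept deliberately broken tables).
    """

    def __init__(self, frame: pd.DataFrame, spec: CovariateSpec = DEFAULT_SPEC,
                 validate: bool = True):
        self.frame = frame.reset_index(drop=True)
        self.spec = spec
        if validate:
            self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[dict], spec: CovariateSpec = DEFAULT_SPEC,
                     validate: bool = True) -> "Cohort":
        df = pd.DataFrame.from_records(records, columns=list(COLUMNS))
        df["id"] = df["id"].astype(str)
        for col in ("age", "bmi", "t_rec", "t_death"):
            df[col] = df[col].astype(float)
        for col in _INDICATOR:
            df[col] = df[col].astype(int)
        return cls(df, spec=spec, validate=validate)

    def _validate(self) -> None:
        df = self.frame
        ids = df["id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise CohortValidationError("duplicate subject ids", dup.unique())

        for col, levels in (("sex", self.spec.sex_levels),
                            ("stage", self.spec.stage_levels),
                            ("metastasis", self.spec.yesno_levels),
                            ("chemotherapy", self.spec.yesno_levels)):
            bad = ~df[col].isin(levels)
            if bad.any():
                raise CohortValidationError(
                    f"invalid {col} value (expected one of {levels})", ids[bad])

        for col in _INDICATOR:
            bad = ~df[col].isin((0, 1))
            if bad.any():
                raise CohortValidationError(f"{col} must be 0 or 1", ids[bad])

        for col in ("age", "t_rec", "t_death"):
            arr = df[col].to_numpy(dtype=float)
            bad = ~np.isfinite(arr)
            if col != "age":
                bad |= arr < 0
            if bad.any():
                raise CohortValidationError(f"{col} must be finite and non-negative", ids[bad])

        t_rec = df["t_rec"].to_numpy(dtype=float)
        t_death = df["t_death"].to_numpy(dtype=float)
        d_rec = df["d_rec"].to_numpy(dtype=float)
        d_death = df["d_death"].to_numpy(dtype=float)

        bad = t_rec > t_death
        if bad.any():
            raise CohortValidationError("t_rec exceeds t_death", ids[bad])
        # death recorded at the recurrence instant is allowed only if observed
        bad = (d_rec == 1) & (t_rec == t_death) & (d_death == 0)
        if bad.any():
            raise CohortValidationError(
                "recurrence at the censoring time without observed death", ids[bad])
        # shared censoring clock: no recurrence => t_rec is the follow-up time
        bad = (d_rec == 0) & (t_rec != t_death)
        if bad.any():
            raise CohortValidationError(
                "censored-for-recurrence subjects must have t_rec == t_death "
                "(shared censoring time)", ids[bad])

    # -- basic container protocol -------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> pd.Series:
        return self.frame["id"]

    def equals(self, other: "Cohort") -> bool:
        return self.frame.equals(other.frame)

    # -- design matrix -------------------------------------------------

    def design(self, center_age: float | None = None) -> pd.DataFrame:
        """Dummy-encoded numeric table for model fitting.

        Returns columns ``id``, the six covariates of :data:`COVARIATES`
        (age optionally centered at ``center_age``), and the outcome
        columns ``t_rec, d_rec, t_death, d_death``.
        """
        df = self.frame
        out = pd.DataFrame({"id": df["id"].astype(str)})
        age = df["age"].astype(float)
        out["age"] = age - center_age if center_age is not None else age
        out["sex_male"] = (df["sex"] == self.spec.sex_levels[1]).astype(float)
        out["stage_III"] = (df["stage"] == "III").astype(float)
        out["stage_IV"] = (df["stage"] == "IV").astype(float)
        out["chemotherapy"] = (df["chemotherapy"] == "yes").astype(float)
        out["metastasis"] = (df["metastasis"] == "yes").astype(float)
        for col in ("t_rec", "d_rec", "t_death", "d_death"):
            out[col] = df[col].to_numpy(dtype=float)
        return out


def read_cohort(path: str | Path | io.TextIOBase,
                spec: CovariateSpec = DEFAULT_SPEC) -> Cohort:
    """Read and validate a cohort CSV.

    Raises :class:`CohortSchemaError` for missing columns,
    :class:`CohortParseError` for unparseable fields (naming the row id) and
    :class:`CohortValidationError` for invariant violations (listing ids).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    ids = raw["id"].astype(str)

    df = pd.DataFrame({"id": ids})
    df["age"] = _parse_numeric(raw["age"], "age", ids, allow_missing=False)
    for col in ("sex", "stage", "metastasis", "chemotherapy"):
        df[col] = raw[col].astype(str).str.strip()
    df["bmi"] = _parse_numeric(raw["bmi"], "bmi", ids, allow_missing=True)
    df["t_rec"] = _parse_numeric(raw["t_rec"], "t_rec", ids, allow_missing=False)
    df["t_death"] = _parse_numeric(raw["t_death"], "t_death", ids, allow_missing=False)
    for col in _INDICATOR:
        vals = _parse_numeric(raw[col], col, ids, allow_missing=False)
        frac = vals != np.round(vals)
        if frac.any():
            raise CohortParseError(
                f"non-integer value in column {col!r} (row id={ids[frac].iloc[0]!r})")
        df[col] = vals.astype(int)
    return Cohort(df[list(COLUMNS)], spec=spec)


def write_cohort(cohort: Cohort, path: str | Path | io.TextIOBase) -> None:
    """Write a cohort as CSV that :func:`read_cohort` reproduces exactly."""
    df = cohort.frame.copy()
    df.to_csv(path, index=False, columns=list(COLUMNS))
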