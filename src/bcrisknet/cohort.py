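"""Cohort data model: one row per woman, raw survey/clinical variables plus outcome.

The canonical in-memory container is a :class:`pandas.DataFrame` with the columns
listed in :data:`COHORT_COLUMNS`; :class:`WomanRecord` is a validated single-row
view used where per-record semantics matter (error messages naming the offending
field, round-tripping single records).

Missing values are encoded as empty CSV fields / ``NaN`` / ``None``.  A missing
variable never aborts categorization — the woman is simply left unlabelled for
that variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CohortValidationError",
    "WomanRecord",
    "COHORT_COLUMNS",
    "ENUM_DOMAINS",
    "COMORBIDITY_GROUPS",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_cohort",
    "compute_reproductive_quartiles",
]


class CohortValidationError(ValueError):
    """A record (or cohort) violates the data-model invariants.

    ``field`` names the offending column when a single variable is at fault.
    """

    def __init__(self, message: str, field: Optional[str] = None):
        super().__init__(message)
        self.field = field


COMORBIDITY_GROUPS = (
    "cardiometabolic",
    "endocrine",
    "intestinal",
    "neuropsychiatric",
    "autoimmune",
)

#: enum-valued columns and their admissible (non-missing) values
ENUM_DOMAINS = {
    "density": ("A", "B", "C", "D"),
    "family_history": ("none", "female", "male", "male_and_female"),
    "education": ("primary_secondary", "high_school", "university"),
    "occupation": ("unemployed", "employed", "retired", "night_shift"),
    "oral_contraception": ("never_or_lt1y", "y1_5", "gt5y"),
    "smoking": ("never", "c1_5", "c6_10", "gt10"),
    "alcohol": ("none", "weekly_or_less", "several_per_week", "binge_weekly"),
}

WCRF_ITEMS = (
    "wcrf_physical_activity",
    "wcrf_energy_dense_food",
    "wcrf_plant_based_diet",
    "wcrf_red_meat",
    "wcrf_salt",
    "wcrf_varied_diet",
)
for _item in WCRF_ITEMS:
    ENUM_DOMAINS[_item] = ("low", "medium", "high")

YESNO_COLUMNS = (
    "pregnancy",
    "breastfeeding",
    "crt",
    "ovarian_stimulation",
    "hrt",
    "weight_gain_menopause",
)

COMORBIDITY_COLUMNS = tuple(f"comorb_{g}" for g in COMORBIDITY_GROUPS)

#: documented CSV header, in order
COHORT_COLUMNS = (
    "id",
    "age",
    "density",
    "menarche_age",
    "menopause_age",
    "family_history",
    "education",
    "occupation",
    "comorbidity_count",
    *COMORBIDITY_COLUMNS,
    *YESNO_COLUMNS[:3],  # pregnancy, breastfeeding, crt
    "oral_contraception",
    "ovarian_stimulation",
    "hrt",
    "bmi",
    "weight_gain_menopause",
    "smoking",
    "alcohol",
    *WCRF_ITEMS,
    "bc_case",
)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v == ""


@dataclass
class WomanRecord:
    """One woman's raw variables plus the dichotomous breast-cancer outcome."""

    id: str
    age: int
    bc_case: int
    density: Optional[str] = None
    menarche_age: Optional[float] = None
    menopause_age: Optional[float] = None
    family_history: Optional[str] = None
    education: Optional[str] = None
    occupation: Optional[str] = None
    comorbidity_count: Optional[int] = None
    comorbidity_flags: frozenset = field(default_factory=frozenset)
    pregnancy: Optional[int] = None
    breastfeeding: Optional[int] = None
    crt: Optional[int] = None
    oral_contraception: Optional[str] = None
    ovarian_stimulation: Optional[int] = None
    hrt: Optional[int] = None
    bmi: Optional[float] = None
    weight_gain_menopause: Optional[int] = None
    smoking: Optional[str] = None
    alcohol: Optional[str] = None
    wcrf_physical_activity: Optional[str] = None
    wcrf_energy_dense_food: Optional[str] = None
    wcrf_plant_based_diet: Optional[str] = None
    wcrf_red_meat: Optional[str] = None
    wcrf_salt: Optional[str] = None
    wcrf_varied_diet: Optional[str] = None

    def validate(self) -> "WomanRecord":
        if _is_missing(self.age) or self.age < 40:
            raise CohortValidationError(
                f"age must be >= 40 (post-menopausal cohort), got {self.age!r}",
                field="age",
            )
        if not _is_missing(self.menopause_age):
            if self.menopause_age > self.age:
                raise CohortValidationError(
                    "menopause_age must not exceed age", field="menopause_age"
                )
            if not _is_missing(self.menarche_age) and not (
                self.menarche_age < self.menopause_age
            ):
                raise CohortValidationError(
                    "menarche_age must be below menopause_age", field="menarche_age"
                )
        if not _is_missing(self.bmi) and self.bmi <= 0:
            raise CohortValidationError("bmi must be positive", field="bmi")
        if not _is_missing(self.comorbidity_count) and self.comorbidity_count < 0:
            raise CohortValidationError(
                "comorbidity_count must be non-negative", field="comorbidity_count"
            )
        for col, domain in ENUM_DOMAINS.items():
            v = getattr(self, col)
            if not _is_missing(v) and v not in domain:
                raise CohortValidationError(
                    f"{col}={v!r} not in {domain}", field=col
                )
        for col in YESNO_COLUMNS + ("bc_case",):
            v = getattr(self, col)
            if not _is_missing(v) and v not in (0, 1):
                raise CohortValidationError(
                    f"{col} must be 0/1 or missing, got {v!r}", field=col
                )
        for g in self.comorbidity_flags:
            if g not in COMORBIDITY_GROUPS:
                raise CohortValidationError(
                    f"unknown comorbidity group {g!r}", field="comorbidity_flags"
                )
        return self

    @classmethod
    def from_series(cls, row: pd.Series) -> "WomanRecord":
        kwargs = {}
        for f in fields(cls):
            if f.name == "comorbidity_flags":
                flags = frozenset(
                    g for g in COMORBIDITY_GROUPS if row.get(f"comorb_{g}", 0) == 1
                )
                kwargs[f.name] = flags
            elif f.name in row.index:
                v = row[f.name]
                kwargs[f.name] = None if _is_missing(v) else v
        return cls(**kwargs)

    def to_series(self) -> pd.Series:
        d = {}
        for col in COHORT_COLUMNS:
            if col in COMORBIDITY_COLUMNS:
                g = col[len("comorb_"):]
                d[col] = int(g in self.comorbidity_flags)
            else:
                d[col] = getattr(self, col)
        return pd.Series(d)


_INT_COLS = ("age", "comorbidity_count", "bc_case") + YESNO_COLUMNS + COMORBIDITY_COLUMNS
_FLOAT_COLS = ("menarche_age", "menopause_age", "bmi")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (empty fields = missing) and validate it."""
    df = pd.read_csv(path, dtype={"id": str})
    return validate_cohort(df)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized invariant checks; raises :class:`CohortValidationError`."""
    missing_cols = [c for c in ("id", "age", "bc_case") if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"missing required columns: {missing_cols}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise CohortValidationError(f"duplicate woman id {dup!r}", field="id")
    if (df["age"] < 40).any():
        raise CohortValidationError("age must be >= 40 for every record", field="age")
    if "menopause_age" in df.columns:
        bad = df["menopause_age"] > df["age"]
        if bad.any():
            raise CohortValidationError(
                "menopause_age exceeds age for some records", field="menopause_age"
            )
        if "menarche_age" in df.columns:
            bad = df["menarche_age"] >= df["menopause_age"]
            if bad.fillna(False).any():
                raise CohortValidationError(
                    "menarche_age must be below menopause_age", field="menarche_age"
                )
    if "bmi" in df.columns and (df["bmi"] <= 0).fillna(False).any():
        raise CohortValidationError("bmi must be positive", field="bmi")
    for col, domain in ENUM_DOMAINS.items():
        if col in df.columns:
            vals = df[col].dropna()
            bad = ~vals.isin(domain)
            if bad.any():
                raise CohortValidationError(
                    f"{col} contains values outside {domain}: "
                    f"{sorted(vals[bad].unique())}",
                    field=col,
                )
    return df


def compute_reproductive_quartiles(
    cohort: pd.DataFrame | Iterable[WomanRecord],
    method: str = "linear",
) -> np.ndarray:
    """Quartile cut points of the reproductive period (menopause − menarche age).

    Returns the three inner cut points ``[Q1, Q2, Q3]`` partitioning the observed
    periods into four classes; a value equal to a cut point belongs to the lower
    class.  ``method`` is passed to :func:`numpy.quantile` (default linear
    interpolation between order statistics).

    Raises :class:`CohortValidationError` if fewer than 4 women have both ages.
    """
    if isinstance(cohort, pd.DataFrame):
        periods = (cohort["menopause_age"] - cohort["menarche_age"]).dropna().to_numpy()
    else:
        periods = np.array(
            [
                r.menopause_age - r.menarche_age
                for r in cohort
                if not _is_missing(r.menarche_age) and not _is_missing(r.menopause_age)
            ]
        )
    if periods.size < 4:
        raise CohortValidationError(
            f"need >= 4 records with menarche and menopause ages, got {periods.size}"
        )
    cuts = np.quantile(periods, [0.25, 0.5, 0.75], method=method)
    return cuts
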