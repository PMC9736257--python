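"""Deterministic categorization of raw variables into per-profile characteristics.

Each woman is described on three profiles:

* profile 1 — non-modifiable factors: age band, BI-RADS breast density,
  reproductive-period quartile class, years since menopause (≤5 / >5),
  first-line family history of breast cancer;
* profile 2 — personal history: education, occupation, comorbidity class,
  pregnancy, breastfeeding, chest radiation therapy, oral-contraception
  duration, ovarian stimulation, hormone replacement therapy, BMI class,
  weight gain during menopause, age band;
* profile 3 — lifestyle: smoking level, alcohol level, the six WCRF
  compliance scores, age band.

A catalog is a list of variable specs whose category predicates are mutually
exclusive and exhaustive over non-missing values; applying it to a cohort
yields one label per non-missing variable per woman.  Catalogs serialize to
YAML/JSON so every cut point is auditable and overridable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import (
    CohortValidationError,
    WomanRecord,
    compute_reproductive_quartiles,
    validate_cohort,
)

__all__ = [
    "VariableSpec",
    "CharacteristicCatalog",
    "ProfileAssignment",
    "ProfileCategorizer",
    "default_catalog",
    "categorize",
    "categorize_cohort",
    "fertility_labels",
]

#: age-band inner edges (left-closed bins: 40–44, 45–49, ..., 60–64, 65+)
AGE_EDGES = (45.0, 50.0, 55.0, 60.0, 65.0)
AGE_LABELS = ("Age40-44", "Age45-49", "Age50-54", "Age55-59", "Age60-64", "Age65+")

BMI_EDGES = (18.5, 25.0, 30.0)
BMI_LABELS = ("BMI_UnderW", "BMI_NormW", "BMI_OverW", "BMI_Obese")


def _derive(df: pd.DataFrame, source: str) -> pd.Series:
    """Resolve a (possibly derived) source column on the cohort frame."""
    if source in df.columns:
        return df[source]
    if source == "reproductive_period":
        return df["menopause_age"] - df["menarche_age"]
    if source == "years_since_menopause":
        return df["age"] - df["menopause_age"]
    raise KeyError(f"unknown source column {source!r}")


@dataclass
class VariableSpec:
    """One variable's categorization rule.

    ``kind='enum'`` maps raw values to labels via ``mapping``;
    ``kind='interval'`` bins a numeric source at ``cuts`` into ``len(cuts)+1``
    classes labelled by ``labels``.  With ``closed='right'`` a value equal to a
    cut belongs to the lower class (x ≤ cut); with ``closed='left'`` it opens
    the upper class (x < cut), as in the BMI convention where 25.0 is already
    overweight.
    """

    name: str
    kind: str  # 'enum' | 'interval'
    source: str
    mapping: dict = dc_field(default_factory=dict)
    cuts: tuple = ()
    labels: tuple = ()
    closed: str = "right"

    def __post_init__(self):
        if self.kind == "enum":
            labs = list(dict.fromkeys(self.mapping.values()))
            self.labels = tuple(self.labels) or tuple(labs)
        elif self.kind == "interval":
            if len(self.labels) != len(self.cuts) + 1:
                raise ValueError(
                    f"{self.name}: need {len(self.cuts) + 1} labels, "
                    f"got {len(self.labels)}"
                )
            if self.closed not in ("left", "right"):
                raise ValueError(f"{self.name}: closed must be 'left' or 'right'")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")

    def apply(self, df: pd.DataFrame) -> pd.Series:
        src = _derive(df, self.source)
        if self.kind == "enum":
            return src.map(self.mapping)
        x = pd.to_numeric(src, errors="coerce").to_numpy(dtype=float)
        # searchsorted side: 'left' puts x == cut into the lower bin for
        # right-closed classes, 'right' for left-closed ones.
        side = "left" if self.closed == "right" else "right"
        idx = np.searchsorted(np.asarray(self.cuts, dtype=float), x, side=side)
        out = np.where(np.isnan(x), None, np.asarray(self.labels, dtype=object)[
            np.clip(idx, 0, len(self.labels) - 1)
        ])
        return pd.Series(out, index=df.index, dtype=object)

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "source": self.source}
        if self.kind == "enum":
            d["mapping"] = dict(self.mapping)
        else:
            d["cuts"] = [float(c) for c in self.cuts]
            d["labels"] = list(self.labels)
            d["closed"] = self.closed
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSpec":
        return cls(
            name=d["name"],
            kind=d["kind"],
            source=d["source"],
            mapping=d.get("mapping", {}),
            cuts=tuple(d.get("cuts", ())),
            labels=tuple(d.get("labels", ())),
            closed=d.get("closed", "right"),
        )


@dataclass
class CharacteristicCatalog:
    """The categorization rules for one profile."""

    profile_id: int
    variables: list  # list[VariableSpec]

    def __post_init__(self):
        labels = self.labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate category labels in profile "
                             f"{self.profile_id}: {dupes}")

    def labels(self) -> list:
        return [l for v in self.variables for l in v.labels]

    def variable_names(self) -> list:
        return [v.name for v in self.variables]

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        """Wide label frame: one column per variable, values = label or None."""
        return pd.DataFrame(
            {v.name: v.apply(df) for v in self.variables}, index=df.index
        )

    def to_dict(self) -> dict:
        return {
            "profile_id": self.profile_id,
            "variables": [v.to_dict() for v in self.variables],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CharacteristicCatalog":
        return cls(
            profile_id=d["profile_id"],
            variables=[VariableSpec.from_dict(v) for v in d["variables"]],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CharacteristicCatalog":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CharacteristicCatalog":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ProfileAssignment:
    """One woman's category labels (one per non-missing variable) for a profile."""

    woman_id: str
    profile_id: int
    labels: dict  # variable name -> label

    def label_set(self) -> frozenset:
        return frozenset(self.labels.values())


def fertility_labels(cuts: Sequence[float], min_period: Optional[float] = None) -> tuple:
    """Human-readable labels for the four reproductive-period quartile classes.

    Integer cut points yield range labels in the cohort-report style
    (``Fert15-35``, ``Fert36-38``, ``Fert39-40``, ``Fert41+``); fractional cuts
    fall back to inequality labels so classes stay unambiguous.
    """
    cuts = [float(c) for c in cuts]
    integral = all(abs(c - round(c)) < 1e-9 for c in cuts)
    if integral:
        c = [int(round(x)) for x in cuts]
        lo = f"Fert{int(min_period)}-{c[0]}" if min_period is not None else f"Fert<={c[0]}"
        labs = [lo]
        for a, b in zip(c[:-1], c[1:]):
            labs.append(f"Fert{a + 1}-{b}" if a + 1 < b else f"Fert{b}")
        labs.append(f"Fert{c[-1] + 1}+")
        return tuple(labs)
    labs = [f"Fert<={cuts[0]:g}"]
    for a, b in zip(cuts[:-1], cuts[1:]):
        labs.append(f"Fert({a:g}-{b:g}]")
    labs.append(f"Fert>{cuts[-1]:g}")
    return tuple(labs)


def _age_spec() -> VariableSpec:
    return VariableSpec(
        name="age_band", kind="interval", source="age",
        cuts=AGE_EDGES, labels=AGE_LABELS, closed="left",
    )


def default_catalog(
    profile_id: int,
    fert_cuts: Sequence[float] = (35.0, 38.0, 40.0),
    fert_min: Optional[float] = None,
    separate_binge: bool = False,
    fert_label_override: Optional[Sequence[str]] = None,
) -> CharacteristicCatalog:
    """The package's default categorization rules for one profile.

    ``fert_cuts`` are the reproductive-period quartile cut points (profile 1
    only); pass the cohort-fitted values from
    :func:`bcrisknet.cohort.compute_reproductive_quartiles`.  ``separate_binge``
    keeps weekly binge drinking as its own category instead of folding it into
    the highest drinking level (the default, since binge drinkers are <1% of a
    typical cohort and would form a near-empty node).
    """
    if profile_id == 1:
        variables = [
            _age_spec(),
            VariableSpec(
                name="density", kind="enum", source="density",
                mapping={"A": "BI-A", "B": "BI-B", "C": "BI-C", "D": "BI-D"},
            ),
            VariableSpec(
                name="reproductive_period", kind="interval",
                source="reproductive_period",
                cuts=tuple(float(c) for c in fert_cuts),
                labels=tuple(fert_label_override)
                if fert_label_override is not None
                else fertility_labels(fert_cuts, fert_min),
                closed="right",
            ),
            VariableSpec(
                name="menopause_length", kind="interval",
                source="years_since_menopause",
                cuts=(5.0,), labels=("MenopUpTo5", "Menop6+"), closed="right",
            ),
            VariableSpec(
                name="family_history", kind="enum", source="family_history",
                mapping={
                    "none": "NoFamhist",
                    "female": "FeFamhist",
                    "male": "MaFamhist",
                    "male_and_female": "MaFeFamhist",
                },
            ),
        ]
    elif profile_id == 2:
        variables = [
            VariableSpec(
                name="education", kind="enum", source="education",
                mapping={
                    "primary_secondary": "Edu_PriSec",
                    "high_school": "Edu_HigSch",
                    "university": "Edu_Univ",
                },
            ),
            VariableSpec(
                name="occupation", kind="enum", source="occupation",
                mapping={
                    "unemployed": "Oc_Unempl",
                    "employed": "Oc_Empl",
                    "retired": "Oc_Retir",
                    "night_shift": "Oc_NightSh",
                },
            ),
            VariableSpec(
                name="comorbidity_class", kind="interval",
                source="comorbidity_count",
                cuts=(0.0, 1.0), labels=("Comorb_NO", "Comorb_1", "Comorb_2+"),
                closed="right",
            ),
            VariableSpec(
                name="pregnancy", kind="enum", source="pregnancy",
                mapping={1: "Pregn_Yes", 0: "Pregn_NO"},
            ),
            VariableSpec(
                name="breastfeeding", kind="enum", source="breastfeeding",
                mapping={1: "BrFeed_Yes", 0: "BrFeed_NO"},
            ),
            VariableSpec(
                name="crt", kind="enum", source="crt",
                mapping={1: "CRT_Yes", 0: "CRT_NO"},
            ),
            VariableSpec(
                name="oral_contraception", kind="enum", source="oral_contraception",
                mapping={
                    "never_or_lt1y": "OrContr_NO",
                    "y1_5": "OrContr_UpTo5",
                    "gt5y": "OrContr_6+",
                },
            ),
            VariableSpec(
                name="ovarian_stimulation", kind="enum", source="ovarian_stimulation",
                mapping={1: "OvStim_Yes", 0: "OvStim_NO"},
            ),
            VariableSpec(
                name="hrt", kind="enum", source="hrt",
                mapping={1: "TOS_Yes", 0: "TOS_NO"},
            ),
            VariableSpec(
                name="bmi_class", kind="interval", source="bmi",
                cuts=BMI_EDGES, labels=BMI_LABELS, closed="left",
            ),
            VariableSpec(
                name="weight_gain_menopause", kind="enum",
                source="weight_gain_menopause",
                mapping={1: "WGainMNP_Yes", 0: "WGainMNP_No"},
            ),
            _age_spec(),
        ]
    elif profile_id == 3:
        alcohol_map = {
            "none": "Drink_NO",
            "weekly_or_less": "Drink_Low",
            "several_per_week": "Drink_Med" if separate_binge else "Drink_Hig",
            "binge_weekly": "Drink_Hig",
        }
        variables = [
            VariableSpec(
                name="smoking", kind="enum", source="smoking",
                mapping={
                    "never": "Smok_NO", "c1_5": "Smok_Low",
                    "c6_10": "Smok_Med", "gt10": "Smok_Hig",
                },
            ),
            VariableSpec(name="alcohol", kind="enum", source="alcohol",
                         mapping=alcohol_map),
        ]
        wcrf_prefix = {
            "wcrf_physical_activity": "PhisAct",
            "wcrf_energy_dense_food": "LimCalFood",
            "wcrf_plant_based_diet": "VegFood",
            "wcrf_red_meat": "LimRedMeat",
            "wcrf_salt": "LimSalt",
            "wcrf_varied_diet": "VaryDiet",
        }
        for col, prefix in wcrf_prefix.items():
            variables.append(
                VariableSpec(
                    name=col, kind="enum", source=col,
                    mapping={
                        "low": f"{prefix}_Low",
                        "medium": f"{prefix}_Med",
                        "high": f"{prefix}_Hig",
                    },
                )
            )
        variables.append(_age_spec())
    else:
        raise ValueError(f"profile_id must be 1, 2 or 3, got {profile_id}")
    return CharacteristicCatalog(profile_id=profile_id, variables=variables)


class ProfileCategorizer(BaseEstimator, TransformerMixin):
    """Transformer mapping a raw cohort frame to per-woman characteristic labels.

    ``fit`` learns the only data-dependent cut points (the reproductive-period
    quartiles, profile 1) and freezes the catalog; ``transform`` emits a long
    assignment frame with columns ``(id, profile, variable, label)`` — one row
    per non-missing variable per woman.

    Parameters
    ----------
    profile : int
        Which of the three profiles to categorize (1, 2 or 3).
    quartile_method : str
        Quantile interpolation passed to numpy (default ``"linear"``).
    separate_binge : bool
        Keep binge drinking as its own alcohol category (profile 3).
    fert_cuts : sequence of 3 floats, optional
        Explicit reproductive-period cut points; bypasses fitting them.
    """

    def __init__(self, profile: int = 1, quartile_method: str = "linear",
                 separate_binge: bool = False, fert_cuts=None):
        self.profile = profile
        self.quartile_method = quartile_method
        self.separate_binge = separate_binge
        self.fert_cuts = fert_cuts

    def fit(self, X: pd.DataFrame, y=None):
        validate_cohort(X)
        if self.profile == 1:
            if self.fert_cuts is not None:
                cuts = np.asarray(self.fert_cuts, dtype=float)
                fmin = None
            else:
                cuts = compute_reproductive_quartiles(X, method=self.quartile_method)
                periods = (X["menopause_age"] - X["menarche_age"]).dropna()
                fmin = float(periods.min())
            labels_override = None
            if np.any(np.diff(cuts) <= 0):
                # tied cut points: some classes are zero-width; keep the
                # classes ordinal and strictly ordered so labels stay unique
                self.degenerate_cuts_ = True
                cuts = cuts + np.arange(3) * 1e-9
                labels_override = ("FertQ1", "FertQ2", "FertQ3", "FertQ4")
            else:
                self.degenerate_cuts_ = False
            self.fert_cuts_ = cuts
            self.catalog_ = default_catalog(
                1, fert_cuts=cuts, fert_min=fmin,
                separate_binge=self.separate_binge,
                fert_label_override=labels_override,
            )
        else:
            self.fert_cuts_ = None
            self.degenerate_cuts_ = False
            self.catalog_ = default_catalog(
                self.profile, separate_binge=self.separate_binge
            )
        self.labels_ = self.catalog_.labels()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "catalog_"):
            raise RuntimeError("ProfileCategorizer must be fitted before transform")
        wide = self.catalog_.apply(X)
        long = wide.assign(id=X["id"].values).melt(
            id_vars="id", var_name="variable", value_name="label"
        )
        long = long.dropna(subset=["label"]).reset_index(drop=True)
        long.insert(1, "profile", self.profile)
        # stable order: woman, then catalog variable order
        order = {v: i for i, v in enumerate(self.catalog_.variable_names())}
        long = long.sort_values(
            ["id", "variable"], key=lambda s: s.map(order) if s.name == "variable" else s
        ).reset_index(drop=True)
        return long


def categorize(record: WomanRecord, catalog: CharacteristicCatalog) -> ProfileAssignment:
    """Categorize a single validated record against a frozen catalog."""
    record.validate()
    df = record.to_series().to_frame().T
    df["age"] = pd.to_numeric(df["age"])
    for c in ("menarche_age", "menopause_age", "bmi", "comorbidity_count",
              "pregnancy", "breastfeeding", "crt", "ovarian_stimulation",
              "hrt", "weight_gain_menopause"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    wide = catalog.apply(df).iloc[0]
    labels = {v: l for v, l in wide.items() if l is not None and not pd.isna(l)}
    return ProfileAssignment(
        woman_id=record.id, profile_id=catalog.profile_id, labels=labels
    )


def categorize_cohort(
    cohort: pd.DataFrame, profiles=(1, 2, 3), **kwargs
) -> dict:
    """Fit-and-transform a categorizer per profile; returns {profile: long frame}."""
    out = {}
    for p in profiles:
        out[p] = ProfileCategorizer(profile=p, **kwargs).fit(cohort).transform(cohort)
    return out
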