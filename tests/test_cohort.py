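"""Cohort data model and categorization rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrisknet.catalog import (
    ProfileCategorizer,
    categorize,
    default_catalog,
    fertility_labels,
)
from bcrisknet.cohort import (
    CohortValidationError,
    WomanRecord,
    compute_reproductive_quartiles,
    read_cohort_csv,
    validate_cohort,
    write_cohort_csv,
)


def _record(**overrides):
    base = dict(
        id="w1", age=55, bc_case=0, density="B", menarche_age=12.0,
        menopause_age=50.0, family_history="none", education="high_school",
        occupation="employed", comorbidity_count=1, pregnancy=1,
        breastfeeding=1, crt=0, oral_contraception="y1_5",
        ovarian_stimulation=0, hrt=0, bmi=24.0, weight_gain_menopause=0,
        smoking="never", alcohol="none", wcrf_physical_activity="medium",
        wcrf_energy_dense_food="medium", wcrf_plant_based_diet="medium",
        wcrf_red_meat="medium", wcrf_salt="medium", wcrf_varied_diet="medium",
    )
    base.update(overrides)
    return WomanRecord(**base)


class TestWomanRecord:
    def test_valid_record_passes(self):
        _record().validate()

    @pytest.mark.parametrize(
        "overrides, field",
        [
            ({"age": 39}, "age"),
            ({"menopause_age": 60.0}, "menopause_age"),
            ({"menarche_age": 50.0}, "menarche_age"),
            ({"bmi": -1.0}, "bmi"),
            ({"density": "E"}, "density"),
            ({"smoking": "heavy"}, "smoking"),
            ({"pregnancy": 2}, "pregnancy"),
        ],
    )
    def test_invariant_violations_name_the_field(self, overrides, field):
        with pytest.raises(CohortValidationError) as exc:
            _record(**overrides).validate()
        assert exc.value.field == field

    def test_missing_values_are_legal(self):
        _record(density=None, menarche_age=None, menopause_age=None).validate()


class TestCohortFrame:
    def test_csv_round_trip(self, tmp_path, small_cohort):
        cohort, _ = small_cohort
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        back = read_cohort_csv(path)
        assert len(back) == len(cohort)
        assert list(back["id"]) == list(cohort["id"])
        assert back["bc_case"].sum() == cohort["bc_case"].sum()

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({"id": ["a", "a"], "age": [50, 51], "bc_case": [0, 0]})
        with pytest.raises(CohortValidationError, match="duplicate"):
            validate_cohort(df)


class TestReproductiveQuartiles:
    def test_linear_interpolation_example(self):
        df = pd.DataFrame(
            {"menarche_age": [10.0] * 4, "menopause_age": [40.0, 45.0, 50.0, 55.0]}
        )
        cuts = compute_reproductive_quartiles(df)
        # periods {30, 35, 40, 45}: order-statistic interpolation
        assert cuts == pytest.approx([33.75, 37.5, 41.25])

    def test_insufficient_records(self):
        df = pd.DataFrame({"menarche_age": [12.0, 12.0], "menopause_age": [50.0, 51.0]})
        with pytest.raises(CohortValidationError, match=">= 4"):
            compute_reproductive_quartiles(df)

    def test_constant_periods_flagged_degenerate(self):
        df = pd.DataFrame(
            {
                "id": [f"w{i}" for i in range(6)],
                "age": [55] * 6,
                "bc_case": [0] * 6,
                "menarche_age": [12.0] * 6,
                "menopause_age": [50.0] * 6,
            }
        )
        cat = ProfileCategorizer(profile=1).fit(df)
        assert cat.degenerate_cuts_
        # labels still unique so the catalog stays valid
        assert len(set(cat.labels_)) == len(cat.labels_)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        periods=st.lists(
            st.integers(min_value=15, max_value=45), min_size=8, max_size=60
        )
    )
    def test_quartiles_partition_into_near_equal_classes(self, periods):
        df = pd.DataFrame(
            {
                "menarche_age": [12.0] * len(periods),
                "menopause_age": [12.0 + p for p in periods],
            }
        )
        cuts = compute_reproductive_quartiles(df)
        arr = np.asarray(periods, dtype=float)
        sizes = [
            (arr <= cuts[0]).sum(),
            ((arr > cuts[0]) & (arr <= cuts[1])).sum(),
            ((arr > cuts[1]) & (arr <= cuts[2])).sum(),
            (arr > cuts[2]).sum(),
        ]
        assert sum(sizes) == len(periods)
        n_ties = sum(int((arr == c).sum()) for c in cuts)
        assert max(sizes) - min(sizes) <= max(n_ties, 1) + len(periods) % 4 + 3


class TestFertilityLabels:
    def test_integer_cuts_reproduce_report_style(self):
        labs = fertility_labels([35, 38, 40], min_period=15)
        assert labs == ("Fert15-35", "Fert36-38", "Fert39-40", "Fert41+")

    def test_fractional_cuts_fall_back_to_inequalities(self):
        labs = fertility_labels([33.75, 37.5, 41.25])
        assert labs[0] == "Fert<=33.75"
        assert labs[-1] == "Fert>41.25"
        assert len(set(labs)) == 4


class TestCategorize:
    @pytest.mark.parametrize(
        "bmi, label",
        [(18.4, "BMI_UnderW"), (18.5, "BMI_NormW"), (24.9, "BMI_NormW"),
         (25.0, "BMI_OverW"), (29.9, "BMI_OverW"), (30.0, "BMI_Obese")],
    )
    def test_bmi_boundaries(self, bmi, label):
        cat = default_catalog(2)
        a = categorize(_record(bmi=bmi), cat)
        assert a.labels["bmi_class"] == label

    @pytest.mark.parametrize(
        "age, menopause, label",
        [(55, 50.0, "MenopUpTo5"), (56, 50.0, "Menop6+")],
    )
    def test_menopause_length_boundary(self, age, menopause, label):
        cat = default_catalog(1)
        a = categorize(_record(age=age, menopause_age=menopause), cat)
        assert a.labels["menopause_length"] == label

    def test_missing_variables_yield_no_label(self):
        cat = default_catalog(1)
        rec = _record(density=None, menarche_age=None, menopause_age=None,
                      family_history=None)
        a = categorize(rec, cat)
        assert set(a.labels) == {"age_band"}
        assert a.labels["age_band"] == "Age55-59"

    def test_profile_label_counts_match_design(self):
        assert len(default_catalog(1).labels()) == 20
        assert len(default_catalog(2).labels()) == 35
        assert len(default_catalog(3).labels()) == 31
        assert len(default_catalog(3, separate_binge=True).labels()) == 32

    def test_binge_folds_into_highest_level(self):
        cat = default_catalog(3)
        a = categorize(_record(alcohol="binge_weekly"), cat)
        b = categorize(_record(alcohol="several_per_week"), cat)
        assert a.labels["alcohol"] == b.labels["alcohol"] == "Drink_Hig"
        cat2 = default_catalog(3, separate_binge=True)
        assert categorize(_record(alcohol="binge_weekly"), cat2).labels["alcohol"] \
            == "Drink_Hig"
        assert categorize(_record(alcohol="several_per_week"), cat2).labels["alcohol"] \
            == "Drink_Med"


class TestProfileCategorizer:
    def test_idempotent_and_deterministic(self, small_cohort):
        cohort, _ = small_cohort
        a = ProfileCategorizer(profile=1).fit(cohort).transform(cohort)
        b = ProfileCategorizer(profile=1).fit(cohort).transform(cohort)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("profile", [1, 2, 3])
    def test_label_count_equals_non_missing_variables(self, small_cohort, profile):
        cohort, _ = small_cohort
        cat = ProfileCategorizer(profile=profile).fit(cohort)
        long = cat.transform(cohort)
        wide = cat.catalog_.apply(cohort)
        expected = wide.notna().sum().sum()
        assert len(long) == expected
        # at most one label per (woman, variable)
        assert not long.duplicated(subset=["id", "variable"]).any()
        assert set(long["label"]).issubset(set(cat.labels_))

    def test_catalog_yaml_round_trip(self, tmp_path, small_cohort):
        cohort, _ = small_cohort
        cat = ProfileCategorizer(profile=1).fit(cohort)
        path = tmp_path / "catalog.yaml"
        cat.catalog_.to_yaml(path)
        from bcrisknet.catalog import CharacteristicCatalog

        back = CharacteristicCatalog.from_yaml(path)
        assert back.labels() == cat.catalog_.labels()
        pd.testing.assert_frame_equal(
            back.apply(cohort), cat.catalog_.apply(cohort)
        )
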