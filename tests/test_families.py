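"""Community combinations, family grouping and outcome screening."""

import numpy as np
import pandas as pd
import pytest

from bcrisknet.families import (
    FamilyScreener,
    combination_table,
    combine,
    group_families,
    screen_families,
    two_by_two_or,
)
from bcrisknet.simulate import generate_cohort, planted_params
from bcrisknet.stats import fit_logistic


def _series(values, ids=None):
    ids = ids or [f"w{i}" for i in range(len(values))]
    return pd.Series(values, index=ids)


class TestCombine:
    def test_identical_triples_collapse(self):
        p1 = _series(["a", "a"])
        p2 = _series(["x", "x"])
        p3 = _series([1, 1])
        y = _series([0, 1])
        comb = combine(p1, p2, p3, y)
        tab = combination_table(comb)
        assert len(tab) == 1
        assert tab.iloc[0]["n_women"] == 2
        assert tab.iloc[0]["n_cases"] == 1

    def test_id_mismatch_rejected(self):
        p1 = _series(["a", "b"])
        p2 = pd.Series(["x"], index=["w0"])
        with pytest.raises(ValueError, match="ids"):
            combine(p1, p2, p1, _series([0, 0]))

    def test_distinct_count_bounded_by_product(self):
        rng = np.random.default_rng(0)
        n = 500
        p1 = _series(rng.integers(0, 4, n))
        p2 = _series(rng.integers(0, 4, n))
        p3 = _series(rng.integers(0, 5, n))
        y = _series(rng.integers(0, 2, n))
        tab = combination_table(combine(p1, p2, p3, y))
        assert len(tab) <= 4 * 4 * 5

    def test_independent_groups_match_product_frequencies(self):
        """With independently planted groups the combination frequencies
        factorize, up to 3 binomial standard errors."""
        params = planted_params(n_women=20_000, k=2, separation=1.0)
        _, truth = generate_cohort(params, seed=11)
        comb = combine(
            _series(truth["group_p1"].values, list(truth["id"])),
            _series(truth["group_p2"].values, list(truth["id"])),
            _series(truth["group_p3"].values, list(truth["id"])),
            _series(truth["bc_case"].values, list(truth["id"])),
        )
        tab = combination_table(comb)
        n = len(comb)
        for row in tab.itertuples():
            expected = (1 / 2) ** 3
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(row.n_women / n - expected) < 3 * se


class TestGroupFamilies:
    def test_definitional_grouping(self):
        comb = combine(
            _series(["a", "a", "b"]),
            _series(["x", "x", "x"]),
            _series([1, 2, 1]),
            _series([0, 0, 1]),
        )
        fam = group_families(comb)
        assert len(fam) == 2
        ax = fam[(fam.c1 == "a") & (fam.c2 == "x")].iloc[0]
        assert ax["n_combinations"] == 2
        assert ax["n_women"] == 2

    def test_families_partition_cohort(self, small_cohort):
        cohort, truth = small_cohort
        ids = list(truth["id"])
        comb = combine(
            _series(truth["group_p1"].values, ids),
            _series(truth["group_p2"].values, ids),
            _series(truth["group_p3"].values, ids),
            _series(truth["bc_case"].values, ids),
        )
        fam = group_families(comb)
        assert fam["n_women"].sum() == len(cohort)
        assert fam["n_cases"].sum() == truth["bc_case"].sum()


class TestScreening:
    def test_reported_two_by_two_example(self):
        # family of 193 women with 9 of the 100 cohort cases, n = 5601
        or_, se, z, p, corrected = two_by_two_or(9, 184, 91, 5317)
        assert or_ == pytest.approx(2.858, abs=5e-4)
        assert not corrected

    def test_null_family_or_one(self):
        # prevalence identical inside and outside: OR = 1, p = 1
        or_, _, z, p, _ = two_by_two_or(10, 90, 100, 900)
        assert or_ == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_cell_haldane_corrected(self):
        or_, _, _, _, corrected = two_by_two_or(0, 50, 100, 5000)
        assert corrected
        assert or_ > 0

    def test_closed_form_matches_iterative_logistic(self):
        """Central cross-check: exp(coef) of the single-indicator logistic
        fit equals the 2x2 odds ratio to 1e-6 on the log scale."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = 2000
            member = rng.random(n) < 0.25
            p = np.where(member, 0.05, 0.02)
            y = (rng.random(n) < p).astype(float)
            a = int(((member) & (y == 1)).sum())
            b = int(((member) & (y == 0)).sum())
            c = int(((~member) & (y == 1)).sum())
            d = int(((~member) & (y == 0)).sum())
            if min(a, b, c, d) == 0:
                continue
            or_, *_ = two_by_two_or(a, b, c, d)
            fit = fit_logistic(member.astype(float), y)
            assert np.log(or_) == pytest.approx(fit.coef[1], abs=1e-6)

    def test_selected_direction_matches_prevalence(self):
        comb = pd.DataFrame(
            {
                "id": [f"w{i}" for i in range(1000)],
                "c1": ["a"] * 250 + ["b"] * 750,
                "c2": ["x"] * 1000,
                "c3": [0] * 1000,
                "bc_case": [1] * 30 + [0] * 220 + [1] * 10 + [0] * 740,
            }
        )
        fam = screen_families(group_families(comb), 1000, 40)
        high = fam[fam.c1 == "a"].iloc[0]
        low = fam[fam.c1 == "b"].iloc[0]
        assert high["or"] > 1 > low["or"]
        assert high["prevalence"] > low["prevalence"]

    def test_invariant_to_label_renaming(self):
        rng = np.random.default_rng(10)
        n = 800
        comb = pd.DataFrame(
            {
                "id": [f"w{i}" for i in range(n)],
                "c1": rng.integers(0, 3, n),
                "c2": rng.integers(0, 2, n),
                "c3": rng.integers(0, 2, n),
                "bc_case": (rng.random(n) < 0.05).astype(int),
            }
        )
        fam_a = screen_families(group_families(comb), n, int(comb.bc_case.sum()))
        renamed = comb.assign(c1=comb.c1.map({0: "zebra", 1: "ox", 2: "ant"}))
        fam_b = screen_families(group_families(renamed), n, int(comb.bc_case.sum()))
        a = fam_a.sort_values(["n_women", "n_cases"]).reset_index(drop=True)
        b = fam_b.sort_values(["n_women", "n_cases"]).reset_index(drop=True)
        assert np.allclose(a["or"], b["or"])
        assert np.allclose(a["p"], b["p"])

    def test_degenerate_cohort_rejected(self):
        comb = pd.DataFrame(
            {"id": ["w0", "w1"], "c1": ["a", "a"], "c2": ["x", "x"],
             "c3": [0, 0], "bc_case": [0, 0]}
        )
        with pytest.raises(ValueError, match="at least one case"):
            screen_families(group_families(comb), 2, 0)


class TestFamilyScreener:
    def test_fit_from_raw_profiles(self, small_cohort):
        cohort, truth = small_cohort
        ids = list(truth["id"])
        scr = FamilyScreener().fit(
            (
                _series(truth["group_p1"].values, ids),
                _series(truth["group_p2"].values, ids),
                _series(truth["group_p3"].values, ids),
            ),
            _series(truth["bc_case"].values, ids),
        )
        assert scr.n_women_ == len(cohort)
        assert scr.families_["n_women"].sum() == scr.n_women_
        assert scr.families_["n_cases"].sum() == scr.n_cases_
        assert "small_sample" in scr.families_.columns

    def test_zero_case_cohort_not_screened(self):
        comb = pd.DataFrame(
            {"id": ["w0", "w1"], "c1": ["a", "a"], "c2": ["x", "y"],
             "c3": [0, 0], "bc_case": [0, 0]}
        )
        scr = FamilyScreener().fit(comb)
        assert not scr.screened_
        assert len(scr.selected_) == 0

    def test_duplicate_woman_rejected(self):
        comb = pd.DataFrame(
            {"id": ["w0", "w0"], "c1": ["a", "a"], "c2": ["x", "x"],
             "c3": [0, 1], "bc_case": [0, 1]}
        )
        with pytest.raises(ValueError, match="exactly once"):
            FamilyScreener().fit(comb)
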