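"""Seeded synthetic cohorts with planted per-profile group structure.

The study cohort itself is not shareable, so every downstream stage is
exercised on a simulated stand-in.  The generative model:

* each woman independently draws one latent group per profile (an optional
  correlation knob copies the profile-1 group into profile 2 with probability
  ``rho12``);
* given her group, each categorical variable of that profile is drawn from a
  group-specific multinomial; category draws are then back-mapped to plausible
  raw values (a BMI class to a BMI value inside the class interval, an age
  band to an integer age, ...);
* the breast-cancer outcome is Bernoulli with logit equal to an intercept
  plus coefficients on selected category indicators, plus optional extra
  log-odds for chosen (profile-1, profile-2) group pairs (planted high-risk
  families).

Defaults emulate the scale of the real cohort: 5601 post-menopausal women,
target outcome prevalence 1.8%, group counts and mixing weights shaped like
the published community sizes (4 / 4 / 5 groups), and planted effects echoing
the published risk directions (age, extreme breast density, male first-line
family history up; high physical-activity and salt compliance down).  The
intercept is calibrated so the exact expected prevalence hits the target.

Identical parameters + seed give byte-identical cohorts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import COHORT_COLUMNS, COMORBIDITY_GROUPS

__all__ = [
    "ProfileModel",
    "OutcomeModel",
    "SimulationParams",
    "default_params",
    "planted_params",
    "generate_cohort",
    "expected_prevalence",
    "calibrate_intercept",
]

_TOL = 1e-9

# raw-value back-mapping ranges
AGE_BANDS = {
    "40-44": (40, 44), "45-49": (45, 49), "50-54": (50, 54),
    "55-59": (55, 59), "60-64": (60, 64), "65+": (65, 80),
}
FERT_RANGES = {"q1": (20, 35), "q2": (36, 38), "q3": (39, 40), "q4": (41, 45)}
MENOP_RANGES = {"le5": (0, 5), "gt5": (6, 25)}
BMI_RANGES = {
    "under": (16.0, 18.4), "normal": (18.5, 24.9),
    "over": (25.0, 29.9), "obese": (30.0, 40.0),
}
COMORB_FLAG_P = np.array([0.35, 0.28, 0.08, 0.22, 0.07])  # matches COMORBIDITY_GROUPS

#: category spaces per profile variable (raw-value classes, not graph labels)
PROFILE_CATEGORIES = {
    1: {
        "age_band": list(AGE_BANDS),
        "density": ["A", "B", "C", "D"],
        "fert_class": list(FERT_RANGES),
        "menop_class": list(MENOP_RANGES),
        "family_history": ["none", "female", "male", "male_and_female"],
    },
    2: {
        "education": ["primary_secondary", "high_school", "university"],
        "occupation": ["unemployed", "employed", "retired", "night_shift"],
        "comorb_class": ["0", "1", "2+"],
        "pregnancy": ["yes", "no"],
        "breastfeeding": ["yes", "no"],
        "crt": ["yes", "no"],
        "oral_contraception": ["never_or_lt1y", "y1_5", "gt5y"],
        "ovarian_stimulation": ["yes", "no"],
        "hrt": ["yes", "no"],
        "bmi_class": list(BMI_RANGES),
        "weight_gain_menopause": ["yes", "no"],
    },
    3: {
        "smoking": ["never", "c1_5", "c6_10", "gt10"],
        "alcohol": ["none", "weekly_or_less", "several_per_week", "binge_weekly"],
        "wcrf_physical_activity": ["low", "medium", "high"],
        "wcrf_energy_dense_food": ["low", "medium", "high"],
        "wcrf_plant_based_diet": ["low", "medium", "high"],
        "wcrf_red_meat": ["low", "medium", "high"],
        "wcrf_salt": ["low", "medium", "high"],
        "wcrf_varied_diet": ["low", "medium", "high"],
    },
}


class SimulationParamsError(ValueError):
    """Invalid probability tables or mixing weights."""


@dataclass
class ProfileModel:
    """One profile's planted group structure.

    ``weights``: mixing weights over the K latent groups.
    ``tables``: for each variable, a (K, n_categories) row-stochastic matrix.
    """

    profile_id: int
    weights: np.ndarray
    tables: dict  # variable -> (K, n_cat) array

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.tables = {v: np.asarray(t, dtype=float) for v, t in self.tables.items()}

    @property
    def k(self) -> int:
        return self.weights.size

    def validate(self):
        if abs(self.weights.sum() - 1.0) > _TOL or (self.weights < 0).any():
            raise SimulationParamsError(
                f"profile {self.profile_id}: mixing weights must be a distribution"
            )
        cats = PROFILE_CATEGORIES[self.profile_id]
        for var, table in self.tables.items():
            if var not in cats:
                raise SimulationParamsError(
                    f"profile {self.profile_id}: unknown variable {var!r}"
                )
            expect = (self.k, len(cats[var]))
            if table.shape != expect:
                raise SimulationParamsError(
                    f"profile {self.profile_id}, {var}: table shape "
                    f"{table.shape} != {expect}"
                )
            if (table < 0).any() or np.abs(table.sum(axis=1) - 1.0).max() > _TOL:
                raise SimulationParamsError(
                    f"profile {self.profile_id}, {var}: rows must be distributions"
                )
        missing = set(cats) - set(self.tables)
        if missing:
            raise SimulationParamsError(
                f"profile {self.profile_id}: missing tables for {sorted(missing)}"
            )
        return self


@dataclass
class OutcomeModel:
    """Logistic outcome model on category indicators (log-odds scale)."""

    intercept: float = 0.0
    coefficients: dict = field(default_factory=dict)  # (variable, category) -> beta
    family_effects: dict = field(default_factory=dict)  # (g1, g2) -> extra log-odds


@dataclass
class SimulationParams:
    n_women: int = 5601
    profiles: dict = field(default_factory=dict)  # profile_id -> ProfileModel
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    rho12: float = 0.0  # P(profile-2 group copied from profile-1 group)
    shared_groups: bool = False  # one cohort-wide group drives all profiles
    seed: int = 0

    def validate(self) -> "SimulationParams":
        if self.n_women <= 0:
            raise SimulationParamsError("n_women must be positive")
        if set(self.profiles) != {1, 2, 3}:
            raise SimulationParamsError("profiles 1, 2 and 3 must all be specified")
        for pm in self.profiles.values():
            pm.validate()
        if not 0.0 <= self.rho12 <= 1.0:
            raise SimulationParamsError("rho12 must lie in [0, 1]")
        if self.shared_groups and len({pm.k for pm in self.profiles.values()}) != 1:
            raise SimulationParamsError(
                "shared_groups requires the same K in every profile"
            )
        var_profile = {
            v: p for p, cats in PROFILE_CATEGORIES.items() for v in cats
        }
        for (var, cat) in self.outcome.coefficients:
            if var not in var_profile:
                raise SimulationParamsError(f"outcome coefficient on unknown {var!r}")
            if cat not in PROFILE_CATEGORIES[var_profile[var]][var]:
                raise SimulationParamsError(
                    f"outcome coefficient on unknown category {var}={cat!r}"
                )
        prev = expected_prevalence(self)
        if not 0.0 < prev < 1.0:
            raise SimulationParamsError(
                f"expected outcome prevalence {prev} outside (0, 1)"
            )
        return self


def _pref_table(categories, preferences, separation):
    """Row-stochastic K x n table: mass ``separation`` spread over each
    group's preferred categories (proportional to their weights), the rest
    uniform over all categories."""
    n = len(categories)
    k = len(preferences)
    table = np.full((k, n), (1.0 - separation) / n)
    for g, prefs in enumerate(preferences):
        total = sum(w for _, w in prefs)
        for cat, w in prefs:
            table[g, categories.index(cat)] += separation * w / total
    return table


def default_params(
    n_women: int = 5601,
    target_prevalence: float = 0.018,
    separation: float = 0.8,
    rho12: float = 0.0,
    seed: int = 0,
) -> SimulationParams:
    """The package's stated synthetic world (see module docstring)."""
    c = PROFILE_CATEGORIES

    p1_prefs = {
        # oldest women, low density, long reproductive period, long menopause
        "age_band": [
            [("60-64", 1), ("65+", 1)],
            [("50-54", 1), ("55-59", 1)],
            [("40-44", 1), ("45-49", 1)],
            [("55-59", 1), ("60-64", 1)],
        ],
        "density": [
            [("A", 1), ("B", 1.5)],
            [("C", 1.5), ("D", 0.6)],
            [("B", 1), ("C", 1)],
            [("B", 1), ("C", 1)],
        ],
        "fert_class": [
            [("q3", 1), ("q4", 1)],
            [("q2", 1), ("q3", 1)],
            [("q1", 1)],
            [("q2", 1)],
        ],
        "menop_class": [
            [("gt5", 1)],
            [("le5", 1)],
            [("le5", 1)],
            [("gt5", 1)],
        ],
        "family_history": [
            [("none", 1)],
            [("female", 1), ("male", 0.03)],
            [("none", 1), ("female", 0.5)],
            [("male_and_female", 1)],
        ],
    }
    p1 = ProfileModel(
        profile_id=1,
        weights=np.array([2615, 2312, 626, 48], dtype=float) / 5601,
        tables={v: _pref_table(c[1][v], p1_prefs[v], separation) for v in c[1]},
    )

    p2_prefs = {
        "education": [
            [("primary_secondary", 1)],
            [("university", 1)],
            [("high_school", 1)],
            [("high_school", 1)],
        ],
        "occupation": [
            [("unemployed", 1.2), ("retired", 0.3)],
            [("employed", 1.2), ("night_shift", 0.1)],
            [("employed", 1)],
            [("employed", 1), ("unemployed", 1)],
        ],
        "comorb_class": [
            [("2+", 1)],
            [("1", 1)],
            [("0", 1)],
            [("1", 1)],
        ],
        "pregnancy": [
            [("yes", 1)],
            [("no", 1)],
            [("yes", 1)],
            [("yes", 1)],
        ],
        "breastfeeding": [
            [("yes", 1)],
            [("no", 1)],
            [("yes", 1)],
            [("yes", 1)],
        ],
        "crt": [
            [("yes", 0.3), ("no", 1)],
            [("no", 1)],
            [("no", 1)],
            [("no", 1)],
        ],
        "oral_contraception": [
            [("never_or_lt1y", 1)],
            [("gt5y", 1)],
            [("y1_5", 1)],
            [("y1_5", 1)],
        ],
        "ovarian_stimulation": [
            [("no", 1)],
            [("yes", 0.4), ("no", 1)],
            [("no", 1)],
            [("no", 1)],
        ],
        "hrt": [
            [("yes", 0.6), ("no", 1)],
            [("no", 1)],
            [("no", 1)],
            [("no", 1)],
        ],
        "bmi_class": [
            [("over", 1), ("obese", 0.5)],
            [("normal", 1)],
            [("normal", 1)],
            [("under", 1), ("normal", 0.5)],
        ],
        "weight_gain_menopause": [
            [("yes", 1)],
            [("yes", 1), ("no", 1)],
            [("yes", 1), ("no", 1)],
            [("no", 1)],
        ],
    }
    p2 = ProfileModel(
        profile_id=2,
        weights=np.array([2255, 2009, 1003, 334], dtype=float) / 5601,
        tables={v: _pref_table(c[2][v], p2_prefs[v], separation) for v in c[2]},
    )

    wcrf = ["wcrf_physical_activity", "wcrf_energy_dense_food",
            "wcrf_plant_based_diet", "wcrf_red_meat", "wcrf_salt",
            "wcrf_varied_diet"]
    p3_prefs = {
        "smoking": [
            [("gt10", 1)],
            [("c1_5", 1)],
            [("c1_5", 1), ("gt10", 0.5)],
            [("never", 1)],
            [("c6_10", 1)],
        ],
        "alcohol": [
            [("weekly_or_less", 1)],
            [("several_per_week", 1)],
            [("several_per_week", 1), ("binge_weekly", 0.05)],
            [("none", 1)],
            [("weekly_or_less", 1)],
        ],
    }
    for item in wcrf:
        p3_prefs[item] = [
            [("high", 1)],
            [("medium", 1)],
            [("low", 1)],
            [("medium", 1), ("high", 1)],
            [("medium", 1)],
        ]
    p3 = ProfileModel(
        profile_id=3,
        weights=np.array([1852, 1699, 1125, 555, 370], dtype=float) / 5601,
        tables={v: _pref_table(c[3][v], p3_prefs[v], separation) for v in c[3]},
    )

    outcome = OutcomeModel(
        intercept=0.0,
        coefficients={
            ("age_band", "60-64"): 0.35,
            ("age_band", "65+"): 0.70,
            ("density", "D"): math.log(2.5),
            ("family_history", "male"): math.log(5.5),
            ("wcrf_physical_activity", "high"): math.log(0.4),
            ("wcrf_salt", "high"): math.log(0.6),
        },
    )
    params = SimulationParams(
        n_women=n_women,
        profiles={1: p1, 2: p2, 3: p3},
        outcome=outcome,
        rho12=rho12,
        seed=seed,
    )
    calibrate_intercept(params, target_prevalence)
    return params.validate()


def planted_params(
    n_women: int,
    k: int = 3,
    separation: float = 0.9,
    target_prevalence: float = 0.02,
    family_effects: dict | None = None,
    shared_groups: bool = False,
    seed: int = 0,
) -> SimulationParams:
    """A deliberately simple world: K equally weighted groups per profile,
    each preferring one category per variable (round-robin over the category
    list), within-group preferred-category mass ``separation``.

    With ``shared_groups=True`` one cohort-wide group drives all three
    profiles, so every profile's variables — including the single raw age
    shared by the three catalogs — carry the same planted structure; this is
    the clean setting for community-recovery experiments.  With independent
    groups (the default) the age band, generated from the profile-1 group,
    leaks a rival block structure into the other two profiles' graphs.
    """
    profiles = {}
    for p, cats in PROFILE_CATEGORIES.items():
        tables = {}
        for var, levels in cats.items():
            prefs = [[(levels[g % len(levels)], 1)] for g in range(k)]
            tables[var] = _pref_table(levels, prefs, separation)
        profiles[p] = ProfileModel(
            profile_id=p, weights=np.full(k, 1.0 / k), tables=tables
        )
    params = SimulationParams(
        n_women=n_women,
        profiles=profiles,
        outcome=OutcomeModel(family_effects=dict(family_effects or {})),
        shared_groups=shared_groups,
        seed=seed,
    )
    calibrate_intercept(params, target_prevalence)
    return params.validate()


# ---------------------------------------------------------------------------
# exact expected prevalence


def _var_profile_map():
    return {v: p for p, cats in PROFILE_CATEGORIES.items() for v in cats}


def expected_prevalence(params: SimulationParams) -> float:
    """Exact outcome prevalence by summation over the discrete covariate law.

    Conditional on the group triple, the involved variables are independent,
    and only the distinct coefficient values per variable matter, so each
    variable collapses to a few (log-odds, probability) atoms before the
    product is enumerated.
    """
    om = params.outcome
    vp = _var_profile_map()
    involved: dict = {}
    for (var, cat), beta in om.coefficients.items():
        involved.setdefault(var, {})[cat] = beta

    p1, p2, p3 = (params.profiles[i] for i in (1, 2, 3))
    if params.shared_groups:
        triples = ((g, g, g) for g in range(p1.k))
    else:
        triples = itertools.product(range(p1.k), range(p2.k), range(p3.k))
    prev = 0.0
    for g1, g2, g3 in triples:
        if params.shared_groups:
            w = p1.weights[g1]
        else:
            w12 = params.rho12 * (1.0 if g2 == g1 % p2.k else 0.0) + (
                1.0 - params.rho12
            ) * p2.weights[g2]
            w = p1.weights[g1] * w12 * p3.weights[g3]
        if w == 0.0:
            continue
        base = om.intercept + om.family_effects.get((g1, g2), 0.0)
        group_of = {1: g1, 2: g2, 3: g3}
        atom_sets = []
        for var, betas in involved.items():
            profile = params.profiles[vp[var]]
            probs = profile.tables[var][group_of[vp[var]]]
            cats = PROFILE_CATEGORIES[vp[var]][var]
            atoms: dict = {}
            for cat, pr in zip(cats, probs):
                b = betas.get(cat, 0.0)
                atoms[b] = atoms.get(b, 0.0) + pr
            atom_sets.append(list(atoms.items()))
        total = 0.0
        for combo in itertools.product(*atom_sets):
            lp = base + sum(b for b, _ in combo)
            pr = math.prod(q for _, q in combo)
            total += pr / (1.0 + math.exp(-lp))
        prev += w * total
    return prev


def calibrate_intercept(params: SimulationParams, target: float) -> float:
    """Set the outcome intercept so the exact expected prevalence equals
    ``target``; returns the intercept."""
    if not 0.0 < target < 1.0:
        raise SimulationParamsError("target prevalence must lie in (0, 1)")

    def f(b0):
        params.outcome.intercept = b0
        return expected_prevalence(params) - target

    b0 = brentq(f, -20.0, 10.0, xtol=1e-12)
    params.outcome.intercept = float(b0)
    return float(b0)


# ---------------------------------------------------------------------------
# cohort generation


def _draw_categories(rng, groups, table, categories):
    """Vectorized per-group multinomial draw."""
    n = groups.size
    out = np.empty(n, dtype=object)
    u = rng.random(n)
    cum = np.cumsum(table, axis=1)
    idx = (u[:, None] > cum[groups]).sum(axis=1)
    cats = np.asarray(categories, dtype=object)
    out[:] = cats[np.clip(idx, 0, len(categories) - 1)]
    return out


def generate_cohort(params: SimulationParams, seed: int | None = None):
    """Draw a cohort and its ground truth.

    Returns ``(cohort, truth)`` where ``cohort`` follows the documented CSV
    schema (:data:`bcrisknet.cohort.COHORT_COLUMNS`) and ``truth`` holds the
    latent group per profile, the linear predictor and the outcome
    probability per woman.
    """
    params.validate()
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    rng_groups, rng_cats, rng_back, rng_out = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n = params.n_women
    p1, p2, p3 = (params.profiles[i] for i in (1, 2, 3))

    g1 = rng_groups.choice(p1.k, size=n, p=p1.weights)
    if params.shared_groups:
        g2 = g1.copy()
        g3 = g1.copy()
    else:
        g2 = rng_groups.choice(p2.k, size=n, p=p2.weights)
        if params.rho12 > 0:
            copy = rng_groups.random(n) < params.rho12
            g2 = np.where(copy, g1 % p2.k, g2)
        g3 = rng_groups.choice(p3.k, size=n, p=p3.weights)
    groups = {1: g1, 2: g2, 3: g3}

    draws: dict = {}
    for pid, pm in ((1, p1), (2, p2), (3, p3)):
        for var in PROFILE_CATEGORIES[pid]:
            draws[var] = _draw_categories(
                rng_cats, groups[pid], pm.tables[var], PROFILE_CATEGORIES[pid][var]
            )

    # --- back-map categories to raw values -------------------------------
    def band_uniform(values, ranges):
        lo = np.array([ranges[v][0] for v in values], dtype=float)
        hi = np.array([ranges[v][1] for v in values], dtype=float)
        return lo, hi

    lo, hi = band_uniform(draws["age_band"], AGE_BANDS)
    age = rng_back.integers(lo.astype(int), hi.astype(int) + 1)

    lo, hi = band_uniform(draws["menop_class"], MENOP_RANGES)
    ys = rng_back.integers(lo.astype(int), hi.astype(int) + 1)
    ys = np.minimum(ys, age - 40)  # menopause at 40 or later
    menopause_age = age - ys

    lo, hi = band_uniform(draws["fert_class"], FERT_RANGES)
    period = rng_back.integers(lo.astype(int), hi.astype(int) + 1)
    period = np.minimum(period, menopause_age - 9)  # menarche age >= 9
    menarche_age = menopause_age - period

    lo, hi = band_uniform(draws["bmi_class"], BMI_RANGES)
    bmi = np.round(lo + rng_back.random(n) * (hi - lo), 1)

    comorb_class = draws["comorb_class"]
    many = rng_back.integers(2, 5, size=n)
    count = np.where(
        comorb_class == "0", 0, np.where(comorb_class == "1", 1, many)
    ).astype(int)
    # top-`count` comorbidity groups via the Gumbel trick (vectorized
    # weighted sampling without replacement)
    gumbel = rng_back.gumbel(size=(n, len(COMORBIDITY_GROUPS)))
    keys = np.log(COMORB_FLAG_P)[None, :] + gumbel
    ranks = np.argsort(np.argsort(-keys, axis=1), axis=1)
    flags = (ranks < count[:, None]).astype(int)

    yes = lambda var: (draws[var] == "yes").astype(int)

    # --- outcome ----------------------------------------------------------
    lp = np.full(n, params.outcome.intercept, dtype=float)
    for (var, cat), beta in params.outcome.coefficients.items():
        lp += beta * (draws[var] == cat)
    for (a, b), beta in params.outcome.family_effects.items():
        lp += beta * ((g1 == a) & (g2 == b))
    p_out = 1.0 / (1.0 + np.exp(-lp))
    bc = (rng_out.random(n) < p_out).astype(int)

    width = len(str(n))
    ids = [f"w{i:0{width}d}" for i in range(1, n + 1)]
    cohort = pd.DataFrame(
        {
            "id": ids,
            "age": age.astype(int),
            "density": draws["density"],
            "menarche_age": menarche_age.astype(float),
            "menopause_age": menopause_age.astype(float),
            "family_history": draws["family_history"],
            "education": draws["education"],
            "occupation": draws["occupation"],
            "comorbidity_count": count,
            **{
                f"comorb_{g}": flags[:, i]
                for i, g in enumerate(COMORBIDITY_GROUPS)
            },
            "pregnancy": yes("pregnancy"),
            "breastfeeding": yes("breastfeeding"),
            "crt": yes("crt"),
            "oral_contraception": draws["oral_contraception"],
            "ovarian_stimulation": yes("ovarian_stimulation"),
            "hrt": yes("hrt"),
            "bmi": bmi,
            "weight_gain_menopause": yes("weight_gain_menopause"),
            "smoking": draws["smoking"],
            "alcohol": draws["alcohol"],
            "wcrf_physical_activity": draws["wcrf_physical_activity"],
            "wcrf_energy_dense_food": draws["wcrf_energy_dense_food"],
            "wcrf_plant_based_diet": draws["wcrf_plant_based_diet"],
            "wcrf_red_meat": draws["wcrf_red_meat"],
            "wcrf_salt": draws["wcrf_salt"],
            "wcrf_varied_diet": draws["wcrf_varied_diet"],
            "bc_case": bc,
        },
        columns=list(COHORT_COLUMNS),
    )
    truth = pd.DataFrame(
        {
            "id": ids,
            "group_p1": g1,
            "group_p2": g2,
            "group_p3": g3,
            "linear_predictor": lp,
            "p_outcome": p_out,
            "bc_case": bc,
        }
    )
    return cohort, truth
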