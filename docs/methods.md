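# Methods

## The problem and the approach

`bcrisknet` stratifies a cohort of post-menopausal women attending breast
screening into data-driven *risk-profile families* and screens those families
against a dichotomous breast-cancer (BC) outcome. Each woman is described on
three profiles of categorical characteristics:

1. **non-modifiable factors** — age band, BI-RADS mammographic density (A–D),
   reproductive-period quartile class, years since menopause (≤5 / >5), and
   first-line family history of BC;
2. **personal history** — education, occupation, comorbidity class (0/1/≥2),
   pregnancy, breastfeeding, chest radiation therapy, oral-contraception
   duration, ovarian stimulation, hormone replacement therapy, BMI class,
   menopausal weight gain, age band;
3. **lifestyle** — smoking level, alcohol level, the six WCRF compliance
   scores (physical activity, energy-dense-food limitation, plant-based diet,
   red/cured-meat limitation, salt limitation, varied diet), age band.

For each profile, the cohort becomes an **affiliation graph**: one node per
woman, one node per characteristic carried by at least one woman, an edge from
each woman to each of her characteristics, and an edge between two
characteristics whenever at least one woman carries both. The graph is
undirected, simple and analyzed unweighted (the co-occurrence multiplicity is
kept as an auditable `weight` attribute and ignored by default).

Communities are detected by maximizing Newman modularity

    Q = Σ_c [ e_c/m − (d_c/2m)² ],   Q ∈ [−1, 1],

with a seeded Louvain heuristic. Each woman then carries a triple of
community labels; a **combination** is a distinct triple, and a **family** is
the set of combinations sharing the profile-1 and profile-2 communities.
Families partition the cohort. Each family is screened against the outcome
with a single-predictor binomial logistic model of case status on the
family-membership indicator (reference group: all women outside the family),
which for the 2×2 family × case table has the closed form
OR = ad/bc, SE(ln OR) = √(1/a+1/b+1/c+1/d); a family is *selected* when the
two-sided Wald p < 0.05. Selected families are characterized variable by
variable with chi-square tests and **adjusted standardized Pearson residuals**

    r_ij = (O_ij − E_ij) / √(E_ij (1 − R_i/n)(1 − C_j/n)),

flagging cells with |r| > 2, plus within-family case × category tables for
the case-level associations. A classical companion analysis (age-adjusted
univariate logistic pre-screen at p < 0.05 feeding a joint binomial logistic
model) is run on the same categorized variables.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `seed` | 0 | drives node-order shuffles and all simulation draws |
| `restarts` | 10 | independent Louvain restarts, max-Q partition kept |
| `resolution` | 1.0 | modularity resolution in local moves (Q is always reported at 1) |
| `alpha` | 0.05 | family selection and univariate screening threshold |
| `residual_threshold` | 2.0 | adjusted-residual flag level |
| `ci_method` | `wilson` | prevalence interval (Clopper–Pearson and Wald selectable) |
| `quartile_method` | `linear` | numpy quantile interpolation for the reproductive-period cuts |
| `separate_binge` | False | keep weekly binge drinking as its own category |
| `comparison_mode` | `pooled` | reference in family comparisons: one pooled "others" column, or each family vs its complement |

## Design choices where the design was open

* **Quartile convention.** Reproductive-period classes use linear
  interpolation between order statistics; a value equal to a cut point falls
  in the lower class. Any consistent convention is defensible; this one is
  configurable via `quartile_method`.
* **Missing data.** A woman missing a variable simply receives no label for
  it (her graph degree drops by one). No imputation, no exclusion.
* **Menopause-length classes** are ≤5 vs >5 years since menopause, matching
  the convention of the summary tables this pipeline emulates.
* **Age bands** (40–44 … 60–64, 65+) appear in all three profiles' catalogs;
  with the default catalogs the profiles carry 20, 35 and 31 characteristic
  labels (32 for profile 3 with `separate_binge=True`).
* **Binge drinking** (<1% of a typical cohort) is folded into the highest
  drinking level by default to avoid a near-empty node.
* **Screening reference group** is all women outside the family; no
  multiple-testing correction is applied (the number of tests is recorded so
  users can apply their own). Families under 30 women are screened but
  flagged `small_sample`.
* **Univariate pre-screen** records the minimum Wald p over a variable's
  dummy-coded levels (reference = most frequent level), age-adjusted.
* **Separation** in logistic fits is detected (diverging coefficients /
  singular information) and flagged, not penalized away — the joint-model
  output preserves the degenerate OR 0.00 (0.00–0.00) signature rather than
  hiding it behind a Firth correction.

## Numerical choices

* Logistic fits use Newton/IRLS with step-halving; convergence when the
  maximum absolute score < 1e-8 or the relative log-likelihood change
  < 1e-10; the log-likelihood is asserted non-decreasing across iterations.
  Standard errors come from the inverse observed information; Wald CIs are
  exp(coef ± 1.96·SE).
* A zero cell in a 2×2 screening table triggers the Haldane–Anscombe +0.5
  correction, flagged in the output.
* Louvain breaks local-move ties toward the first best-gain community under
  the seeded node order, making runs reproducible given a seed. Isolated
  nodes become singleton communities and contribute nothing to Q. Because
  classic Louvain can terminate with improving single-node moves still hidden
  inside aggregated super-nodes, the implementation repeats the full
  local-move + aggregation cascade, re-initialized from the previous
  partition at original-node granularity, until no move increases Q; on all
  probed graphs this matches the optima found by Leiden while remaining a
  pure greedy modularity maximizer. The reported Q is recomputed from the
  final membership and must agree with the internal value to 1e-12.
* The brute-force oracle enumerates all set partitions (≤12 nodes), breaking
  Q ties (1e-12) toward fewer communities.
* Chi-square tests use no continuity correction; tables with a zero margin
  raise a degenerate-table error (skipped and listed in pipeline reports).

## The synthetic world

The real cohort is not shareable, so a seeded generator stands in. Each
woman draws one latent group per profile (defaults: 4/4/5 groups with mixing
weights shaped like the published community sizes); given the group, every
categorical variable follows a group-specific multinomial with 80% of mass on
the group's preferred categories; categories are then back-mapped to raw
values (uniform age inside the band, uniform BMI inside the class interval,
comorbidity flags by weighted sampling without replacement). The outcome is
Bernoulli with logit = intercept + indicator effects echoing the published
risk directions (age 60–64 +0.35, 65+ +0.70, BI-RADS D ln 2.5, male
first-line family history ln 5.5, high physical-activity compliance ln 0.4,
high salt-limitation compliance ln 0.6), plus optional extra log-odds for
chosen (profile-1, profile-2) group pairs to plant high-risk families. The
intercept is calibrated by root finding so the *exact* expected prevalence
(computed by summation over the discrete covariate law) equals the 1.8%
target.

Constraints applied during back-mapping (menopause at age ≥40, menarche age
≥9) can re-classify a handful of young women's reproductive-period or
menopause-length classes; this is realistic (a 41-year-old cannot have a
41-year reproductive period) but means planted profile-1 classes are
recovered with slight noise. Short reproductive periods combined with late
menopause can also imply menarche ages above the biological range; the
marginal distributions are only meant to match the emulated cohort in order
of magnitude.

Two deliberate choices in the recovery experiments:

* **Community recovery uses cohort-wide shared groups** (`shared_groups=True`,
  the extreme of the generator's cross-profile correlation knob). Age is a
  single raw variable read by all three catalogs; with independent
  per-profile groups the profile-1-driven age band plants a *rival* block
  structure in the other two profiles' graphs, and their modularity optimum
  then legitimately differs from the planted partition — a property of the
  world, not of the detector. With shared groups every profile's variables,
  age included, carry one consistent structure.
* **The planted high-risk family uses K=2 groups per profile** (family share
  ~25% of the cohort), matching the scale of the flagged family in the
  emulated study (1299/5601 ≈ 23%).

## What a green test does and does not establish

The generator plants clean multinomial group structure with independent
variables given the group; real questionnaire data have within-profile
correlations, missingness, and measurement error that the synthetic world
does not emulate. Green recovery tests therefore establish that the
pipeline's machinery (categorization → graph → Louvain → families →
screening) is correct and internally consistent — not that the published
cohort's communities, modularity values (0.159/0.08/0.137) or fitted odds
ratios would be reproduced; those depend on the unavailable data and are
treated as non-reproducible references. The in-report arithmetic that *is*
fully determined by printed counts (prevalences and Wilson intervals such as
100/5601 → 1.8% [1.5, 2.2]) is reproduced exactly and asserted in the test
suite.

## Known limitations

* The published source is ambiguous about whether characteristic
  co-occurrence edges were weighted inside the graph tool; the unweighted
  reading is implemented, with counts retained as an edge attribute.
* Wilson intervals reproduce most, but not all, of the printed family CIs at
  one decimal (the emulated report's CI method appears inconsistent across
  rows); the method tag is recorded in all outputs and alternatives are
  selectable.
* Modularity maximization is NP-hard; the heuristic carries no optimality
  guarantee beyond the ≤12-node oracle checks, and no statistical
  significance is attached to Q.
* Families are screened without multiple-testing correction, mirroring the
  emulated procedure.
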