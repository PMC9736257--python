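"""End-to-end orchestration: cohort -> categorization -> graphs -> communities
-> combinations -> families -> statistics, with a machine-readable report.

The composite estimator :class:`RiskProfilePipeline` runs every stage on a
cohort frame and exposes each intermediate as a fitted attribute;
:func:`run_pipeline` wraps it with config handling, artifact writing and a
JSON report.  Identical config + seed give identical reports (no timestamps
are embedded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from . import __version__
from .catalog import ProfileCategorizer
from .cohort import read_cohort_csv, validate_cohort, write_cohort_csv
from .community import (
    LouvainCommunities,
    partition_to_frame,
    summarize_communities,
)
from .families import FamilyScreener
from .graphs import WOMAN_PREFIX, build_affiliation_graph, export_graph
from .stats import (
    ContingencyTable,
    DegenerateTableError,
    RESIDUAL_THRESHOLD,
    chi_square,
    fit_logistic,
    prevalence_ci,
    univariate_screen,
)
from .simulate import default_params, generate_cohort

logger = logging.getLogger("bcrisknet")

__all__ = [
    "RunConfig",
    "PipelineStageError",
    "RiskProfilePipeline",
    "run_pipeline",
    "compare_family_characteristics",
    "traditional_analysis",
]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    input_csv: Optional[str] = None       # read a cohort ...
    simulate: Optional[dict] = None       # ... or simulate one (kwargs of default_params)
    seed: int = 0
    restarts: int = 10
    resolution: float = 1.0
    alpha: float = 0.05
    residual_threshold: float = RESIDUAL_THRESHOLD
    ci_method: str = "wilson"
    quartile_method: str = "linear"
    separate_binge: bool = False
    comparison_mode: str = "pooled"       # 'pooled' others column vs 'complement'
    export_format: str = "gexf"
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.alpha <= 0 or self.residual_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.comparison_mode not in ("pooled", "complement"):
            raise ValueError("comparison_mode must be 'pooled' or 'complement'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class RiskProfilePipeline(BaseEstimator):
    """Composite estimator running the full stratification on a cohort frame.

    Attributes (after ``fit``)
    --------------------------
    categorizers_ : {profile: ProfileCategorizer}
    assignments_ : {profile: long label frame}
    graphs_ : {profile: networkx.Graph}
    detectors_ : {profile: LouvainCommunities}
    woman_communities_ : {profile: Series woman id -> community label}
    screener_ : FamilyScreener
    families_, selected_families_ : DataFrames
    prevalence_ : PrevalenceEstimate for the whole cohort
    report_ : dict (JSON-serializable)
    """

    def __init__(self, seed: int = 0, restarts: int = 10, resolution: float = 1.0,
                 alpha: float = 0.05, residual_threshold: float = RESIDUAL_THRESHOLD,
                 ci_method: str = "wilson", quartile_method: str = "linear",
                 separate_binge: bool = False, comparison_mode: str = "pooled",
                 run_comparisons: bool = True, run_traditional: bool = True):
        self.seed = seed
        self.restarts = restarts
        self.resolution = resolution
        self.alpha = alpha
        self.residual_threshold = residual_threshold
        self.ci_method = ci_method
        self.quartile_method = quartile_method
        self.separate_binge = separate_binge
        self.comparison_mode = comparison_mode
        self.run_comparisons = run_comparisons
        self.run_traditional = run_traditional

    def fit(self, X: pd.DataFrame, y=None):
        def stage(name):
            logger.info("stage %s: starting (n=%d)", name, len(X))
            return name

        cohort = X
        try:
            stage("validate")
            validate_cohort(cohort)
        except Exception as e:  # noqa: BLE001 - stage attribution
            raise PipelineStageError("validate", e) from e

        self.categorizers_, self.assignments_ = {}, {}
        self.graphs_, self.detectors_ = {}, {}
        self.partitions_, self.community_summaries_ = {}, {}
        self.woman_communities_ = {}
        for p in (1, 2, 3):
            try:
                cat = ProfileCategorizer(
                    profile=p, quartile_method=self.quartile_method,
                    separate_binge=self.separate_binge,
                ).fit(cohort)
                self.categorizers_[p] = cat
                self.assignments_[p] = cat.transform(cohort)
            except Exception as e:
                raise PipelineStageError(f"categorize_p{p}", e) from e
            try:
                self.graphs_[p] = build_affiliation_graph(self.assignments_[p], p)
            except Exception as e:
                raise PipelineStageError(f"graph_p{p}", e) from e
            try:
                det = LouvainCommunities(
                    seed=int(self.seed) + p, restarts=self.restarts,
                    resolution=self.resolution,
                ).fit(self.graphs_[p])
                self.detectors_[p] = det
                self.partitions_[p] = det.partition_
                self.community_summaries_[p] = summarize_communities(
                    self.graphs_[p], det.partition_
                )
                membership = det.partition_.membership
                self.woman_communities_[p] = pd.Series(
                    {
                        str(node)[len(WOMAN_PREFIX):]: c
                        for node, c in membership.items()
                        if self.graphs_[p].nodes[node].get("kind") == "woman"
                    }
                )
                logger.info(
                    "profile %d: %d nodes, %d edges, Q=%.4f, %d communities",
                    p, self.graphs_[p].number_of_nodes(),
                    self.graphs_[p].number_of_edges(), det.modularity_,
                    det.partition_.n_communities(),
                )
            except Exception as e:
                raise PipelineStageError(f"communities_p{p}", e) from e

        try:
            outcome = pd.Series(
                cohort["bc_case"].astype(int).values,
                index=cohort["id"].astype(str).values,
            )
            self.screener_ = FamilyScreener(
                alpha=self.alpha, ci_method=self.ci_method
            ).fit(
                (
                    self.woman_communities_[1],
                    self.woman_communities_[2],
                    self.woman_communities_[3],
                ),
                outcome,
            )
            self.families_ = self.screener_.families_
            self.selected_families_ = self.screener_.selected_
        except Exception as e:
            raise PipelineStageError("families", e) from e

        try:
            self.prevalence_ = prevalence_ci(
                int(cohort["bc_case"].sum()), len(cohort), method=self.ci_method
            )
        except Exception as e:
            raise PipelineStageError("prevalence", e) from e

        self.comparisons_ = None
        if self.run_comparisons and len(self.selected_families_) > 0:
            try:
                self.comparisons_ = compare_family_characteristics(
                    cohort,
                    self.screener_.combinations_,
                    self.categorizers_,
                    selected=[
                        (r["c1"], r["c2"])
                        for _, r in self.selected_families_.iterrows()
                    ],
                    residual_threshold=self.residual_threshold,
                    mode=self.comparison_mode,
                )
            except Exception as e:
                raise PipelineStageError("comparisons", e) from e

        self.traditional_ = None
        if self.run_traditional:
            try:
                self.traditional_ = traditional_analysis(
                    cohort, self.categorizers_, alpha=self.alpha
                )
            except Exception as e:
                raise PipelineStageError("traditional", e) from e

        self.report_ = self._build_report()
        return self

    # -- report -----------------------------------------------------------

    def _build_report(self) -> dict:
        rep: dict = {
            "provenance": {
                "package_version": __version__,
                "seed": int(self.seed),
                "restarts": int(self.restarts),
                "resolution": float(self.resolution),
            },
            "cohort": {
                "n_women": int(self.prevalence_.n),
                "n_cases": int(self.prevalence_.x),
                "prevalence": {
                    "rate": self.prevalence_.rate,
                    "ci_low": self.prevalence_.lower,
                    "ci_high": self.prevalence_.upper,
                    "method": self.prevalence_.method,
                },
            },
            "profiles": {},
        }
        for p in (1, 2, 3):
            g = self.graphs_[p]
            part = self.partitions_[p]
            rep["profiles"][str(p)] = {
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
                "n_women": len(self.woman_communities_[p]),
                "n_characteristics": g.number_of_nodes()
                - len(self.woman_communities_[p]),
                "modularity": part.q,
                "n_communities": part.n_communities(),
                "communities": [
                    {
                        "label": str(cp.label),
                        "n_women": cp.n_women,
                        "characteristics": cp.characteristics,
                    }
                    for cp in self.community_summaries_[p]
                ],
            }
        ct = self.screener_.combination_table_
        rep["combinations"] = {
            "n_distinct": int(len(ct)),
            "table": _records(ct),
        }
        rep["families"] = {
            "screened": bool(self.screener_.screened_),
            "n_tests": int(self.families_.attrs.get("n_tests", 0)),
            "table": _records(self.families_),
            "selected": [
                {"c1": str(r["c1"]), "c2": str(r["c2"])}
                for _, r in self.selected_families_.iterrows()
            ],
        }
        if not self.screener_.screened_:
            rep["families"]["note"] = (
                "screening not applicable: cohort lacks cases or non-cases"
            )
        if self.comparisons_ is not None:
            rep["comparisons"] = self.comparisons_
        if self.traditional_ is not None:
            rep["traditional"] = self.traditional_
        return rep


def _records(df: pd.DataFrame) -> list:
    out = []
    for _, row in df.iterrows():
        rec = {}
        for k, v in row.items():
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif isinstance(v, (np.bool_,)):
                v = bool(v)
            elif isinstance(v, tuple):
                v = list(map(str, v))
            rec[str(k)] = v
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# family characterization


def compare_family_characteristics(
    cohort: pd.DataFrame,
    combinations: pd.DataFrame,
    categorizers: dict,
    selected: list,
    residual_threshold: float = RESIDUAL_THRESHOLD,
    mode: str = "pooled",
) -> dict:
    """Contrast selected families on every profile variable.

    Builds, per variable, the (group x category) contingency table where the
    groups are the selected families plus a reference of women outside them
    (one pooled "others" column when ``mode='pooled'``, or each family versus
    its own complement when ``mode='complement'``), with chi-square, adjusted
    residuals, and cell flags at ``residual_threshold``.  Within each family
    the (case x category) table flags which categories carry the cases —
    the within-group association annotations of a cohort report.
    """
    ids = cohort["id"].astype(str)
    fam_key = pd.Series(
        [f"{c1}|{c2}" for c1, c2 in zip(combinations["c1"], combinations["c2"])],
        index=combinations["id"].astype(str).values,
    )
    selected_keys = [f"{c1}|{c2}" for c1, c2 in selected]
    member = fam_key.reindex(ids.values)
    group = member.where(member.isin(selected_keys), other="others")
    group.index = ids.values

    out: dict = {"mode": mode, "threshold": residual_threshold, "variables": {}}
    for p, cat in categorizers.items():
        wide = cat.catalog_.apply(cohort)
        wide.index = ids.values
        for var in wide.columns:
            labels = wide[var]
            key = f"p{p}:{var}"
            if mode == "pooled":
                entry = _group_table(
                    labels, group, order=selected_keys + ["others"],
                    threshold=residual_threshold,
                )
            else:
                entry = {"per_family": {}}
                for k in selected_keys:
                    gg = pd.Series(
                        np.where(group == k, k, "complement"), index=group.index
                    )
                    entry["per_family"][k] = _group_table(
                        labels, gg, order=[k, "complement"],
                        threshold=residual_threshold,
                    )
            # within-family case/non-case association per category
            cases = pd.Series(
                cohort["bc_case"].astype(int).values, index=ids.values
            )
            within = {}
            for k in selected_keys:
                sel = group == k
                sub = _case_table(labels[sel], cases[sel], residual_threshold)
                if sub is not None:
                    within[k] = sub
            entry["within_family_cases"] = within
            out["variables"][key] = entry
    return out


def _group_table(labels: pd.Series, group: pd.Series, order, threshold):
    tab = pd.crosstab(group, labels)
    tab = tab.reindex(index=[g for g in order if g in tab.index])
    ct = ContingencyTable(
        tab.to_numpy(), row_labels=list(tab.index), col_labels=list(tab.columns)
    )
    try:
        stat, dof, p = ct.chi_square()
        resid = ct.adjusted_residuals()
        flags = ct.flagged(threshold)
        return {
            "observed": ct.observed.astype(int).tolist(),
            "rows": list(map(str, tab.index)),
            "cols": list(map(str, tab.columns)),
            "chi2": stat, "df": dof, "p": p,
            "adjusted_residuals": np.round(resid, 4).tolist(),
            "flags": flags.tolist(),
        }
    except DegenerateTableError:
        return {
            "observed": ct.observed.astype(int).tolist(),
            "rows": list(map(str, tab.index)),
            "cols": list(map(str, tab.columns)),
            "skipped": "degenerate table (zero expected count)",
        }


def _case_table(labels: pd.Series, cases: pd.Series, threshold):
    tab = pd.crosstab(cases, labels)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return None
    ct = ContingencyTable(
        tab.to_numpy(), row_labels=list(tab.index), col_labels=list(tab.columns)
    )
    try:
        stat, dof, p = ct.chi_square()
    except DegenerateTableError:
        return None
    flags = ct.flagged(threshold)
    case_row = list(tab.index).index(1)
    return {
        "cols": list(map(str, tab.columns)),
        "chi2": stat, "df": dof, "p": p,
        "case_flags": flags[case_row].tolist(),
    }


# ---------------------------------------------------------------------------
# classical (model-driven) analysis: univariate pre-screen + joint fit


def traditional_analysis(cohort: pd.DataFrame, categorizers: dict,
                         alpha: float = 0.05) -> dict:
    """Age-adjusted univariate screen over all profile variables, then a
    joint binomial logistic model on the selected ones (the classical
    companion table to the network analysis)."""
    ids = cohort["id"].astype(str).values
    frames = []
    for p, cat in categorizers.items():
        wide = cat.catalog_.apply(cohort)
        wide = wide.drop(columns=[c for c in ("age_band",) if c in wide.columns])
        wide.index = ids
        frames.append(wide)
    variables = pd.concat(frames, axis=1)
    outcome = pd.Series(cohort["bc_case"].astype(int).values, index=ids)
    age = pd.Series(cohort["age"].astype(float).values, index=ids)
    if outcome.nunique() < 2:
        return {"applicable": False,
                "note": "outcome constant; logistic screen skipped"}

    screen = univariate_screen(variables, outcome, age, alpha=alpha)
    selected = screen.loc[screen["selected"], "variable"].tolist()

    joint = None
    if selected:
        cols, names = [age.to_numpy()[:, None]], ["age"]
        mask = outcome.notna()
        for var in selected:
            v = variables[var]
            mask &= v.notna()
        sub = variables.loc[mask]
        yv = outcome[mask].to_numpy()
        cols = [age[mask].to_numpy()[:, None]]
        for var in selected:
            counts = sub[var].value_counts()
            ref = counts.index[0]
            for lvl in counts.index[1:]:
                cols.append((sub[var] == lvl).astype(float).to_numpy()[:, None])
                names.append(f"{var}={lvl}")
        design = np.hstack(cols)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            fit = fit_logistic(design, yv, names=names)
        joint = {
            "converged": bool(fit.converged),
            "separation": bool(fit.separation),
            "table": _records(
                fit.summary_frame().reset_index().rename(columns={"index": "term"})
            ),
        }
    return {
        "applicable": True,
        "univariate": _records(screen),
        "selected_variables": selected,
        "joint_model": joint,
    }


# ---------------------------------------------------------------------------
# run + artifacts


def run_pipeline(config: RunConfig):
    """Execute the full pipeline per ``config``; returns the fitted
    :class:`RiskProfilePipeline` (report under ``.report_``) and writes
    artifacts when ``config.out_dir`` is set."""
    truth = None
    if config.input_csv:
        try:
            cohort = read_cohort_csv(config.input_csv)
        except Exception as e:
            raise PipelineStageError("read_cohort", e) from e
    else:
        try:
            sim_kwargs = dict(config.simulate or {})
            params = default_params(seed=config.seed, **sim_kwargs)
            cohort, truth = generate_cohort(params, seed=config.seed)
        except Exception as e:
            raise PipelineStageError("simulate", e) from e

    pipe = RiskProfilePipeline(
        seed=config.seed, restarts=config.restarts, resolution=config.resolution,
        alpha=config.alpha, residual_threshold=config.residual_threshold,
        ci_method=config.ci_method, quartile_method=config.quartile_method,
        separate_binge=config.separate_binge, comparison_mode=config.comparison_mode,
    ).fit(cohort)
    pipe.report_["provenance"]["config_hash"] = config.hash()

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if truth is not None:
            write_cohort_csv(cohort, out / "cohort.csv")
            truth.to_csv(out / "truth.csv", index=False)
        for p in (1, 2, 3):
            export_graph(pipe.graphs_[p], out / f"p{p}.{config.export_format}")
            partition_to_frame(pipe.graphs_[p], pipe.partitions_[p]).to_csv(
                out / f"communities_p{p}.csv", index=False
            )
            pipe.categorizers_[p].catalog_.to_yaml(out / f"catalog_p{p}.yaml")
        pipe.screener_.combination_table_.to_csv(
            out / "combinations.csv", index=False
        )
        fam = pipe.families_.copy()
        fam.to_csv(out / "families.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(pipe.report_, fh, indent=2, sort_keys=True)
    return pipe
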