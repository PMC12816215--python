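"""Cluster characterisation, composite immunogenomic score, and survival.

Per-cluster summaries mirror a clinical characteristics table: size, RECIST
response proportions, PD-L1 high fraction, immune-phenotype mix, mean TMB,
mutation frequencies and mean expression of configurable gene panels
(T-cell activation, immunosuppressive, TGF-beta).

The composite score combines seven binary immunogenomic factors — five
activation factors (PD-L1 high, immune phenotype excluded/inflamed, TMB
high, CXCL13 expression high, TP53 mutated) scored +1 and two suppression
factors (TGFB1 expression high, FGFR3 mutated) scored -1 — giving a default
range of [-2, +5]. The weighting is a reconstruction: signed unit weights
are the simplest combination consistent with the factor definitions and are
fully configurable. Continuous factors are dichotomized at the cohort
median ('high' strictly above). Patients are grouped into quartiles of the
score and survival is summarised with Kaplan-Meier curves and log-rank
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test

from .cohort_io import (
    IMMUNE_PHENOTYPES,
    RESPONSE_CATEGORIES,
    ClinicalTable,
    ExpressionMatrix,
    MutationTable,
    median_dichotomize,
)
from .shap_cluster import ClusterAssignment


@dataclass
class GenePanelConfig:
    """Named gene panels summarised per cluster."""

    panels: dict[str, list[str]] = field(
        default_factory=lambda: {
            "t_activation": ["CXCL9", "CXCL10", "CXCL13", "GZMB"],
            "immunosuppressive": [],
            "tgf_beta": ["TGFB1"],
        }
    )


@dataclass
class CompositeScoreConfig:
    """Seven-factor immunogenomic score configuration."""

    activation_factors: tuple[str, ...] = (
        "pdl1_high",
        "phenotype_excluded_or_inflamed",
        "tmb_high",
        "cxcl13_high",
        "tp53_mutated",
    )
    suppression_factors: tuple[str, ...] = ("tgfb1_high", "fgfr3_mutated")
    activation_weight: float = 1.0
    suppression_weight: float = -1.0

    def __post_init__(self) -> None:
        names = list(self.activation_factors) + list(self.suppression_factors)
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")


# factor name -> (source, key) used by resolve_score_factors
_FACTOR_SOURCES = {
    "pdl1_high": ("clinical_cat", ("pdl1_level", ("high",))),
    "phenotype_excluded_or_inflamed": ("clinical_cat", ("immune_phenotype", ("excluded", "inflamed"))),
    "tmb_high": ("clinical_median", "tmb"),
    "cxcl13_high": ("expr_median", "CXCL13"),
    "tp53_mutated": ("mutation", "TP53"),
    "tgfb1_high": ("expr_median", "TGFB1"),
    "fgfr3_mutated": ("mutation", "FGFR3"),
}


def resolve_score_factors(
    clinical: ClinicalTable,
    expr: ExpressionMatrix,
    mutations: MutationTable,
    cfg: CompositeScoreConfig | None = None,
) -> pd.DataFrame:
    """Boolean factor matrix (patients x 7 factors), aligned to the clinical table.

    Raises naming the factor when its source column/gene is unavailable.
    """
    cfg = cfg or CompositeScoreConfig()
    sample_ids = clinical.sample_ids
    expr = expr.subset_samples(sample_ids)
    out = {}
    for name in list(cfg.activation_factors) + list(cfg.suppression_factors):
        if name not in _FACTOR_SOURCES:
            raise KeyError(f"unknown composite-score factor {name!r}")
        kind, key = _FACTOR_SOURCES[name]
        try:
            if kind == "clinical_cat":
                col, levels = key
                out[name] = clinical.require(col).isin(levels).to_numpy()
            elif kind == "clinical_median":
                vals = clinical.require(key).to_numpy(dtype=float)
                out[name] = median_dichotomize(vals) == "high"
            elif kind == "expr_median":
                out[name] = median_dichotomize(expr.sample_profile(key)) == "high"
            elif kind == "mutation":
                out[name] = mutations.mutated_vector(key, sample_ids).astype(bool)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"cannot resolve composite-score factor {name!r}: {exc}") from exc
    return pd.DataFrame(out, index=sample_ids)


def composite_score(factors: pd.DataFrame, cfg: CompositeScoreConfig | None = None) -> pd.Series:
    """Signed sum of satisfied factors (default weights +1 / -1, range [-2, +5])."""
    cfg = cfg or CompositeScoreConfig()
    missing = [f for f in list(cfg.activation_factors) + list(cfg.suppression_factors)
               if f not in factors.columns]
    if missing:
        raise ValueError(f"factor matrix missing: {missing}")
    act = factors[list(cfg.activation_factors)].to_numpy(dtype=float).sum(axis=1)
    sup = factors[list(cfg.suppression_factors)].to_numpy(dtype=float).sum(axis=1)
    score = cfg.activation_weight * act + cfg.suppression_weight * sup
    return pd.Series(score, index=factors.index, name="composite_score")


def quartile_groups(scores) -> np.ndarray:
    """Quartile labels Q1..Q4 (Q4 = highest) with midpoint-interpolated cuts.

    Ties at a cut point fall into the lower group; an all-equal vector has
    no quartile structure and raises.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise ValueError("need at least 4 scores for quartile groups")
    if np.all(scores == scores[0]):
        raise ValueError("all scores equal; no quartile structure")
    q25, q50, q75 = np.percentile(scores, [25, 50, 75])
    labels = np.full(scores.shape, "Q4", dtype=object)
    labels[scores <= q75] = "Q3"
    labels[scores <= q50] = "Q2"
    labels[scores <= q25] = "Q1"
    return labels.astype(str)


# ---------------------------------------------------------------------------
# Survival


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate at the distinct observed times."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    median: float  # NaN when S(t) never reaches 0.5

    def to_dataframe(self, group: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time": self.times, "at_risk": self.at_risk, "events": self.events,
             "survival": self.survival}
        )
        if group is not None:
            df.insert(0, "group", group)
        return df


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator; censored-only times change at-risk counts only."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be binary")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = np.unique(times)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    table = kmf.event_table
    at_risk = np.array([int(table.loc[t, "at_risk"]) if t in table.index else 0 for t in grid])
    observed = np.array([int(table.loc[t, "observed"]) if t in table.index else 0 for t in grid])
    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        median = float("nan")
    return SurvivalCurve(times=grid, at_risk=at_risk, events=observed, survival=surv, median=median)


def logrank_test(times, events, group) -> tuple[float, float]:
    """Log-rank test across 2+ groups; returns (chi-square, p-value)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) < 2:
        raise ValueError("need at least two non-empty groups")
    if events.sum() == 0:
        raise ValueError("no events observed; log-rank test undefined")
    if len(levels) == 2:
        m0 = group == levels[0]
        res = _ll_logrank(times[m0], times[~m0], event_observed_A=events[m0],
                          event_observed_B=events[~m0])
    else:
        res = multivariate_logrank_test(times, group, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cluster profile


def cluster_profile(
    assign: ClusterAssignment,
    clinical: ClinicalTable,
    mutations: MutationTable | None,
    expr: ExpressionMatrix,
    panels: GenePanelConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-cluster characteristics table (rows = hierarchy-path cluster names).

    Returns (profile, missing_genes) where missing_genes lists panel genes
    absent from the expression matrix (reported, not fatal).
    """
    panels = panels or GenePanelConfig()
    clin = clinical.aligned(assign.sample_ids)
    expr = expr.subset_samples(assign.sample_ids)
    names = np.array(assign.path_names)
    clusters = sorted(set(names), key=lambda s: [int(x) for x in s.split("-")])

    missing: dict[str, list[str]] = {}
    panel_rows: dict[str, np.ndarray] = {}
    for panel, genes in panels.panels.items():
        present = [g for g in genes if g in expr.gene_ids]
        absent = [g for g in genes if g not in expr.gene_ids]
        if absent:
            missing[panel] = absent
        if present:
            panel_rows[panel] = expr.subset_genes(present).values.mean(axis=0)

    wide_mut = mutations.to_wide(sample_ids=assign.sample_ids) if mutations is not None else None

    rows = []
    for c in clusters:
        mask = names == c
        sub = clin.df.loc[mask]
        row: dict = {"cluster": c, "n": int(mask.sum())}
        for cat in RESPONSE_CATEGORIES:
            row[f"prop_{cat}"] = float((sub["response"] == cat).mean())
        row["responder_rate"] = float(sub["responder"].mean())
        if "pdl1_level" in sub.columns:
            row["pdl1_high_frac"] = float((sub["pdl1_level"] == "high").mean())
        if "immune_phenotype" in sub.columns:
            for ph in IMMUNE_PHENOTYPES:
                row[f"phenotype_{ph}_frac"] = float((sub["immune_phenotype"] == ph).mean())
        if "tmb" in sub.columns:
            row["mean_tmb"] = float(pd.to_numeric(sub["tmb"]).mean())
        if wide_mut is not None:
            for gene in wide_mut.columns:
                row[f"mut_{gene}_freq"] = float(wide_mut.loc[mask, gene].mean())
        for panel, values in panel_rows.items():
            row[f"panel_{panel}_mean"] = float(values[mask].mean())
        rows.append(row)
    profile = pd.DataFrame(rows).set_index("cluster")
    return profile, missing


def survival_by_cluster(assign: ClusterAssignment, clinical: ClinicalTable) -> pd.DataFrame:
    """Tidy KM curves per hierarchy-path cluster (time, at_risk, events, survival)."""
    clin = clinical.aligned(assign.sample_ids).df
    names = np.array(assign.path_names)
    frames = []
    for c in sorted(set(names), key=lambda s: [int(x) for x in s.split("-")]):
        mask = names == c
        curve = km_curve(clin.loc[mask, "os_months"].to_numpy(),
                         clin.loc[mask, "os_event"].to_numpy())
        frames.append(curve.to_dataframe(group=c))
    return pd.concat(frames, ignore_index=True)


def median_os_by_cluster(assign: ClusterAssignment, clinical: ClinicalTable) -> pd.Series:
    clin = clinical.aligned(assign.sample_ids).df
    names = np.array(assign.path_names)
    out = {}
    for c in sorted(set(names), key=lambda s: [int(x) for x in s.split("-")]):
        mask = names == c
        out[c] = km_curve(clin.loc[mask, "os_months"].to_numpy(),
                          clin.loc[mask, "os_event"].to_numpy()).median
    return pd.Series(out, name="median_os")
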