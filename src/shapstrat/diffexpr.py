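"""Two-group differential expression with empirical-Bayes moderated t-statistics.

Per gene, a two-group linear model (intercept + group indicator) yields the
log2 fold change, pooled residual variance s_g^2 and residual df d_g = N - 2.
Gene variances are then shrunk toward a common prior by the standard
empirical-Bayes hierarchy: s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_{d_g} / d_g
with 1/sigma_g^2 ~ chi^2_{d0} s0^-2 / d0. The prior (d0, s0^2) is estimated
by moment matching on z = log s_g^2 using digamma/trigamma inversion, and the
moderated statistic

    t_g = log_fc_g / (s_tilde_g * sqrt(1/n0 + 1/n1)),
    s_tilde_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

is referred to a t distribution on d0 + d_g degrees of freedom. With d0 = 0
this reduces to the ordinary pooled two-sample t; with d0 = +inf every gene
uses the common prior variance. DEGs are gated at FDR < 0.05 and linear fold
change > 1.3 (i.e. |log2 FC| > log2 1.3) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import ExpressionMatrix


@dataclass(frozen=True)
class EBayesPrior:
    """Shrinkage hyperparameters: prior df d0 (may be +inf) and prior variance s0_sq."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("prior degrees of freedom d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance s0_sq must be positive")


def fit_gene_models(expr: ExpressionMatrix, group: np.ndarray):
    """Per-gene two-group fit.

    Returns (log_fc, s_sq, d_g) where log_fc = mean(group 1) - mean(group 0),
    s_sq is the pooled within-group variance and d_g = N - 2.
    """
    group = np.asarray(group).astype(int)
    if group.shape != (expr.n_samples,):
        raise ValueError("group vector must align with expression samples")
    if not set(np.unique(group)) <= {0, 1}:
        raise ValueError("group must be binary 0/1")
    n1 = int(group.sum())
    n0 = int(len(group) - n1)
    if n0 < 1 or n1 < 1:
        raise ValueError("both groups must be non-empty")
    if n0 + n1 < 3:
        raise ValueError("need at least 3 samples for a residual df")
    x0 = expr.values[:, group == 0]
    x1 = expr.values[:, group == 1]
    m0 = x0.mean(axis=1)
    m1 = x1.mean(axis=1)
    log_fc = m1 - m0
    rss = ((x0 - m0[:, None]) ** 2).sum(axis=1) + ((x1 - m1[:, None]) ** 2).sum(axis=1)
    d_g = n0 + n1 - 2
    s_sq = rss / d_g
    return log_fc, s_sq, d_g


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the standard recurrence)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s_sq: np.ndarray, d_g: int) -> EBayesPrior:
    """Moment-matching estimate of (d0, s0^2) from observed gene variances.

    Works on z = log s_g^2, whose mean and excess variance over
    trigamma(d_g/2) identify the prior; d0 = +inf when the empirical spread
    of z does not exceed the sampling spread of a chi-square variance.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    positive = s_sq[s_sq > 0]
    if positive.size == 0:
        raise ValueError("all gene variances are zero; cannot estimate a prior")
    if positive.size < 10:
        raise ValueError("need at least 10 genes with positive variance")
    z = np.log(positive)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d_g / 2.0))
    if e_var > 0:
        half_d0 = _trigamma_inverse(e_var)
        d0 = 2.0 * half_d0
        s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        # no excess dispersion beyond chi-square sampling noise: variances are
        # exchangeable and the pooled (arithmetic-mean) variance is the prior
        d0 = np.inf
        s0_sq = float(positive.mean())
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(
    log_fc: np.ndarray,
    s_sq: np.ndarray,
    d_g: int,
    prior: EBayesPrior | None,
    n0: int,
    n1: int,
    d0: float | None = None,
    s0_sq: float | None = None,
):
    """Moderated t-statistics, total df and two-sided p-values.

    The prior may be passed as an :class:`EBayesPrior` or as raw (d0, s0_sq)
    — the latter admits d0 = 0, the classical pooled-t limit. Genes with a
    zero posterior variance are flagged and assigned p = 0.
    """
    if prior is not None:
        d0, s0_sq = prior.d0, prior.s0_sq
    if d0 is None or s0_sq is None:
        raise ValueError("either prior or (d0, s0_sq) must be given")
    if n0 < 1 or n1 < 1:
        raise ValueError("both group sizes must be >= 1")
    log_fc = np.asarray(log_fc, dtype=float)
    s_sq = np.asarray(s_sq, dtype=float)
    if np.isinf(d0):
        s2_post = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d_g * s_sq) / (d0 + d_g)
        df_total = d0 + d_g
    se = np.sqrt(s2_post * (1.0 / n0 + 1.0 / n1))
    zero_flag = se == 0
    if zero_flag.any():
        warnings.warn(
            f"{int(zero_flag.sum())} genes have zero posterior variance; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(zero_flag, np.sign(log_fc) * np.inf, log_fc / np.where(zero_flag, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where(zero_flag, 0.0, p)
    return t_mod, df_total, p, zero_flag


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix, group: np.ndarray, prior: EBayesPrior | None = None
) -> pd.DataFrame:
    """Full moderated-t DEG analysis; returns the per-gene table.

    Columns: gene, log_fc, mean_expr, t_mod, p_value, fdr, direction,
    zero_variance. Zero-variance genes are excluded from prior estimation but
    retained in the output.
    """
    group = np.asarray(group).astype(int)
    log_fc, s_sq, d_g = fit_gene_models(expr, group)
    n1 = int(group.sum())
    n0 = len(group) - n1
    if prior is None:
        prior = estimate_prior(s_sq, d_g)
    t_mod, _, p, zero_flag = moderated_t(log_fc, s_sq, d_g, prior, n0, n1)
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "log_fc": log_fc,
            "mean_expr": expr.values.mean(axis=1),
            "t_mod": t_mod,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(log_fc > 0, "up", "down"),
            "zero_variance": zero_flag,
        }
    )


def select_degs(deg: pd.DataFrame, fdr_max: float = 0.05, fc_min: float = 1.3) -> pd.DataFrame:
    """Gate the DEG table at FDR < fdr_max and linear fold change > fc_min."""
    if fc_min <= 1:
        raise ValueError("fc_min must exceed 1 (linear-scale fold change)")
    keep = (deg["fdr"] < fdr_max) & (np.abs(deg["log_fc"]) > np.log2(fc_min))
    return deg.loc[keep].reset_index(drop=True)


def write_deg_table(deg: pd.DataFrame, path: str | Path) -> None:
    """Export with limma-compatible column names."""
    out = deg.rename(
        columns={
            "log_fc": "logFC",
            "mean_expr": "AveExpr",
            "t_mod": "t",
            "p_value": "P.Value",
            "fdr": "adj.P.Val",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Read gene symbols from a DEG TSV (gene column) or a one-per-line file."""
    path = Path(path)
    first = path.read_text().splitlines()[0]
    if "\t" in first or first.strip().lower() == "gene":
        df = pd.read_csv(path, sep="\t")
        col = "gene" if "gene" in df.columns else df.columns[0]
        return [str(g) for g in df[col]]
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]
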