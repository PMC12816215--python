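import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shapstrat.cohort_io import ExpressionMatrix
from shapstrat.diffexpr import (
    EBayesPrior,
    bh_adjust,
    differential_expression,
    estimate_prior,
    fit_gene_models,
    moderated_t,
    select_degs,
)


def _expr(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values, [f"g{i}" for i in range(values.shape[0])], [f"s{i}" for i in range(values.shape[1])]
    )


class TestFitGeneModels:
    def test_log_fc_is_difference_of_group_means(self):
        expr = _expr([[1, 1, 3, 3]])
        lfc, s_sq, d = fit_gene_models(expr, np.array([0, 0, 1, 1]))
        assert lfc[0] == pytest.approx(2.0)
        assert d == 2

    def test_identical_groups_give_zero_fc_and_variance(self):
        expr = _expr([[2, 2, 2, 2]])
        lfc, s_sq, _ = fit_gene_models(expr, np.array([0, 0, 1, 1]))
        assert lfc[0] == 0.0
        assert s_sq[0] == 0.0

    def test_matches_brute_force_recomputation(self, rng):
        x = rng.normal(size=(40, 12))
        group = np.array([0] * 5 + [1] * 7)
        lfc, s_sq, d = fit_gene_models(_expr(x), group)
        for g in range(40):
            a, b = x[g, group == 0], x[g, group == 1]
            assert lfc[g] == pytest.approx(b.mean() - a.mean(), abs=1e-12)
            pooled = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / (12 - 2)
            assert s_sq[g] == pytest.approx(pooled, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            fit_gene_models(_expr([[1, 2, 3]]), np.array([1, 1, 1]))


class TestEstimatePrior:
    def test_equal_variances_give_infinite_prior_df(self):
        prior = estimate_prior(np.full(50, 0.7), d_g=8)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.7)

    def test_recovers_planted_hyperparameters(self):
        # s_g^2 ~ s0^2 * chi2_d / d scaled by inverse-chi-square(d0) gene variances
        rng = np.random.default_rng(42)
        d0, s0_sq, d_g, n_genes = 4.0, 1.0, 10, 20000
        sigma2 = s0_sq * d0 / rng.chisquare(d0, n_genes)
        s_sq = sigma2 * rng.chisquare(d_g, n_genes) / d_g
        prior = estimate_prior(s_sq, d_g)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s0_sq > 0

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            estimate_prior(np.zeros(100), d_g=4)


class TestModeratedT:
    def test_d0_zero_reduces_to_classical_pooled_t(self, rng):
        x = rng.normal(size=(50, 12))
        group = np.array([0] * 6 + [1] * 6)
        lfc, s_sq, d = fit_gene_models(_expr(x), group)
        t_mod, df, p, _ = moderated_t(lfc, s_sq, d, prior=None, n0=6, n1=6, d0=0.0, s0_sq=1.0)
        classic = stats.ttest_ind(x[:, group == 1], x[:, group == 0], axis=1, equal_var=True)
        assert np.allclose(t_mod, classic.statistic, atol=1e-10)
        assert np.allclose(p, classic.pvalue, atol=1e-10)

    def test_d0_infinite_uses_common_prior_variance(self):
        prior = EBayesPrior(d0=np.inf, s0_sq=2.0)
        t_mod, df, p, _ = moderated_t(np.array([1.0]), np.array([5.0]), 4, prior, 3, 3)
        # s_tilde^2 = s0^2 regardless of the observed variance
        assert t_mod[0] == pytest.approx(1.0 / np.sqrt(2.0 * (1 / 3 + 1 / 3)))
        assert np.isinf(df)

    def test_matches_independent_formula_evaluation(self, rng):
        # heterogeneous gene variances so the estimated prior df is finite
        sigma2 = 0.5 * 4 / rng.chisquare(4, 50)
        x = rng.normal(0, np.sqrt(sigma2)[:, None], size=(50, 12)) + 5
        group = np.array([0] * 6 + [1] * 6)
        lfc, s_sq, d = fit_gene_models(_expr(x), group)
        prior = estimate_prior(s_sq, d)
        assert np.isfinite(prior.d0)
        t_mod, df, p, _ = moderated_t(lfc, s_sq, d, prior, 6, 6)
        for g in range(50):  # independent scalar evaluation of the shrinkage formula
            s2 = (prior.d0 * prior.s0_sq + d * s_sq[g]) / (prior.d0 + d)
            t_ref = lfc[g] / np.sqrt(s2 * (1 / 6 + 1 / 6))
            assert t_mod[g] == pytest.approx(t_ref, abs=1e-10)
            assert p[g] == pytest.approx(2 * stats.t.sf(abs(t_ref), prior.d0 + d), abs=1e-12)

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(2024)
        x = rng.normal(5, 1, size=(5000, 20))
        group = np.array([0] * 10 + [1] * 10)
        lfc, s_sq, d = fit_gene_models(_expr(x), group)
        prior = estimate_prior(s_sq, d)
        _, _, p, _ = moderated_t(lfc, s_sq, d, prior, 10, 10)
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05

    def test_zero_variance_gene_flagged_with_zero_p(self):
        with pytest.warns(RuntimeWarning):
            t_mod, _, p, flag = moderated_t(
                np.array([1.0]), np.array([0.0]), 4, prior=None, n0=3, n1=3, d0=0.0, s0_sq=1.0
            )
        assert flag[0]
        assert p[0] == 0.0


class TestAgainstLimma:
    """Cross-check against Bioconductor limma through Rscript on a frozen fixture."""

    def _run_limma(self, tmp_path, values, n0, n1):
        df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                          columns=[f"s{i}" for i in range(values.shape[1])])
        df.to_csv(tmp_path / "expr.csv")
        script = f"""
suppressMessages(library(limma))
x <- as.matrix(read.csv("{tmp_path}/expr.csv", row.names=1))
design <- model.matrix(~c(rep(0,{n0}), rep(1,{n1})))
fit <- eBayes(lmFit(x, design))
tt <- topTable(fit, coef=2, number=Inf, sort.by="none")
write.csv(format(tt, digits=17), "{tmp_path}/out.csv")
"""
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True, capture_output=True)
        return pd.read_csv(tmp_path / "out.csv", index_col=0).astype(float)

    def test_finite_prior_df_agrees_to_machine_precision(self, tmp_path):
        rng = np.random.default_rng(11)
        sigma2 = 0.25 * 4 / rng.chisquare(4, 200)
        x = rng.normal(0, np.sqrt(sigma2)[:, None], size=(200, 10)) + 5
        x[:10, 5:] += 1
        ref = self._run_limma(tmp_path, x, 5, 5)
        tab = differential_expression(_expr(x), np.array([0] * 5 + [1] * 5))
        assert np.allclose(tab["t_mod"], ref["t"], atol=1e-10)
        assert np.allclose(tab["p_value"], ref["P.Value"], atol=1e-10)
        assert np.allclose(tab["fdr"], ref["adj.P.Val"], atol=1e-10)

    def test_infinite_prior_df_t_statistics_agree(self, tmp_path):
        rng = np.random.default_rng(7)
        x = rng.normal(5, 1, size=(50, 12))
        x[:5, 6:] += 1.5
        ref = self._run_limma(tmp_path, x, 6, 6)
        tab = differential_expression(_expr(x), np.array([0] * 6 + [1] * 6))
        assert np.allclose(tab["log_fc"], ref["logFC"], atol=1e-12)
        assert np.allclose(tab["t_mod"], ref["t"], atol=1e-10)
        # limma caps df.total at the pooled df while the moderated-t formula
        # here refers d0 = inf to the normal tail: p agrees only approximately
        assert np.allclose(tab["p_value"], ref["P.Value"], atol=1e-3)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_equal_p_values_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_single_p_identity(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            # independent step-up: fdr_(i) = min_{j>=i} p_(j) * m / j
            order = np.argsort(p)
            m = len(p)
            sorted_fdr = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty_like(p)
            expected[order] = np.minimum(sorted_fdr, 1.0)
            assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestSelectDegs:
    def _table(self, fdr, log_fc):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(fdr))], "log_fc": log_fc, "fdr": fdr,
             "direction": np.where(np.asarray(log_fc) > 0, "up", "down")}
        )

    def test_both_gates_must_pass(self):
        tab = self._table([0.049, 0.049], [0.40, 0.30])  # FC 1.32 vs 1.23
        selected = select_degs(tab)
        assert list(selected["gene"]) == ["g0"]
        assert selected["direction"].iloc[0] == "up"

    def test_count_monotone_in_gates(self, rng):
        tab = self._table(rng.uniform(0, 0.2, 100), rng.normal(0, 0.6, 100))
        counts_fc = [len(select_degs(tab, fc_min=fc)) for fc in [1.1, 1.3, 1.5, 2.0]]
        assert counts_fc == sorted(counts_fc, reverse=True)
        counts_fdr = [len(select_degs(tab, fdr_max=f)) for f in [0.1, 0.05, 0.01]]
        assert counts_fdr == sorted(counts_fdr, reverse=True)
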