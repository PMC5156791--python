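"""Two-group fit, variance-prior estimation, moderation and BH adjustment."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirpoma import diff_expr
from mirpoma.data_io import CONTROL, DISEASE, ExpressionMatrix, ValidationError


def make_expr(rows: dict[str, list[float]], n_control: int) -> ExpressionMatrix:
    n_total = len(next(iter(rows.values())))
    samples = [f"s{i}" for i in range(n_total)]
    groups = {s: (CONTROL if i < n_control else DISEASE) for i, s in enumerate(samples)}
    values = pd.DataFrame(rows, index=samples).T
    values.columns = samples
    return ExpressionMatrix(values=values, groups=groups)


class TestFitGroupModel:
    def test_exact_means_zero_residual(self):
        expr = make_expr({"mir-1": [1, 1, 3, 3]}, n_control=2)
        fit = diff_expr.fit_group_model(expr)
        assert fit.log_fold_change[0] == pytest.approx(2.0)
        assert fit.sigma[0] == 0.0

    def test_hand_computed_two_group_ols(self):
        # control (0,2), case (1,3): lfc 1, pooled SS 4, df 2, sigma sqrt(2)
        expr = make_expr({"mir-1": [0, 2, 1, 3]}, n_control=2)
        fit = diff_expr.fit_group_model(expr)
        assert fit.log_fold_change[0] == pytest.approx(1.0)
        assert fit.sigma[0] == pytest.approx(np.sqrt(2.0))
        assert fit.df_residual == 2
        assert fit.unscaled_se == pytest.approx(1.0)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=10)
        expr = make_expr({"mir-1": list(vals)}, n_control=5)
        # permute within and across groups, keeping labels attached
        perm = [3, 0, 4, 1, 2, 8, 6, 9, 5, 7]
        samples = [f"s{i}" for i in perm]
        shuffled = ExpressionMatrix(
            values=expr.values[samples], groups={s: expr.groups[s] for s in samples}
        )
        f1 = diff_expr.fit_group_model(expr)
        f2 = diff_expr.fit_group_model(shuffled)
        assert f1.log_fold_change[0] == pytest.approx(f2.log_fold_change[0])
        assert f1.sigma[0] == pytest.approx(f2.sigma[0])

    def test_small_group_rejected(self):
        expr = make_expr({"mir-1": [1, 2, 3]}, n_control=1)
        with pytest.raises(ValidationError, match=">=2"):
            diff_expr.fit_group_model(expr)


class TestEstimatePrior:
    def test_identical_variances_take_infinite_branch(self):
        d0, s0sq = diff_expr.estimate_prior(np.full(50, 0.3), 10)
        assert np.isinf(d0)
        # with zero dispersion s0sq matches the common variance (bias-corrected scale)
        from scipy.special import digamma

        assert s0sq == pytest.approx(0.09 * np.exp(-digamma(5) + np.log(5)), rel=1e-6)

    def test_parameter_recovery_scaled_inv_chisq(self):
        # variances drawn from the model the estimator assumes
        d0_true, s0_true, df = 4.0, 0.05, 38
        d0s, s0s = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 2000)
            s2 = sigma2 * rng.chisquare(df, 2000) / df
            d0, s0sq = diff_expr.estimate_prior(np.sqrt(s2), df)
            d0s.append(d0)
            s0s.append(s0sq)
        assert 3.0 <= np.median(d0s) <= 5.5
        assert abs(np.median(s0s) - s0_true) / s0_true < 0.15

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        s = np.sqrt(0.05 * 4 / rng.chisquare(4, 500))
        d0_a, s0_a = diff_expr.estimate_prior(s, 20)
        d0_b, s0_b = diff_expr.estimate_prior(np.sqrt(2.0) * s, 20)
        assert d0_b == pytest.approx(d0_a, rel=1e-9)
        assert s0_b == pytest.approx(2.0 * s0_a, rel=1e-9)

    def test_all_zero_sigma_error(self):
        with pytest.raises(ValidationError, match="no variance"):
            diff_expr.estimate_prior(np.zeros(10), 5)


class TestModerate:
    def _fit(self, lfc, sigma, df=4, se=1.0):
        return diff_expr.GroupFit(
            feature_ids=[f"f{i}" for i in range(len(lfc))],
            log_fold_change=np.asarray(lfc, float),
            sigma=np.asarray(sigma, float),
            df_residual=df,
            unscaled_se=se,
        )

    def test_d0_zero_is_ordinary_t(self):
        fit = self._fit([1.2], [0.5], df=6, se=0.6)
        t, p = diff_expr.moderate(fit, d0=0.0, s0sq=1.0)
        t_ord = 1.2 / (0.5 * 0.6)
        assert t[0] == pytest.approx(t_ord)
        assert p[0] == pytest.approx(2 * sps.t.sf(t_ord, 6))

    def test_zero_lfc_gives_p_one(self):
        fit = self._fit([0.0], [0.5])
        t, p = diff_expr.moderate(fit, d0=4.0, s0sq=0.05)
        assert t[0] == 0.0 and p[0] == 1.0

    def test_infinite_d0_uses_prior_variance_normal_tail(self):
        fit = self._fit([1.0], [0.5], df=4, se=1.0)
        t, p = diff_expr.moderate(fit, d0=np.inf, s0sq=0.25)
        assert t[0] == pytest.approx(2.0)
        assert p[0] == pytest.approx(2 * sps.norm.sf(2.0), rel=1e-6)

    def test_posterior_variance_interpolates(self):
        # s~^2 must lie between s_g^2 and s0sq, so |t| between the two extremes
        fit = self._fit([1.0], [0.8], df=4, se=1.0)
        t_mod, _ = diff_expr.moderate(fit, d0=4.0, s0sq=0.04)
        t_ord = 1.0 / 0.8
        t_prior = 1.0 / 0.2
        assert min(t_ord, t_prior) <= abs(t_mod[0]) <= max(t_ord, t_prior)

    def test_p_matches_monte_carlo_tail(self):
        # one hand-built feature: p from the t CDF vs simulated null statistics
        d0, s0sq, dg, n1 = 4.0, 0.05, 6, 4
        rng = np.random.default_rng(123)
        n_draws = 10**6
        sigma2 = s0sq * d0 / rng.chisquare(d0, n_draws)
        s2 = sigma2 * rng.chisquare(dg, n_draws) / dg
        lfc_null = rng.normal(0, np.sqrt(sigma2 * 2 / n1))
        s2_post = (d0 * s0sq + dg * s2) / (d0 + dg)
        t_null = lfc_null / np.sqrt(s2_post * 2 / n1)

        t_obs = 2.5
        p_mc = np.mean(np.abs(t_null) >= t_obs)
        p_an = 2 * sps.t.sf(t_obs, d0 + dg)
        se_mc = np.sqrt(p_an * (1 - p_an) / n_draws)
        assert abs(p_mc - p_an) < 3 * se_mc


class TestAdjustBH:
    def test_hand_step_up(self):
        q = diff_expr.adjust_bh([0.01, 0.04, 0.03, 0.02])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert diff_expr.adjust_bh([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.all(diff_expr.adjust_bh([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            diff_expr.adjust_bh([0.5, 1.2])

    def test_monotone_and_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=200) ** 2
        q = diff_expr.adjust_bh(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(diff_expr.adjust_bh(p)[perm], diff_expr.adjust_bh(p[perm]))


class TestSelectDe:
    def _result(self, q):
        table = pd.DataFrame(
            {"p_adjusted": q, "is_de": np.asarray(q) < 0.05},
            index=[f"mir-{i}" for i in range(len(q))],
        )
        return diff_expr.DEResult(table=table, d0=4.0, s0sq=0.05, alpha=0.05)

    def test_strict_inequality(self):
        res = self._result([0.04, 0.05, 0.06])
        assert diff_expr.select_de(res) == {"mir-0"}

    def test_alpha_zero_empty(self):
        res = self._result([0.0001, 0.01])
        assert diff_expr.select_de(res, alpha=0.0) == frozenset()


def test_moderated_t_matches_limma_oracle(tmp_path):
    """Independent oracle: the reference R implementation of the moderated
    t pipeline on one small synthetic matrix."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    rng = np.random.default_rng(42)
    m, n1, n2 = 60, 5, 5
    sigma2 = 0.05 * 4 / rng.chisquare(4, m)
    mu = rng.normal(7, 1, m)
    shift = np.where(rng.random(m) < 0.3, rng.choice([-1.5, 1.5], m), 0.0)
    ctrl = rng.normal(mu[:, None], np.sqrt(sigma2)[:, None], (m, n1))
    case = rng.normal((mu + shift)[:, None], np.sqrt(sigma2)[:, None], (m, n2))
    rows = {f"mir-{i}": list(ctrl[i]) + list(case[i]) for i in range(m)}
    expr = make_expr(rows, n_control=n1)

    mat = tmp_path / "mat.tsv"
    expr.values.to_csv(mat, sep="\t")
    rout = tmp_path / "limma_out.tsv"
    script = tmp_path / "run_limma.R"
    script.write_text(
        f"""
suppressMessages(library(limma))
x <- as.matrix(read.delim("{mat}", row.names=1))
design <- cbind(Intercept=1, Case=c(rep(0,{n1}), rep(1,{n2})))
fit <- eBayes(lmFit(x, design))
out <- data.frame(id=rownames(x), t=fit$t[, "Case"], p=fit$p.value[, "Case"],
                  lfc=fit$coefficients[, "Case"])
write.table(out, "{rout}", sep="\\t", quote=FALSE, row.names=FALSE)
cat(fit$df.prior, fit$s2.prior, "\\n")
"""
    )
    proc = subprocess.run(
        ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
    )
    assert proc.returncode == 0, proc.stderr
    ref = pd.read_csv(rout, sep="\t", index_col=0)

    res = diff_expr.run_de(expr)
    ours = res.table.loc[ref.index]
    assert np.allclose(ours["log_fold_change"], ref["lfc"], atol=1e-8)
    assert np.allclose(ours["t_moderated"], ref["t"], atol=1e-4)
    assert np.allclose(ours["p_raw"], ref["p"], atol=1e-6)
    d0_ref, s0_ref = map(float, proc.stdout.split()[:2])
    assert res.d0 == pytest.approx(d0_ref, rel=1e-3)
    assert res.s0sq == pytest.approx(s0_ref, rel=1e-3)
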