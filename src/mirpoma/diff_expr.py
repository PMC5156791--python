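"""Two-group differential expression with empirical-Bayes variance moderation.

The model is the standard moderated t-statistic for a two-group comparison:
per feature g an ordinary least-squares fit gives the log2 fold change
(case - control difference of means), residual standard deviation s_g and
residual degrees of freedom d_g = n - 2.  The residual variances are assumed
to follow a scaled inverse-chi-square prior s0^2 * d0 / chi2(d0); the prior
parameters (d0, s0sq) are estimated across features by the method of moments
on log variances, and each feature's variance is shrunk to the posterior

    s~_g^2 = (d0 * s0sq + d_g * s_g^2) / (d0 + d_g),

giving t = lfc / (s~_g * sqrt(1/n1 + 1/n2)) on d0 + d_g degrees of freedom.
P-values are Benjamini-Hochberg adjusted and features with adjusted
p < alpha (strict) are called differentially expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data_io import CONTROL, DISEASE, ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class GroupFit:
    """Per-feature two-group OLS summaries (case minus control)."""

    feature_ids: list[str]
    log_fold_change: np.ndarray
    sigma: np.ndarray          # pooled residual SD; 0 for constant features
    df_residual: int           # n_total - 2, shared across features
    unscaled_se: float         # sqrt(1/n_case + 1/n_control)


@dataclass
class DEResult:
    """Full differential-expression table plus the fitted variance prior."""

    table: pd.DataFrame        # mirna_id-indexed; see run_de for columns
    d0: float
    s0sq: float
    alpha: float

    @property
    def de_mirnas(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["is_de"]])


def fit_group_model(expr: ExpressionMatrix) -> GroupFit:
    """Fit the two-group mean model feature-by-feature.

    Both groups need at least two samples.  Constant features get
    ``sigma = 0`` and are flagged in the log rather than dropped; they still
    receive a moderated test through the variance prior.
    """
    ctrl = expr.samples_in_group(CONTROL)
    case = expr.samples_in_group(DISEASE)
    if len(ctrl) < 2 or len(case) < 2:
        raise ValidationError(
            f"need >=2 samples per group, got {len(ctrl)} control / {len(case)} disease"
        )
    x_ctrl = expr.values[ctrl].to_numpy(float)
    x_case = expr.values[case].to_numpy(float)
    if not (np.isfinite(x_ctrl).all() and np.isfinite(x_case).all()):
        raise ValidationError("non-finite expression values")

    lfc = x_case.mean(axis=1) - x_ctrl.mean(axis=1)
    ss = ((x_ctrl - x_ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x_case - x_case.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = len(ctrl) + len(case) - 2
    sigma = np.sqrt(ss / df)
    n_const = int((sigma == 0).sum())
    if n_const:
        log.warning("%d constant (zero-variance) feature(s); sigma set to 0", n_const)
    return GroupFit(
        feature_ids=expr.feature_ids,
        log_fold_change=lfc,
        sigma=sigma,
        df_residual=df,
        unscaled_se=float(np.sqrt(1.0 / len(case) + 1.0 / len(ctrl))),
    )


def estimate_prior(sigmas: np.ndarray, dfs: np.ndarray | int) -> tuple[float, float]:
    """Estimate the variance-prior parameters (d0, s0sq) across features.

    Method of moments on log variances: with e_g = log(s_g^2)
    - psi(d_g/2) + log(d_g/2), the excess dispersion
    var(e_g) - mean(psi'(d_g/2)) equals psi'(d0/2) under the scaled
    inverse-chi-square model; d0 is recovered by inverting the (monotone)
    trigamma function and s0sq from the mean of e_g.  When the observed
    dispersion does not exceed the sampling noise, d0 is reported as
    infinite (no evidence of variance heterogeneity) with
    s0sq = exp(mean(e_g)).

    Zero-variance features carry no information about the prior and are
    excluded here (they still get moderated downstream).
    """
    sigmas = np.asarray(sigmas, dtype=float)
    dfs = np.broadcast_to(np.asarray(dfs, dtype=float), sigmas.shape)
    keep = sigmas > 0
    if keep.sum() == 0:
        raise ValidationError("no variance information (all residual SDs are zero)")
    if keep.sum() < 2:
        raise ValidationError("need >=2 features with positive residual SD")
    s2 = sigmas[keep] ** 2
    d = dfs[keep]
    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    target = float(np.var(e, ddof=1) - np.mean(special.polygamma(1, d / 2.0)))
    if target <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    # trigamma is strictly decreasing on (0, inf): bracket then root-find
    lo, hi = 1e-8, 10.0
    while special.polygamma(1, hi) > target:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - numerically unreachable
            return np.inf, float(np.exp(np.mean(e)))
    x = optimize.brentq(lambda v: special.polygamma(1, v) - target, lo, hi)
    d0 = 2.0 * x
    # E[e_g] = log(s0sq) - psi(d0/2) + log(d0/2) under the prior model
    s0sq = float(np.exp(np.mean(e) + special.digamma(x) - np.log(x)))
    return float(d0), s0sq


def moderate(fit: GroupFit, d0: float, s0sq: float) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t-statistics and two-sided p-values.

    Posterior variance s~^2 = (d0*s0sq + d*s^2)/(d0 + d); with d0 infinite
    all features share the prior variance and the reference distribution is
    normal.  d0 = 0 recovers the ordinary two-sample t-test.
    """
    if s0sq <= 0 and not np.isinf(d0):
        raise ValidationError("s0sq must be positive")
    d = fit.df_residual
    if np.isinf(d0):
        s2_post = np.full_like(fit.sigma, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + d * fit.sigma**2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.log_fold_change / (np.sqrt(s2_post) * fit.unscaled_se)
    t = np.where(fit.log_fold_change == 0, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, np.clip(p, 0.0, 1.0)


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    Sorted ascending, q(i) = p(i)*m/i, made monotone non-decreasing from the
    largest p down, capped at 1.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_de(expr: ExpressionMatrix, alpha: float = DEFAULT_ALPHA) -> DEResult:
    """Full DE pipeline: fit, estimate prior, moderate, adjust, flag."""
    fit = fit_group_model(expr)
    d0, s0sq = estimate_prior(fit.sigma, fit.df_residual)
    t, p = moderate(fit, d0, s0sq)
    q = adjust_bh(p)
    table = pd.DataFrame(
        {
            "log_fold_change": fit.log_fold_change,
            "sigma": fit.sigma,
            "df_residual": fit.df_residual,
            "t_moderated": t,
            "p_raw": p,
            "p_adjusted": q,
            "is_de": q < alpha,
        },
        index=pd.Index(fit.feature_ids, name="mirna_id"),
    )
    log.info(
        "DE: %d/%d features at adjusted p < %g (d0=%.3g, s0sq=%.3g)",
        int(table["is_de"].sum()), len(table), alpha, d0, s0sq,
    )
    return DEResult(table=table, d0=d0, s0sq=s0sq, alpha=alpha)


def select_de(result: DEResult, alpha: float | None = None) -> frozenset[str]:
    """IDs with adjusted p strictly below alpha."""
    a = result.alpha if alpha is None else alpha
    return frozenset(result.table.index[result.table["p_adjusted"] < a])
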