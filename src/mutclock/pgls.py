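"""Phylogenetic generalized least squares (PGLS) regression.

Fits log10(mu_y) on log10(generation time) with residual covariance
proportional to the Brownian expected covariance of the phylogeny,
optionally scaled by Pagel's lambda (off-diagonal multiplier).  With
lambda = 0 the fit reduces exactly to ordinary least squares; lambda = 1
is the pure Brownian model and the package default.

All solves go through a Cholesky whitening of the covariance (no explicit
inverse).  A singular covariance triggers a one-shot diagonal jitter of
1e-8 * mean(diag) with a warning, then a hard failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize_scalar

from .errors import AnalysisError
from .phylo import PhyloCovariance, brownian_vcv, leaf_names, prune_to

log = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "ComparisonResult",
    "fit_pgls",
    "fit_groups",
    "compare_fits",
    "doubling_effect",
]

_JITTER = 1e-8


@dataclass(frozen=True)
class RegressionFit:
    """Result of a (phylogenetic) GLS fit of y on a single predictor."""

    coefficients: np.ndarray  # (intercept, slope)
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    residual_variance: float  # sigma^2 = RSS_gls / (n - p)
    adjusted_r2: float
    lam: float  # Pagel's lambda actually used
    n: int
    df_residual: int
    log_likelihood: float  # ML (variance profiled at RSS/n)

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])


@dataclass(frozen=True)
class ComparisonResult:
    t: float
    df: float
    p: float


def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def _chol_with_jitter(V: np.ndarray) -> np.ndarray:
    try:
        return cholesky(V, lower=True)
    except np.linalg.LinAlgError:
        pass
    jit = _JITTER * float(np.mean(np.diag(V)))
    log.warning("covariance singular; adding diagonal jitter %.3g", jit)
    try:
        return cholesky(V + jit * np.eye(V.shape[0]), lower=True)
    except np.linalg.LinAlgError:
        raise AnalysisError(
            "phylogenetic covariance is singular even after jitter; "
            "check for duplicated tips or zero-length terminal branches"
        ) from None


def _gls_core(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """GLS via Cholesky whitening. Returns (beta, rss, rss0, XtViX_inv, logdetV)."""
    L = _chol_with_jitter(V)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    # intercept-only GLS fit for the R^2 baseline, same V
    ones = Xw[:, 0]
    b0 = float(ones @ yw) / float(ones @ ones)
    r0 = yw - ones * b0
    rss0 = float(r0 @ r0)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    XtX_inv = cho_solve((cholesky(XtX, lower=True), True), np.eye(XtX.shape[0]))
    return beta, rss, rss0, XtX_inv, logdetV


def _ml_loglik(rss: float, logdetV: float, n: int) -> float:
    s2 = rss / n
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdetV + n)


def fit_pgls(y, x, C: PhyloCovariance, lam: float | str = 1.0) -> RegressionFit:
    """Fit y = b0 + b1 * x with residual covariance sigma^2 * C(lambda).

    ``lam`` is either a fixed value in [0, 1] or ``"ml"`` to maximize the
    profile likelihood over [0, 1] (bounded search, tolerance 1e-6).
    Species order of ``y`` and ``x`` must match ``C.species_order``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = C.n
    if y.shape != (n,) or x.shape != (n,):
        raise AnalysisError(f"y/x must have length n = {n} matching the covariance")
    if n < 3:
        raise AnalysisError("PGLS needs at least 3 species")
    if np.ptp(x) == 0:
        raise AnalysisError("constant predictor: regression is undefined")
    X = np.column_stack([np.ones(n), x])

    if lam == "ml":
        def neg_ll(lm: float) -> float:
            _, rss, _, _, logdetV = _gls_core(y, X, _lambda_transform(C.matrix, lm))
            return -_ml_loglik(rss, logdetV, n)

        res = minimize_scalar(neg_ll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-6})
        # the bounded search can stall short of a boundary optimum
        lam_hat = min([0.0, 1.0, float(res.x)], key=neg_ll)
        return fit_pgls(y, x, C, lam=lam_hat)

    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise AnalysisError("lambda must lie in [0, 1]")
    V = _lambda_transform(C.matrix, lam)
    beta, rss, rss0, XtX_inv, logdetV = _gls_core(y, X, V)
    p = X.shape[1]
    df = n - p
    sigma2 = rss / df
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    r2 = 1.0 - rss / rss0 if rss0 > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df
    return RegressionFit(
        coefficients=beta,
        standard_errors=se,
        t_statistics=tstat,
        p_values=pvals,
        residual_variance=sigma2,
        adjusted_r2=adj_r2,
        lam=lam,
        n=n,
        df_residual=df,
        log_likelihood=_ml_loglik(rss, logdetV, n),
    )


def fit_groups(table, tree, min_n: int = 3, lam: float | str = 1.0):
    """Per-group PGLS fits (tree pruned to each group's members).

    Returns ``(group_table, skipped)``: a DataFrame with one row per group
    of at least ``min_n`` species (alphabetical order) and a list of
    ``(group, n)`` pairs too small to fit.
    """
    table.require_derived()
    if min_n < 3:
        raise AnalysisError("min_n must be >= 3")
    df = table.data
    if list(df["species"]) != leaf_names(tree):
        raise AnalysisError("table must be matched to the tree (match_to_tree) first")
    rows, skipped, fits = [], [], {}
    for group, sub in df.groupby("group", sort=True):
        if len(sub) < min_n:
            skipped.append((group, len(sub)))
            log.info("group %r skipped (n = %d < %d)", group, len(sub), min_n)
            continue
        subtree = prune_to(tree, list(sub["species"]))
        order = leaf_names(subtree)
        sub = sub.set_index("species").loc[order]
        fit = fit_pgls(
            sub["log10_mu_y"].to_numpy(),
            sub["log10_gt"].to_numpy(),
            brownian_vcv(subtree),
            lam=lam,
        )
        fits[group] = fit
        rows.append(
            {
                "group": group,
                "n": fit.n,
                "slope": fit.slope,
                "p_value": float(fit.p_values[1]),
                "adjusted_r2": fit.adjusted_r2,
            }
        )
    return pd.DataFrame(rows), skipped, fits


def compare_fits(fit_a: RegressionFit, fit_b: RegressionFit, which: str = "slope") -> ComparisonResult:
    """Two-sample t-test on a coefficient of two independent fits.

    t = (a - b) / sqrt(SE_a^2 + SE_b^2), df by Welch-Satterthwaite using
    each fit's residual degrees of freedom, two-sided p.
    """
    idx = {"intercept": 0, "slope": 1}[which]
    ea, eb = fit_a.coefficients[idx], fit_b.coefficients[idx]
    sa, sb = fit_a.standard_errors[idx], fit_b.standard_errors[idx]
    if not (np.isfinite(sa) and np.isfinite(sb) and sa > 0 and sb > 0):
        raise AnalysisError("both fits need a finite positive SE for the comparison")
    t = (ea - eb) / np.hypot(sa, sb)
    df = (sa**2 + sb**2) ** 2 / (
        sa**4 / fit_a.df_residual + sb**4 / fit_b.df_residual
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult(float(t), float(df), float(p))


def doubling_effect(slope: float) -> float:
    """Percent change in mu_y per doubling of generation time.

    A log-log slope b means mu_y scales as GT^b, so doubling GT multiplies
    mu_y by 2^b; returns 100 * (1 - 2^b), positive for negative slopes
    (a reduction).
    """
    if not np.isfinite(slope):
        raise AnalysisError("slope must be finite")
    return 100.0 * (1.0 - 2.0**slope)
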