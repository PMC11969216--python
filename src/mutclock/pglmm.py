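"""Gaussian phylogenetic mixed model (identity link).

The model is y = X beta + u + e with u ~ N(0, sigma_p^2 * C) a species-level
random effect whose covariance is the Brownian phylogenetic matrix C, and
e ~ N(0, sigma_r^2 * I) independent residual error.  Fixed effects can
include the taxonomic group (treatment contrasts, alphabetically first
group as reference) and a group-by-slope interaction.

Estimation is by full maximum likelihood (so likelihood-ratio tests on
fixed effects are valid).  Internally the total covariance is written
sigma^2 * (h * C/mean(diag C) + (1 - h) * I) with the mixing proportion
h in [0, 1]; sigma^2 is profiled analytically and h is found by bounded
one-dimensional search, which is deterministic and makes both variance
boundaries (pure phylogenetic, pure i.i.d.) exactly attainable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize_scalar

from .errors import AnalysisError
from .pgls import _chol_with_jitter
from .phylo import PhyloCovariance

log = logging.getLogger(__name__)

__all__ = ["MixedFit", "ModelComparison", "build_design", "fit_pglmm", "compare_models"]

FORMULAS = ("base", "group", "interaction")


@dataclass(frozen=True)
class MixedFit:
    formula: str
    coefficient_names: tuple[str, ...]
    fixed_effects: np.ndarray
    standard_errors: np.ndarray
    sigma2_phylo: float  # scales the Brownian covariance C
    sigma2_resid: float  # scales the identity
    log_likelihood: float
    n: int
    n_fixed_params: int
    boundary: bool  # a variance component was estimated at exactly 0

    @property
    def aic(self) -> float:
        k = self.n_fixed_params + 2  # two variance components
        return 2.0 * k - 2.0 * self.log_likelihood

    def coefficient(self, name: str) -> float:
        return float(self.fixed_effects[self.coefficient_names.index(name)])


@dataclass(frozen=True)
class ModelComparison:
    table: list  # dicts: label, log_likelihood, k, aic, delta_aic
    lrt: list = field(default_factory=list)  # dicts: pair, statistic, df, p, boundary


def build_design(x, groups, formula: str):
    """Design matrix for the requested fixed-effect structure.

    base: intercept + slope; group: + treatment dummies; interaction:
    + per-group slope offsets.  Returns (X, column names).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if formula not in FORMULAS:
        raise AnalysisError(f"unknown formula {formula!r}; choose from {FORMULAS}")
    cols = [np.ones(n), x]
    names = ["intercept", "slope"]
    if formula in ("group", "interaction"):
        groups = np.asarray(groups)
        if groups.shape != (n,):
            raise AnalysisError("groups must align with x")
        levels = sorted(set(groups))
        if len(levels) < 2:
            raise AnalysisError("group terms need at least 2 groups")
        for lev in levels[1:]:
            cols.append((groups == lev).astype(float))
            names.append(f"group[{lev}]")
        if formula == "interaction":
            for lev in levels[1:]:
                if np.sum(groups == lev) < 3:
                    raise AnalysisError(
                        f"group {lev!r} has < 3 members; interaction slope unidentifiable"
                    )
                cols.append((groups == lev).astype(float) * x)
                names.append(f"slope:group[{lev}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # report which column is aliased with the ones before it
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise AnalysisError(f"fixed-effect design is rank deficient: {names[j]!r} is aliased")
        raise AnalysisError("fixed-effect design is rank deficient")
    return X, tuple(names)


def _profile(y, X, Cs, h):
    """Profiled ML at mixing proportion h: returns (ll, beta, XtWiX_inv, s2)."""
    n = len(y)
    W = h * Cs + (1.0 - h) * np.eye(n)
    L = _chol_with_jitter(W)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    s2 = rss / n
    logdetW = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdetW + n)
    XtX_inv = cho_solve((cholesky(XtX, lower=True), True), np.eye(XtX.shape[0]))
    return ll, beta, XtX_inv, s2


def fit_pglmm(y, x, groups, C: PhyloCovariance, formula: str = "base",
              fix_phylo_proportion: float | None = None) -> MixedFit:
    """ML fit of the Gaussian phylogenetic mixed model.

    ``fix_phylo_proportion`` pins the phylogenetic mixing proportion h
    (h = 1 is the pure-Brownian limit, equivalent to PGLS with lambda = 1;
    h = 0 is ordinary regression); by default h is estimated.
    """
    y = np.asarray(y, dtype=float)
    n = C.n
    if y.shape != (n,):
        raise AnalysisError(f"y must have length n = {n} matching the covariance")
    X, names = build_design(x, groups, formula)
    cbar = float(np.mean(np.diag(C.matrix)))
    if cbar <= 0:
        raise AnalysisError("degenerate covariance: zero tip depths")
    Cs = C.matrix / cbar

    if fix_phylo_proportion is not None:
        h_hat = float(fix_phylo_proportion)
        if not 0.0 <= h_hat <= 1.0:
            raise AnalysisError("fix_phylo_proportion must lie in [0, 1]")
    else:
        def neg_ll(h):
            return -_profile(y, X, Cs, h)[0]

        res = minimize_scalar(neg_ll, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-9})
        if not np.isfinite(res.fun):
            raise AnalysisError("mixed-model likelihood optimization failed to converge")
        h_hat = min([0.0, 1.0, float(res.x)], key=neg_ll)

    ll, beta, XtX_inv, s2 = _profile(y, X, Cs, h_hat)
    se = np.sqrt(s2 * np.diag(XtX_inv))
    boundary = h_hat in (0.0, 1.0) and fix_phylo_proportion is None
    if boundary:
        log.info("variance component on boundary (h = %g); LRTs involving it are conservative", h_hat)
    return MixedFit(
        formula=formula,
        coefficient_names=names,
        fixed_effects=beta,
        standard_errors=se,
        sigma2_phylo=h_hat * s2 / cbar,
        sigma2_resid=(1.0 - h_hat) * s2,
        log_likelihood=ll,
        n=n,
        n_fixed_params=X.shape[1],
        boundary=boundary,
    )


def compare_models(fits: list[tuple[str, MixedFit]],
                   nested_pairs: list[tuple[str, str]] | None = None) -> ModelComparison:
    """AIC ranking plus likelihood-ratio tests for declared nested pairs.

    ``fits`` is an ordered list of (label, fit) on identical data; ties in
    AIC are broken by input order.  Each nested pair is (smaller, larger)
    by label; the LRT uses chi-square df equal to the difference in
    fixed-effect parameter counts.
    """
    if not fits:
        raise AnalysisError("no fits to compare")
    labels = [lb for lb, _ in fits]
    if len(set(labels)) != len(labels):
        raise AnalysisError("fit labels must be unique")
    ns = {f.n for _, f in fits}
    if len(ns) != 1:
        raise AnalysisError(f"fits are on different sample sizes: {sorted(ns)}")
    aics = {lb: f.aic for lb, f in fits}
    best = min(aics.values())
    table = [
        {
            "label": lb,
            "log_likelihood": f.log_likelihood,
            "k": f.n_fixed_params + 2,
            "aic": f.aic,
            "delta_aic": f.aic - best,
        }
        for lb, f in fits
    ]
    by_label = dict(fits)
    lrt = []
    for small, large in nested_pairs or []:
        fs, fl = by_label[small], by_label[large]
        ddf = fl.n_fixed_params - fs.n_fixed_params
        if ddf <= 0:
            raise AnalysisError(f"pair ({small}, {large}) is not nested small-in-large")
        stat = 2.0 * (fl.log_likelihood - fs.log_likelihood)
        if stat < -1e-6:
            raise AnalysisError(
                f"negative LRT statistic for ({small}, {large}); models are not nested "
                "on the same data"
            )
        stat = max(stat, 0.0)
        lrt.append(
            {
                "pair": (small, large),
                "statistic": stat,
                "df": ddf,
                "p": float(stats.chi2.sf(stat, ddf)),
                "boundary": fs.boundary or fl.boundary,
            }
        )
    return ModelComparison(table, lrt)
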