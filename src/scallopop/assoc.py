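"""Individual-level genotype-phenotype association.

A random-intercept linear mixed model regresses a phenotype (shape PC1 or
the colour index) on genetic principal components, with population as the
grouping factor so that among-population structure does not masquerade as an
individual-level association. Parameters are estimated by maximum likelihood
through a one-dimensional profile over the variance ratio
``lambda = var_between / var_resid`` (the per-group covariance
``I + lambda * J`` inverts in closed form), and each fixed coefficient gets
a 1-df Wald chi-square. A likelihood-ratio variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .results import TestResult

__all__ = ["MixedModelFit", "lmm_random_intercept", "run_association"]


@dataclass
class MixedModelFit:
    fixed_effects: np.ndarray
    se: np.ndarray
    var_between: float
    var_resid: float
    wald_chi2: np.ndarray
    p: np.ndarray
    loglik: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.var_between < 0 or self.var_resid <= 0:
            raise ValueError("variance components out of range")


def _profile_pieces(y, X, group_slices, lam):
    """GLS pieces for V = I + lam * J per group; returns XtVX, XtVy, yty_V,
    logdet(V)."""
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for sl in group_slices:
        Xg, yg = X[sl], y[sl]
        ng = len(yg)
        w = lam / (1.0 + ng * lam)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        XtVX += Xg.T @ Xg - w * np.outer(sx, sx)
        XtVy += Xg.T @ yg - w * sx * sy
        ytVy += yg @ yg - w * sy * sy
        logdet += np.log1p(ng * lam)
    return XtVX, XtVy, ytVy, logdet


def _profile_loglik(y, X, group_slices, lam):
    n = len(y)
    XtVX, XtVy, ytVy, logdet = _profile_pieces(y, X, group_slices, lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - XtVy @ beta
    rss = max(rss, 1e-300)
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, beta, sigma2, XtVX


def lmm_random_intercept(y, X, groups, test: str = "wald") -> MixedModelFit:
    """Maximum-likelihood random-intercept linear mixed model.

    ``X`` is the fixed-effect design (include a constant column yourself).
    ``test`` selects per-coefficient p-values: 1-df Wald chi-square
    (default) or likelihood-ratio chi-square from refitting without each
    column.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("y and X must have matching rows")
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [j for j in range(X.shape[1]) if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"singular design: collinear columns {bad}")

    order = np.argsort(groups, kind="stable")
    y_s, X_s, g_s = y[order], X[order], groups[order]
    bounds_idx = np.concatenate([[0], np.nonzero(g_s[1:] != g_s[:-1])[0] + 1, [len(y)]])
    slices = [slice(bounds_idx[i], bounds_idx[i + 1]) for i in range(len(bounds_idx) - 1)]

    def neg_ll(u):
        return -_profile_loglik(y_s, X_s, slices, np.exp(u))[0]

    res = optimize.minimize_scalar(neg_ll, bounds=(-14.0, 10.0), method="bounded",
                                   options={"xatol": 1e-10})
    ll_opt = -res.fun
    lam = float(np.exp(res.x))
    ll0 = _profile_loglik(y_s, X_s, slices, 0.0)[0]
    if ll0 >= ll_opt:
        lam, ll_opt = 0.0, ll0

    ll, beta, sigma2, XtVX = _profile_loglik(y_s, X_s, slices, lam)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    if test == "wald":
        pvals = stats.chi2.sf(wald, 1)
    elif test == "lrt":
        pvals = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            Xr = np.delete(X_s, j, axis=1)
            res_r = optimize.minimize_scalar(
                lambda u: -_profile_loglik(y_s, Xr, slices, np.exp(u))[0],
                bounds=(-14.0, 10.0), method="bounded", options={"xatol": 1e-10},
            )
            ll_r = max(-res_r.fun, _profile_loglik(y_s, Xr, slices, 0.0)[0])
            pvals[j] = stats.chi2.sf(2.0 * (ll - ll_r), 1)
    else:
        raise ValueError("test must be 'wald' or 'lrt'")

    return MixedModelFit(
        fixed_effects=beta,
        se=se,
        var_between=lam * sigma2,
        var_resid=sigma2,
        wald_chi2=wald,
        p=pvals,
        loglik=ll,
        meta={"lambda": lam, "test": test, "n_groups": len(labels)},
    )


def run_association(
    phenotype,
    genetic_pcs: np.ndarray,
    population_labels,
    exclude: list[str] | None = None,
    test: str = "wald",
) -> dict[str, TestResult]:
    """Phenotype ~ genetic PCs with a population random intercept.

    The first two genetic PCs (columns of ``genetic_pcs``) enter together as
    fixed effects; ``exclude`` drops named populations (the typical use is
    removing an outlier population that is both genetically and
    phenotypically distinct) before fitting.
    """
    y = np.asarray(phenotype, dtype=float)
    pcs = np.asarray(genetic_pcs, dtype=float)
    if pcs.ndim != 2:
        raise ValueError("genetic_pcs must be 2-D (individuals x components)")
    pops = np.asarray(population_labels)
    if not (len(y) == pcs.shape[0] == len(pops)):
        raise ValueError("inputs must be aligned by individual")
    keep = ~np.isin(pops, exclude or [])
    y, pcs, pops = y[keep], pcs[keep], pops[keep]
    names = [f"PC{i + 1}" for i in range(pcs.shape[1])]
    if len(np.unique(pops)) < 3:
        return {nm: TestResult(statistic=np.nan, p=np.nan, testable=False) for nm in names}

    X = np.column_stack([np.ones(len(y)), pcs])
    fit = lmm_random_intercept(y, X, pops, test=test)
    out: dict[str, TestResult] = {}
    for i, nm in enumerate(names):
        j = i + 1  # skip intercept
        out[nm] = TestResult(
            statistic=float(fit.wald_chi2[j] if test == "wald" else stats.chi2.isf(fit.p[j], 1)),
            df=1,
            p=float(fit.p[j]),
            meta={"estimate": float(fit.fixed_effects[j]), "se": float(fit.se[j]),
                  "n_used": int(len(y)), "fit": fit},
        )
    return out
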