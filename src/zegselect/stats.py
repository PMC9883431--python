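"""Count-based inference for selection experiments.

Whole-embryo knock-in (or indel) read counts are modeled with negative
binomial regression using the log total read count of each sample as an
offset, so the selected-versus-excluded fixed effect is a log ratio of
editing frequencies.  When several indel alleles enter one comparison, the
allele identity gets a random intercept and the marginal likelihood is
integrated by Gauss-Hermite quadrature.  Dispersion uses the "size"
parameterization: Var(Y) = mu + mu^2 / theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import gammaln, logsumexp
from scipy.stats import norm, studentized_range


class StatsError(ValueError):
    pass


@dataclass
class NBFit:
    """A fitted negative binomial (possibly mixed) regression."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    theta: float
    llf: float
    converged: bool
    n_obs: int
    method: str
    sigma_re: float | None = None  # random-intercept SD, mixed fits only
    boundary: bool = False  # random-intercept variance hit zero

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise StatsError("theta must be positive")


def _validate_counts(counts: np.ndarray, offsets: np.ndarray) -> None:
    if counts.ndim != 1:
        raise StatsError("counts must be a 1-d array")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise StatsError("counts must be non-negative integers")
    if not counts.any():
        raise StatsError("all counts are zero: nothing to fit")
    if not np.isfinite(offsets).all():
        raise StatsError("offsets must be finite")


def fit_nb_glm(
    counts,
    exog,
    offsets,
    alpha: float | None = None,
    tol: float = 1e-8,
) -> NBFit:
    """NB2 regression with log link and offset; dispersion by profile ML.

    The coefficient step is iteratively reweighted least squares at fixed
    dispersion; the dispersion step maximizes the profile likelihood over
    ``alpha = 1/theta``.  Passing ``alpha`` fixes the dispersion (``alpha``
    near zero reproduces a Poisson GLM).
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(exog, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    off = np.asarray(offsets, dtype=float)
    _validate_counts(y, off)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatsError("design matrix is rank deficient")
    names = (
        list(exog.columns)
        if isinstance(exog, pd.DataFrame)
        else [f"x{i}" for i in range(X.shape[1])]
    )

    def _fit_at(a: float):
        fam = sm.families.NegativeBinomial(alpha=max(a, 1e-12))
        model = sm.GLM(y, X, family=fam, offset=off)
        return model.fit(tol=tol, maxiter=200)

    if alpha is None:
        res_opt = optimize.minimize_scalar(
            lambda la: -_fit_at(math.exp(la)).llf,
            bounds=(-12.0, 5.0),
            method="bounded",
            options={"xatol": 1e-8},
        )
        alpha_hat = float(math.exp(res_opt.x))
    else:
        if alpha < 0:
            raise StatsError("alpha must be >= 0")
        alpha_hat = float(max(alpha, 1e-12))
    res = _fit_at(alpha_hat)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        raise StatsError("negative binomial fit did not converge")
    return NBFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        theta=1.0 / alpha_hat,
        llf=float(res.llf),
        converged=converged,
        n_obs=int(y.size),
        method="nb_glm_profile" if alpha is None else "nb_glm_fixed_alpha",
    )


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def fit_nb_random_intercept(
    counts,
    selected,
    allele_ids,
    offsets,
    n_quad: int = 25,
    sigma_floor: float = 1e-3,
) -> NBFit:
    """NB regression with a per-allele random intercept (Gauss-Hermite ML).

    ``selected`` is the binary fixed factor (selected vs excluded embryo);
    ``allele_ids`` group observations by indel allele.  With a single
    allele the model reduces to :func:`fit_nb_glm`, and a random-intercept
    SD estimated at (or below) ``sigma_floor`` triggers the same fallback
    with the boundary flagged.
    """
    y = np.asarray(counts, dtype=float)
    x = np.asarray(selected, dtype=float)
    off = np.asarray(offsets, dtype=float)
    _validate_counts(y, off)
    alleles = pd.Categorical(np.asarray(allele_ids))
    groups = alleles.codes
    n_groups = len(alleles.categories)
    X = np.column_stack([np.ones_like(x), x])
    if n_groups < 2:
        fit = fit_nb_glm(y, X, off)
        return NBFit(
            params=fit.params.set_axis(["intercept", "selected"]),
            bse=fit.bse.set_axis(["intercept", "selected"]),
            pvalues=fit.pvalues.set_axis(["intercept", "selected"]),
            theta=fit.theta,
            llf=fit.llf,
            converged=fit.converged,
            n_obs=fit.n_obs,
            method="nb_glm_delegated",
            sigma_re=None,
        )

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(weights) - 0.5 * math.log(math.pi)

    def nll(par: np.ndarray) -> float:
        b0, b1, log_theta, log_sigma = par
        theta = math.exp(log_theta)
        sigma = math.exp(log_sigma)
        eta = off + b0 + b1 * x
        # (n_obs, n_quad): linear predictor at each quadrature point
        mu = np.exp(np.clip(eta[:, None] + math.sqrt(2.0) * sigma * nodes[None, :], -700, 700))
        lp = _nb_logpmf(y[:, None], mu, theta)
        group_lp = np.zeros((n_groups, n_quad))
        np.add.at(group_lp, groups, lp)
        return -float(np.sum(logsumexp(group_lp + log_w[None, :], axis=1)))

    start_glm = fit_nb_glm(y, X, off)
    x0 = np.array(
        [start_glm.params.iloc[0], start_glm.params.iloc[1], math.log(start_glm.theta), math.log(0.5)]
    )
    res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 500})
    b0, b1, log_theta, log_sigma = res.x
    sigma = math.exp(log_sigma)
    if sigma <= sigma_floor:
        fit = fit_nb_glm(y, X, off)
        return NBFit(
            params=fit.params.set_axis(["intercept", "selected"]),
            bse=fit.bse.set_axis(["intercept", "selected"]),
            pvalues=fit.pvalues.set_axis(["intercept", "selected"]),
            theta=fit.theta,
            llf=fit.llf,
            converged=fit.converged,
            n_obs=fit.n_obs,
            method="nb_glm_boundary_refit",
            sigma_re=0.0,
            boundary=True,
        )
    if not res.success and res.status != 2:  # status 2: precision loss near optimum
        raise StatsError(f"mixed NB fit did not converge: {res.message}")

    hess = _numerical_hessian(nll, res.x)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as err:
        raise StatsError("singular Hessian in mixed NB fit") from err
    se = np.sqrt(np.clip(np.diag(cov)[:2], 1e-300, None))
    params = pd.Series([b0, b1], index=["intercept", "selected"])
    bse = pd.Series(se, index=params.index)
    z = params / bse
    pvals = pd.Series(2.0 * norm.sf(np.abs(z)), index=params.index)
    return NBFit(
        params=params,
        bse=bse,
        pvalues=pvals,
        theta=float(math.exp(log_theta)),
        llf=-float(res.fun),
        converged=True,
        n_obs=int(y.size),
        method="nb_mixed_gh",
        sigma_re=float(sigma),
    )


def _numerical_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    h = eps * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = x.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = x.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = x.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = x.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            H[i, j] = H[j, i] = (fun(pp) - fun(pm) - fun(mp) + fun(mm)) / (
                4.0 * h[i] * h[j]
            )
    return H


# ---------------------------------------------------------------------------
# multiplicity corrections


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment, capped at 1; ``m`` defaults to len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise StatsError("p-values must lie in [0, 1]")
    m = m if m is not None else p.size
    return np.minimum(1.0, p * m)


def tukey_hsd(means, ses, df_resid: float) -> pd.DataFrame:
    """All pairwise comparisons of fitted group means via the studentized range.

    ``means`` and ``ses`` are the fitted (model-scale) group means and their
    standard errors; the adjusted p for pair (i, j) uses
    q = |mean_i - mean_j| / sqrt((se_i^2 + se_j^2) / 2) against the
    studentized range with k groups and ``df_resid`` degrees of freedom.
    With two groups this reduces to the unadjusted t-test (q = sqrt(2)|t|).
    """
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    k = means.size
    if k < 2:
        raise StatsError("Tukey HSD needs at least 2 groups")
    if ses.size != k or (ses <= 0).any():
        raise StatsError("need one positive SE per group")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se_pair = math.sqrt((ses[i] ** 2 + ses[j] ** 2) / 2.0)
            q = abs(means[i] - means[j]) / se_pair
            p = float(studentized_range.sf(q, k, df_resid))
            rows.append({"group_i": i, "group_j": j, "q": q, "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)


def adjust_pvalues(pvals=None, method: str = "bonferroni", **kwargs):
    """Dispatch to :func:`bonferroni` (needs pvals) or :func:`tukey_hsd`
    (needs means/ses/df_resid)."""
    if method == "bonferroni":
        return bonferroni(pvals, m=kwargs.get("m"))
    if method == "tukey_hsd":
        return tukey_hsd(kwargs["means"], kwargs["ses"], kwargs["df_resid"])
    raise StatsError(f"unknown method {method!r}")


def significance_stars(p: float) -> str:
    """Conventional star coding: *** <0.001, ** <0.01, * <0.05, else NS."""
    if not 0 <= p <= 1:
        raise StatsError("p-value must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"
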