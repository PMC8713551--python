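"""Logistic regression with crossed random intercepts, fit by Laplace ML.

The accuracy models need a binary-outcome model with two *crossed* grouping
factors (every worker sees many trials, every trial is seen by many workers):

    logit P(y_ij = 1) = x_ij' beta + u_w(i) + u_t(j),
    u_w ~ N(0, s2_w),  u_t ~ N(0, s2_t)

Estimation maximizes the Laplace approximation of the marginal likelihood.
For fixed variance parameters, the joint penalized log-likelihood in
(beta, u) is maximized by Newton iterations (the model matrix [X Z] is
sparse; the Hessian is a small dense (p + q_w + q_t) matrix), and the
approximate profiled log-likelihood

    l(theta) = l(y | eta_hat) - u_hat' D^-1 u_hat / 2
               - log det D / 2 - log det(Z' W Z + D^-1) / 2

is optimized over theta = (log s2_w, log s2_t) by Nelder-Mead, warm-starting
the inner Newton solve. This is the same approximation family as lme4's
glmer with the fixed effects estimated at the joint mode.

Standard errors for the fixed effects come from the inverse of the joint
penalized Hessian (Schur complement on the beta block), with two-sided Wald
z tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

__all__ = ["MixedModelFit", "fit_crossed_logistic", "SeparationError"]

_ETA_CLIP = 30.0


class SeparationError(RuntimeError):
    """Raised when the outcome is (quasi-)separable and the MLE diverges."""


@dataclass
class MixedModelFit:
    """Result of a crossed random-intercepts logistic fit."""

    params: pd.Series                  # fixed-effect estimates
    bse: pd.Series                     # Wald standard errors
    vc: dict[str, float]               # random-intercept variances by factor
    loglik: float                      # Laplace-approximated marginal ll
    converged: bool
    n_obs: int
    method: str = "laplace"
    fixed_lp_var: float = float("nan")  # var of X @ beta over the sample
    random_effects: dict[str, pd.Series] = field(default_factory=dict)
    n_iter: int = 0

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse,
                             "z": self.zvalues, "p": self.pvalues})


def _encode(labels) -> tuple[np.ndarray, pd.Index]:
    codes, uniques = pd.factorize(np.asarray(labels), sort=True)
    return codes, pd.Index(uniques)


def _indicator(codes: np.ndarray, q: int) -> sparse.csr_matrix:
    n = codes.shape[0]
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, q))


def _penalized_newton(A, y, pen_diag, psi0, max_iter=100, tol=1e-10):
    """Maximize sum[y*eta - log(1+e^eta)] - psi' P psi / 2 over psi."""
    psi = psi0.copy()
    eta = np.clip(A @ psi, -_ETA_CLIP, _ETA_CLIP)
    mu = 1.0 / (1.0 + np.exp(-eta))

    def pll(psi, eta, mu):
        # Bernoulli log-lik written to stay finite at clipped eta
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - 0.5 * float(psi @ (pen_diag * psi))

    f = pll(psi, eta, mu)
    H = None
    for it in range(max_iter):
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        g = A.T @ (y - mu) - pen_diag * psi
        Aw = A.multiply(w[:, None])
        H = (A.T @ Aw).toarray()
        H[np.diag_indices_from(H)] += pen_diag
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step halving
        t = 1.0
        for _ in range(30):
            psi_new = psi + t * step
            eta_new = np.clip(A @ psi_new, -_ETA_CLIP, _ETA_CLIP)
            mu_new = 1.0 / (1.0 + np.exp(-eta_new))
            f_new = pll(psi_new, eta_new, mu_new)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        gain = f_new - f
        psi, eta, mu, f = psi_new, eta_new, mu_new, f_new
        if abs(gain) < tol * (1.0 + abs(f)):
            break
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    Aw = A.multiply(w[:, None])
    H = (A.T @ Aw).toarray()
    H[np.diag_indices_from(H)] += pen_diag
    return psi, f, H, it + 1


def fit_crossed_logistic(
    y,
    X: pd.DataFrame,
    groups: dict[str, "pd.Series | np.ndarray"],
    start_vc: float = 1.0,
    maxiter_outer: int = 400,
) -> MixedModelFit:
    """Fit a logistic model with one random intercept per grouping factor.

    Parameters
    ----------
    y : binary outcome (0/1), length n.
    X : fixed-effect design matrix (include an intercept column explicitly
        or pass named columns; an ``Intercept`` column is prepended when
        absent).
    groups : mapping factor name -> length-n labels. Factors are crossed.
    """
    y = np.asarray(y, dtype=float)
    if not X.index.is_unique:
        X = X.reset_index(drop=True)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError(
            "outcome is constant; the logistic MLE does not exist")
    if "Intercept" not in X.columns:
        X = X.copy()
        X.insert(0, "Intercept", 1.0)
    n, p = X.shape
    if n != len(y):
        raise ValueError("X and y lengths differ")

    factor_names = list(groups)
    codes_list, levels_list = [], []
    for name in factor_names:
        codes, levels = _encode(groups[name])
        codes_list.append(codes)
        levels_list.append(levels)
    qs = [len(lv) for lv in levels_list]
    Zs = [_indicator(c, q) for c, q in zip(codes_list, qs)]
    Xs = sparse.csr_matrix(np.asarray(X, dtype=float))
    A = sparse.hstack([Xs] + Zs, format="csr")
    q_total = sum(qs)

    psi_warm = np.zeros(p + q_total)

    def laplace_nll(log_vc: np.ndarray) -> float:
        nonlocal psi_warm
        variances = np.exp(np.clip(log_vc, -12.0, 12.0))
        pen = np.concatenate(
            [np.zeros(p)] + [np.full(q, 1.0 / v)
                             for q, v in zip(qs, variances)])
        psi, f_pen, H, _ = _penalized_newton(A, y, pen, psi_warm)
        psi_warm = psi
        Huu = H[p:, p:]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return np.inf
        logdet_D = float(np.dot(qs, np.log(variances)))
        ll = f_pen - 0.5 * logdet_D - 0.5 * logdet
        return -ll

    x0 = np.log(np.full(len(qs), start_vc))
    res = optimize.minimize(
        laplace_nll, x0, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": maxiter_outer,
                 "maxfev": maxiter_outer})
    variances = np.exp(np.clip(res.x, -12.0, 12.0))
    pen = np.concatenate(
        [np.zeros(p)] + [np.full(q, 1.0 / v) for q, v in zip(qs, variances)])
    psi, f_pen, H, n_inner = _penalized_newton(A, y, pen, psi_warm)
    beta = psi[:p]
    if np.max(np.abs(beta)) > 0.8 * _ETA_CLIP:
        raise SeparationError(
            "fixed-effect estimates diverged; data are likely separable "
            f"(max |beta| = {np.max(np.abs(beta)):.1f})")
    try:
        Hinv = np.linalg.inv(H)
        bse = np.sqrt(np.diag(Hinv)[:p])
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)

    u = psi[p:]
    re: dict[str, pd.Series] = {}
    off = 0
    for name, q, levels in zip(factor_names, qs, levels_list):
        re[name] = pd.Series(u[off:off + q], index=levels, name=name)
        off += q

    lp_fixed = np.asarray(X, dtype=float) @ beta
    fit = MixedModelFit(
        params=pd.Series(beta, index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        vc={name: float(v) for name, v in zip(factor_names, variances)},
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_obs=n,
        fixed_lp_var=float(np.var(lp_fixed, ddof=1)) if n > 1 else 0.0,
        random_effects=re,
        n_iter=int(res.nit),
    )
    return fit
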