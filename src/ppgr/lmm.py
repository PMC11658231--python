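"""Random-intercept linear mixed model by profiled (RE)ML.

For the model y_ij = x_ij' beta + b_i + e_ij with b_i ~ N(0, s2_b) and
e_ij ~ N(0, s2_e), both beta and s2_e can be profiled out of the (restricted)
likelihood, leaving a one-dimensional optimisation over the variance ratio
psi = s2_b / s2_e.  For a given psi the GLS normal equations involve only
per-cluster row sums (Woodbury identity for V^-1 = (I - a_i J)/s2_e with
a_i = psi / (1 + n_i psi)), so each evaluation costs O(G p^2).  This makes
the ~10^3 refits of a cluster bootstrap cheap while agreeing with
general-purpose REML fitters to optimiser precision (cross-checked against
statsmodels MixedLM and lme4 in the test suite).

Fixed-effect p-values are two-sided Wald tests on the normal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LMMResult", "fit_lmm"]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LMMResult:
    """Point estimates and inference for a random-intercept fit."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma2_between: float
    sigma2_residual: float
    n_obs: int
    n_groups: int
    converged: bool
    reml: bool
    message: str = ""
    cov_params: np.ndarray | None = field(default=None, repr=False)

    @property
    def icc(self) -> float:
        tot = self.sigma2_between + self.sigma2_residual
        return self.sigma2_between / tot if tot > 0 else float("nan")


def _cluster_stats(X: np.ndarray, y: np.ndarray, codes: np.ndarray):
    order = np.argsort(codes, kind="stable")
    Xs, ys, cs = X[order], y[order], codes[order]
    starts = np.flatnonzero(np.r_[True, cs[1:] != cs[:-1]])
    n_i = np.diff(np.r_[starts, cs.size]).astype(np.float64)
    s = np.add.reduceat(Xs, starts, axis=0)          # G x p row sums
    u = np.add.reduceat(ys, starts)                  # G
    return Xs, ys, s, u, n_i


def fit_lmm(y, X, groups, reml: bool = True, term_names=None) -> LMMResult:
    """Fit a linear mixed model with a person-specific random intercept.

    Parameters
    ----------
    y, X
        Outcome vector and fixed-effect design matrix (including the
        intercept column).  ``X`` may be a DataFrame, in which case its
        columns name the terms.
    groups
        Cluster (participant) labels, one per row.
    reml
        Restricted maximum likelihood (default) or plain ML.
    """
    if isinstance(X, pd.DataFrame):
        term_names = list(X.columns) if term_names is None else term_names
        X = X.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(X, dtype=np.float64)
        if term_names is None:
            term_names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=np.float64)
    codes, _ = pd.factorize(np.asarray(groups))
    n, p = X.shape
    if y.shape[0] != n or codes.shape[0] != n:
        raise ValueError("y, X and groups must have matching lengths")
    if n <= p:
        raise ValueError("more fixed-effect terms than observations")

    Xs, ys, s, u, n_i = _cluster_stats(X, y, codes)
    Sxx = Xs.T @ Xs
    Sxy = Xs.T @ ys
    Syy = float(ys @ ys)
    dof = (n - p) if reml else n

    def profile(log_psi: float):
        psi = np.exp(log_psi)
        a = psi / (1.0 + n_i * psi)
        A = Sxx - (s * a[:, None]).T @ s
        b = Sxy - s.T @ (a * u)
        try:
            cho = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular fixed-effect design")
        beta = np.linalg.solve(cho.T, np.linalg.solve(cho, b))
        quad = Syy - float(a @ (u * u)) - float(beta @ b)
        quad = max(quad, 1e-12)
        sigma2_e = quad / dof
        crit = dof * np.log(sigma2_e) + float(np.sum(np.log1p(n_i * psi)))
        if reml:
            crit += 2.0 * float(np.sum(np.log(np.diag(cho))))
        return crit, beta, sigma2_e, A

    obj = lambda lp: profile(lp)[0]
    res = optimize.minimize_scalar(obj, bounds=(-14.0, 10.0), method="bounded",
                                   options={"xatol": 1e-9})
    log_psi = float(res.x)
    crit, beta, sigma2_e, A = profile(log_psi)
    # Guard the lower boundary: psi ~ 0 means no between-cluster variance.
    crit0 = obj(-14.0)
    if crit0 < crit:
        log_psi = -14.0
        crit, beta, sigma2_e, A = profile(log_psi)
    psi = np.exp(log_psi)
    if psi < 2e-6:
        psi = 0.0
    cov = sigma2_e * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    idx = pd.Index(term_names, name="term")
    return LMMResult(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        sigma2_between=psi * sigma2_e,
        sigma2_residual=sigma2_e,
        n_obs=n,
        n_groups=int(n_i.size),
        converged=bool(res.success),
        reml=reml,
        message=str(getattr(res, "message", "")),
        cov_params=cov,
    )
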