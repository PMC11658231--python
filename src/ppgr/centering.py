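"""Within-/between-person decomposition of longitudinal exposures.

Person-mean centering splits a repeated measure x_ij into a stable
between-person part (the person mean, optionally grand-mean centered) and
a fluctuating within-person part (deviation from the person mean).  The
share of total variance sitting between persons is the intraclass
correlation (ICC) from an intercept-only random-intercept model; the
within-person share is 1 - ICC.  Binary measures use a logistic
random-intercept model and the latent-threshold scale, where the residual
variance is pi^2 / 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .lmm import fit_lmm

__all__ = ["person_center", "VarianceDecomposition", "icc_continuous",
           "icc_binary", "variance_contribution_table"]


def person_center(table: pd.DataFrame, exposure_names: list[str],
                  id_col: str = "participant_id",
                  grand_center: bool = True) -> pd.DataFrame:
    """Add ``<name>_within`` / ``<name>_between`` columns for each exposure.

    ``between`` is the person mean (minus the grand mean when
    ``grand_center``, which leaves slopes untouched but makes the model
    intercept interpretable); ``within`` is the occasion value minus the
    person mean, so within + person mean reconstructs the value exactly
    and within components sum to zero inside each participant.  Boolean
    flags are coerced to 0/1 first.
    """
    out = table.copy()
    grp = out.groupby(id_col, sort=False)
    for name in exposure_names:
        x = out[name].astype(np.float64)
        mean_i = grp[name].transform("mean").astype(np.float64)
        out[f"{name}_within"] = x - mean_i
        out[f"{name}_between"] = mean_i - (x.mean() if grand_center else 0.0)
    return out


@dataclass
class VarianceDecomposition:
    measure: str
    icc: float
    between_var: float
    within_var: float
    scale: str  # "continuous" or "binary_latent"
    converged: bool = True
    message: str = ""

    @property
    def within_share(self) -> float:
        return 1.0 - self.icc


def icc_continuous(values, groups, measure: str = "") -> VarianceDecomposition:
    """ICC of a continuous repeated measure via an intercept-only LMM (REML)."""
    values = np.asarray(values, dtype=np.float64)
    X = np.ones((values.size, 1))
    fit = fit_lmm(values, X, groups, reml=True, term_names=["intercept"])
    return VarianceDecomposition(
        measure=measure, icc=fit.icc, between_var=fit.sigma2_between,
        within_var=fit.sigma2_residual, scale="continuous",
        converged=fit.converged, message=fit.message)


_GH_NODES = 41


def _binary_loglik(mu: float, log_sd: float, k_i: np.ndarray, n_i: np.ndarray,
                   nodes: np.ndarray, weights: np.ndarray) -> float:
    # Gauss-Hermite marginal likelihood of a logistic random-intercept model.
    sd = np.exp(log_sd)
    eta = mu + np.sqrt(2.0) * sd * nodes  # Q
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    # cluster x node log-likelihood of k_i successes out of n_i
    ll = k_i[:, None] * log_p[None, :] + (n_i - k_i)[:, None] * log_q[None, :]
    m = ll.max(axis=1, keepdims=True)
    lik = np.log(np.exp(ll - m) @ (weights / np.sqrt(np.pi))) + m[:, 0]
    return float(np.sum(lik))


def icc_binary(flags, groups, measure: str = "") -> VarianceDecomposition:
    """Latent-scale ICC of a binary repeated measure via a logistic GLMM.

    Maximum likelihood with 41-node Gauss-Hermite quadrature; the ICC is
    s2_b / (s2_b + pi^2/3) on the latent-threshold scale.
    """
    y = np.asarray(flags, dtype=np.float64)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary measure must be coded 0/1")
    codes, _ = pd.factorize(np.asarray(groups))
    k_i = np.bincount(codes, weights=y)
    n_i = np.bincount(codes).astype(np.float64)
    if y.min() == y.max():
        raise ValueError("binary measure is constant; ICC undefined")
    nodes, weights = np.polynomial.hermite.hermgauss(_GH_NODES)

    def neg(params):
        return -_binary_loglik(params[0], params[1], k_i, n_i, nodes, weights)

    p_hat = y.mean()
    start = np.array([np.log(p_hat / (1 - p_hat)), 0.0])
    res = optimize.minimize(neg, start, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-9,
                                     "maxiter": 2000})
    sd = float(np.exp(res.x[1]))
    s2b = sd * sd
    s2w = np.pi ** 2 / 3.0
    return VarianceDecomposition(
        measure=measure, icc=s2b / (s2b + s2w), between_var=s2b,
        within_var=s2w, scale="binary_latent",
        converged=bool(res.success), message=str(res.message))


def variance_contribution_table(events: pd.DataFrame, continuous: list[str],
                                binary: list[str],
                                id_col: str = "participant_id") -> pd.DataFrame:
    """Within/between variance shares for each measure, one row per measure."""
    rows = []
    for name in continuous:
        sub = events[[id_col, name]].dropna()
        d = icc_continuous(sub[name], sub[id_col], measure=name)
        rows.append(d)
    for name in binary:
        sub = events[[id_col, name]].dropna()
        d = icc_binary(sub[name], sub[id_col], measure=name)
        rows.append(d)
    return pd.DataFrame({
        "measure": [d.measure for d in rows],
        "scale": [d.scale for d in rows],
        "icc": [d.icc for d in rows],
        "within_pct": [100.0 * d.within_share for d in rows],
        "between_pct": [100.0 * d.icc for d in rows],
        "converged": [d.converged for d in rows],
    })
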