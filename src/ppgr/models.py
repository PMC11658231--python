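"""Association models for postprandial glucose iAUC.

Linear mixed-effect models with person-specific random intercepts relate
the 2-h postprandial iAUC to within-/between-person lifestyle exposures
and meal time, adjusted for baseline covariates and the 2-h pre-prandial
glucose mean.  A *basic* model carries a single exposure (its within and
between parts); the *full* model is mutually adjusted for all exposures.
Confidence intervals come from a participant-level (cluster) bootstrap
with percentile bounds; sensitivity analyses test sex and prediabetes
interactions and refit the full model inside strata, with between-person
exposures excluded there to limit the parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exposures import EXPOSURES, TIME_CATEGORIES, validate_exposure_names
from .lmm import LMMResult, fit_lmm

__all__ = ["ModelSpec", "Design", "build_design", "fit_random_intercept",
           "bootstrap_ci", "interaction_test", "stratified_fit",
           "association_table"]

#: Dummy-expanded covariate columns (reference levels: female, Chinese,
#: secondary-or-below education).
COVARIATE_TERMS = [
    "age", "sex_male", "ethnicity_malay", "ethnicity_indian",
    "education_a_level", "education_university", "smoker", "heavy_alcohol",
    "bmi", "preprandial_mean_2h",
]
MEAL_TIME_TERMS = ["afternoon_1200_1800", "evening_1800_2400"]


@dataclass
class ModelSpec:
    """What goes into one model fit."""

    mode: str = "full"                       # "basic" or "full"
    exposures: list[str] = field(default_factory=lambda: list(EXPOSURES))
    include_between: bool = True
    include_meal_time: bool = True
    covariates: list[str] = field(default_factory=lambda: list(COVARIATE_TERMS))
    outcome: str = "iauc_2h"

    def __post_init__(self) -> None:
        validate_exposure_names(self.exposures)
        if self.mode == "basic" and len(self.exposures) != 1:
            raise ValueError("basic mode takes exactly one exposure")
        if self.mode not in ("basic", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Design:
    y: np.ndarray
    X: pd.DataFrame
    groups: np.ndarray
    n_dropped: int
    spec: ModelSpec
    dropped_terms: list = field(default_factory=list)


def encode_covariates(events: pd.DataFrame) -> pd.DataFrame:
    """Expand raw categorical covariates into the model's dummy columns."""
    out = events.copy()
    if "sex_male" not in out and "sex" in out:
        out["sex_male"] = (out["sex"] == "male").astype(float)
    if "ethnicity" in out:
        out["ethnicity_malay"] = (out["ethnicity"] == "Malay").astype(float)
        out["ethnicity_indian"] = (out["ethnicity"] == "Indian").astype(float)
    if "education" in out:
        out["education_a_level"] = (out["education"] == "a_level").astype(float)
        out["education_university"] = (
            out["education"] == "university_or_above").astype(float)
    for flag in ("smoker", "heavy_alcohol", "prediabetes"):
        if flag in out:
            out[flag] = out[flag].astype(float)
    return out


def _meal_time_dummies(events: pd.DataFrame) -> pd.DataFrame:
    cat = events["time_category"]
    return pd.DataFrame({
        MEAL_TIME_TERMS[0]: (cat == TIME_CATEGORIES[1]).astype(float),
        MEAL_TIME_TERMS[1]: (cat == TIME_CATEGORIES[2]).astype(float),
    }, index=events.index)


def build_design(events: pd.DataFrame, spec: ModelSpec,
                 extra_terms: pd.DataFrame | None = None) -> Design:
    """Assemble outcome, fixed-effect matrix and grouping for one fit.

    Expects an analysis table that has been person-mean centered
    (``<exposure>_within`` / ``<exposure>_between`` columns present).
    Rows with any missing term are dropped (complete case) and counted.
    """
    events = encode_covariates(events)
    cols: dict[str, pd.Series] = {"intercept": pd.Series(1.0, index=events.index)}
    for e in spec.exposures:
        cols[f"{e}_within"] = events[f"{e}_within"]
        if spec.include_between:
            cols[f"{e}_between"] = events[f"{e}_between"]
    if spec.include_meal_time:
        for name, col in _meal_time_dummies(events).items():
            cols[name] = col
    for c in spec.covariates:
        cols[c] = events[c]
    X = pd.DataFrame(cols).astype(float)
    if extra_terms is not None:
        X = pd.concat([X, extra_terms.astype(float)], axis=1)
    y = events[spec.outcome].astype(float)
    keep = X.notna().all(axis=1) & y.notna()
    n_dropped = int((~keep).sum())
    X, y = X[keep], y[keep]
    if len(X) == 0:
        raise ValueError("no usable rows after complete-case filtering")
    # Degenerate (constant) non-intercept columns carry no information and
    # arise routinely in small strata; drop them rather than fail.
    constant = [c for c in X.columns[1:] if X[c].nunique() <= 1]
    X = X.drop(columns=constant)
    # Rank check with named culprits.  Redundant covariate dummies (an empty
    # categorical level inside a stratum) are dropped silently-but-recorded;
    # collinearity that involves an exposure term fails loudly.
    from scipy import linalg as sla
    M = X.to_numpy()
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        _, _, piv = sla.qr(M, mode="economic", pivoting=True)
        dependent = [X.columns[j] for j in piv[rank:]]
        exposure_dep = [c for c in dependent
                        if c.endswith("_within") or c.endswith("_between")]
        if exposure_dep:
            raise ValueError(
                f"rank-deficient design; collinear terms: {dependent}")
        X = X.drop(columns=dependent)
        constant = constant + dependent
    groups = events.loc[X.index, "participant_id"].to_numpy()
    return Design(y=y.to_numpy(), X=X, groups=groups,
                  n_dropped=n_dropped, spec=spec, dropped_terms=constant)


def _term_level(term: str) -> str:
    if term.endswith("_within"):
        return "within"
    if term.endswith("_between"):
        return "between"
    return "context"


def fit_random_intercept(design: Design, engine: str = "fast") -> pd.DataFrame:
    """REML point estimates for a design; one row per fixed-effect term.

    ``engine="fast"`` uses the package's profiled-REML solver;
    ``engine="statsmodels"`` routes through statsmodels MixedLM (slower,
    used for cross-validation).  Estimates are invariant to row order.
    The returned frame carries variance components and convergence
    diagnostics in ``attrs``.
    """
    if engine == "fast":
        fit = fit_lmm(design.y, design.X, design.groups, reml=True)
    elif engine == "statsmodels":
        import statsmodels.api as sm
        m = sm.MixedLM(design.y, design.X.to_numpy(), groups=design.groups)
        r = None
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                r = m.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if r is None:
            raise RuntimeError("statsmodels MixedLM failed to converge")
        fit = LMMResult(
            params=pd.Series(r.fe_params, index=pd.Index(design.X.columns, name="term")),
            bse=pd.Series(np.asarray(r.bse)[: design.X.shape[1]], index=design.X.columns),
            pvalues=pd.Series(np.asarray(r.pvalues)[: design.X.shape[1]],
                              index=design.X.columns),
            sigma2_between=float(np.asarray(r.cov_re)[0, 0]),
            sigma2_residual=float(r.scale),
            n_obs=int(r.nobs), n_groups=len(np.unique(design.groups)),
            converged=bool(r.converged), reml=True)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    out = pd.DataFrame({
        "term": fit.params.index,
        "beta": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "p_value": fit.pvalues.to_numpy(),
    })
    out["level"] = out["term"].map(_term_level)
    out.attrs.update({
        "sigma2_between": fit.sigma2_between,
        "sigma2_residual": fit.sigma2_residual,
        "icc": fit.icc,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
        "converged": fit.converged,
        "n_dropped": design.n_dropped,
    })
    return out


def bootstrap_ci(design: Design, B: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Cluster-bootstrap percentile CIs for every fixed-effect term.

    Participants are resampled with replacement (each draw keeps a
    participant's full meal set and receives a fresh cluster label, which
    respects the random-intercept dependence); the model is refit on every
    replicate.  Non-converging replicates are dropped and counted.
    """
    if B < 200:
        raise ValueError("use at least 200 bootstrap replicates")
    rng = np.random.default_rng(seed)
    X = design.X.to_numpy()
    y = design.y
    ids = np.asarray(design.groups)
    uniq, codes = np.unique(ids, return_inverse=True)
    G = uniq.size
    by_cluster = [np.flatnonzero(codes == g) for g in range(G)]
    draws = np.empty((B, X.shape[1]))
    n_failed = 0
    for b in range(B):
        picks = rng.integers(0, G, size=G)
        idx = np.concatenate([by_cluster[g] for g in picks])
        grp = np.repeat(np.arange(G), [by_cluster[g].size for g in picks])
        try:
            fit = fit_lmm(y[idx], X[idx], grp, reml=True,
                          term_names=list(design.X.columns))
            draws[b] = fit.params.to_numpy()
        except Exception:
            draws[b] = np.nan
            n_failed += 1
    ok = draws[~np.isnan(draws).any(axis=1)]
    lo, hi = np.percentile(ok, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    out = pd.DataFrame({"term": design.X.columns, "ci_low": lo, "ci_high": hi})
    out.attrs.update({"B": B, "n_failed": n_failed, "seed": seed,
                      "flagged": n_failed > 0.10 * B})
    return out


def interaction_test(events: pd.DataFrame, modifier: str,
                     exposures: list[str] | None = None,
                     engine: str = "fast") -> pd.DataFrame:
    """Wald p-values for exposure-by-modifier product terms.

    The base model is the full model with between-person exposures
    excluded; product terms are added for every within-person exposure and
    the meal-time indicators.  ``modifier`` must be a binary column
    (``sex_male`` / ``prediabetes`` after encoding).  Flags mark p < 0.05
    and the marginal band [0.05, 0.10).
    """
    events = encode_covariates(events)
    mod_col = {"sex": "sex_male", "prediabetes": "prediabetes"}.get(modifier, modifier)
    m = events[mod_col].astype(float)
    if m.nunique() < 2:
        raise ValueError(f"modifier {mod_col!r} is constant")
    exposures = exposures or list(EXPOSURES)
    spec = ModelSpec(mode="full", exposures=exposures, include_between=False)
    covs = list(COVARIATE_TERMS)
    if mod_col not in covs:
        covs.append(mod_col)
    spec = replace(spec, covariates=covs)
    inter = {}
    for e in exposures:
        inter[f"{e}_within:{mod_col}"] = events[f"{e}_within"] * m
    for name, col in _meal_time_dummies(events).items():
        inter[f"{name}:{mod_col}"] = col * m
    design = build_design(events, spec, extra_terms=pd.DataFrame(inter, index=events.index))
    fit = fit_random_intercept(design, engine=engine)
    res = fit[fit["term"].str.contains(":")].copy()
    res["significant"] = res["p_value"] < 0.05
    res["marginal"] = (res["p_value"] >= 0.05) & (res["p_value"] < 0.10)
    res.attrs.update(fit.attrs)
    return res[["term", "beta", "se", "p_value", "significant", "marginal"]]


_STRATA = {
    "sex": [("male", lambda d: d["sex"] == "male", "sex_male"),
            ("female", lambda d: d["sex"] == "female", "sex_male")],
    "prediabetes": [("prediabetes", lambda d: d["prediabetes"].astype(bool), "prediabetes"),
                    ("no_prediabetes", lambda d: ~d["prediabetes"].astype(bool),
                     "prediabetes")],
}


def stratified_fit(events: pd.DataFrame, strata_var: str,
                   engine: str = "fast") -> dict[str, pd.DataFrame]:
    """Full-model fits inside strata of sex or prediabetes status.

    Between-person exposures are excluded and the stratifying variable is
    removed from the covariates.  Strata with fewer than two participants
    are skipped.
    """
    if strata_var not in _STRATA:
        raise ValueError(f"unknown stratifier {strata_var!r}")
    out: dict[str, pd.DataFrame] = {}
    for name, rule, drop_cov in _STRATA[strata_var]:
        sub = events[rule(events)]
        if sub["participant_id"].nunique() < 2:
            continue
        covs = [c for c in COVARIATE_TERMS if c != drop_cov]
        spec = ModelSpec(mode="full", include_between=False, covariates=covs)
        design = build_design(sub, spec)
        out[name] = fit_random_intercept(design, engine=engine)
    return out


def association_table(events: pd.DataFrame, B: int = 0, seed: int = 0,
                      run_basic: bool = True, engine: str = "fast") -> pd.DataFrame:
    """Results table: one row per exposure term, basic and full estimates.

    When ``B > 0``, bootstrap percentile CIs replace the Wald intervals of
    the full model (basic-model CIs stay Wald to keep B x 21 refits out of
    the default path).
    """
    full_spec = ModelSpec(mode="full")
    full_design = build_design(events, full_spec)
    full = fit_random_intercept(full_design, engine=engine).set_index("term")
    z = 1.959963984540054
    full["ci_low"] = full["beta"] - z * full["se"]
    full["ci_high"] = full["beta"] + z * full["se"]
    if B > 0:
        ci = bootstrap_ci(full_design, B=B, seed=seed).set_index("term")
        full.loc[ci.index, ["ci_low", "ci_high"]] = ci[["ci_low", "ci_high"]]
    rows = []
    for e in EXPOSURES:
        row: dict[str, object] = {"term": f"{e}_within"}
        if run_basic:
            basic = fit_random_intercept(
                build_design(events, ModelSpec(mode="basic", exposures=[e])),
                engine=engine).set_index("term")
            b = basic.loc[f"{e}_within"]
            row.update(basic_beta=b["beta"],
                       basic_ci_low=b["beta"] - z * b["se"],
                       basic_ci_high=b["beta"] + z * b["se"],
                       basic_p=b["p_value"])
        f = full.loc[f"{e}_within"]
        row.update(full_beta=f["beta"], full_ci_low=f["ci_low"],
                   full_ci_high=f["ci_high"], full_p=f["p_value"])
        rows.append(row)
    basic_mt = None
    if run_basic:
        basic_mt = fit_random_intercept(
            build_design(events, ModelSpec(mode="full", exposures=[])),
            engine=engine).set_index("term")
    for t in MEAL_TIME_TERMS:
        f = full.loc[t]
        row = {"term": t, "full_beta": f["beta"], "full_ci_low": f["ci_low"],
               "full_ci_high": f["ci_high"], "full_p": f["p_value"]}
        if basic_mt is not None:
            b = basic_mt.loc[t]
            row.update(basic_beta=b["beta"],
                       basic_ci_low=b["beta"] - z * b["se"],
                       basic_ci_high=b["beta"] + z * b["se"],
                       basic_p=b["p_value"])
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["full_model"] = dict(full.attrs)
    return out
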