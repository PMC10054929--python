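"""Regression backbone for the like-to-like wiring-rule models.

All three connectivity outcomes share one linear predictor:

    log E[y_ij] = b0 + b1 * Sim_ij + b2 * Proj_k(ij) + b3 * Sim_ij x Proj_k(ij)
                  + u_{k(ij), i}  (+ offset)

with y the co-travel distance (Tweedie), the synapse count (Poisson), or the
synapse count with a log co-travel offset (Poisson, synapse-density scale).
The group term u is a random intercept per (presynaptic neuron x projection
type).  Two estimation backends are provided:

``re_mode="fixed"`` (default)
    exact fixed-effects treatment: one dummy intercept per group.  Slope
    inference is then exact conditional on groups; the projection main
    effect is absorbed by the group intercepts and not separately reported.
``re_mode="ridge"``
    penalized IRLS in the PQL family: group intercepts are shrunk by a
    ridge penalty ``phi / sigma_u^2`` with ``sigma_u^2`` updated by an
    empirical-Bayes fixed point.  Reports the group variance and keeps the
    projection main effect identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .tweedie import TweedieParams, tweedie_loglik

__all__ = ["ModelFit", "fit_glm", "conditional_slopes", "profile_xi"]

#: canonical ordering of the 4 projection levels; the first present is the
#: reference level of the interaction contrasts
PROJECTION_ORDER = ["V1->V1", "HVA->HVA", "V1->HVA", "HVA->V1"]

#: similarity-metric name -> pair-table column
METRIC_COLUMNS = {
    "signal_corr": "sim_signal_corr",
    "feature": "sim_feature",
    "rf_distance": "rf_distance_deg",
}


@dataclass
class ModelFit:
    """Fitted like-to-like regression."""

    family: str
    metrics: list[str]
    params: pd.Series
    cov: pd.DataFrame
    phi: float
    xi: float | None
    projection_levels: list[str]
    reference_level: str
    group_var: float
    n_obs: int
    loglik: float | None
    r2_marginal: float
    r2_conditional: float
    converged: bool
    group_intercepts: pd.Series | None = None
    fitted_mu: np.ndarray | None = None
    design_columns: list[str] = field(default_factory=list)

    def slope_name(self, metric: str, level: str) -> list[str]:
        cols = [metric]
        if level != self.reference_level:
            cols.append(f"{metric}:{level}")
        return cols


def _ordered_levels(series: pd.Series) -> list[str]:
    present = list(pd.unique(series))
    ordered = [p for p in PROJECTION_ORDER if p in present]
    ordered += [p for p in present if p not in ordered]
    return ordered


def build_design(
    pairs: pd.DataFrame,
    metrics: list[str],
    re_mode: str = "fixed",
    group_cols: tuple[str, ...] = ("pre_id", "projection"),
):
    """Design matrices for the shared linear predictor.

    Returns (X_fixed DataFrame, Z group-dummy DataFrame or None, levels,
    reference level, group labels).  In fixed mode the group dummies (all
    but the first group) are appended to X and the projection main effects
    are omitted (absorbed).
    """
    levels = _ordered_levels(pairs["projection"])
    ref = levels[0]
    n = len(pairs)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    for m in metrics:
        cols[m] = pairs[METRIC_COLUMNS[m]].to_numpy(dtype=float)
    proj = pairs["projection"].to_numpy()
    if re_mode != "fixed":
        for lev in levels[1:]:
            cols[f"proj:{lev}"] = (proj == lev).astype(float)
    for m in metrics:
        for lev in levels[1:]:
            cols[f"{m}:{lev}"] = cols[m] * (proj == lev)

    group = pairs[list(group_cols)].astype(str).agg("|".join, axis=1)
    glabels = pd.unique(group)
    if re_mode == "fixed":
        for g in glabels[1:]:
            cols[f"grp:{g}"] = (group == g).to_numpy(dtype=float)
        Z = None
    else:
        Z = pd.DataFrame(
            {f"u:{g}": (group == g).to_numpy(dtype=float) for g in glabels}, index=pairs.index
        )
    X = pd.DataFrame(cols, index=pairs.index)
    return X, Z, levels, ref, group


def _family(family: str, xi: float | None):
    if family == "tweedie":
        return sm.families.Tweedie(var_power=xi, link=sm.families.links.Log())
    if family in ("poisson", "poisson_offset"):
        return sm.families.Poisson()
    raise ValueError(f"unknown family {family!r}")


def _nakagawa_r2(eta_fixed, group_var, phi, xi, family, mu_bar):
    """Nakagawa-style pseudo-R2 on the log-link latent scale.

    The residual variance on the link scale uses the lognormal
    approximation ln(1 + Var(y|mu)/mu^2) at the mean fitted value.
    """
    var_f = float(np.var(eta_fixed))
    if family == "tweedie":
        var_resid = float(np.log1p(phi * mu_bar**xi / mu_bar**2))
    else:
        var_resid = float(np.log1p(1.0 / mu_bar + max(phi - 1.0, 0.0) / mu_bar))
    tot = var_f + group_var + var_resid
    if tot <= 0:
        return 0.0, 0.0
    return var_f / tot, (var_f + group_var) / tot


def fit_glm(
    pairs: pd.DataFrame,
    metrics: list[str] | str,
    y_col: str,
    family: str,
    offset: np.ndarray | None = None,
    xi: float = 1.5,
    re_mode: str = "fixed",
    group_cols: tuple[str, ...] = ("pre_id", "projection"),
    compute_loglik: bool = False,
) -> ModelFit:
    """Fit one like-to-like GLM (Tweedie or Poisson, log link)."""
    if isinstance(metrics, str):
        metrics = [metrics]
    X, Z, levels, ref, group = build_design(pairs, metrics, re_mode, group_cols)
    y = pairs[y_col].to_numpy(dtype=float)

    if re_mode == "fixed":
        fit = _fit_fixed(y, X, family, xi, offset)
        params, cov, phi, mu, group_var, ginter = fit
    elif re_mode == "ridge":
        params, cov, phi, mu, group_var, ginter = _fit_ridge(y, X, Z, family, xi, offset, group)
    else:
        raise ValueError(f"unknown re_mode {re_mode!r}")

    eta_fixed = X[[c for c in X.columns if not c.startswith("grp:")]].to_numpy() @ params[
        [c for c in params.index if not c.startswith("grp:")]
    ].to_numpy()
    mu_bar = float(np.mean(mu))
    r2m, r2c = _nakagawa_r2(eta_fixed, group_var, phi, xi, family, mu_bar)

    ll = None
    if compute_loglik:
        if family == "tweedie":
            ll = tweedie_loglik(y, mu, TweedieParams(xi, phi))
        else:
            ll = float(np.sum(stats.poisson.logpmf(y.astype(int), mu)))

    keep = [c for c in params.index if not c.startswith("grp:")]
    return ModelFit(
        family=family,
        metrics=metrics,
        params=params[keep],
        cov=cov.loc[keep, keep],
        phi=phi,
        xi=xi if family == "tweedie" else None,
        projection_levels=levels,
        reference_level=ref,
        group_var=group_var,
        n_obs=len(y),
        loglik=ll,
        r2_marginal=r2m,
        r2_conditional=r2c,
        converged=True,
        group_intercepts=ginter,
        fitted_mu=mu,
        design_columns=list(X.columns),
    )


def _fit_fixed(y, X, family, xi, offset):
    fam = _family(family, xi)
    model = sm.GLM(y, X, family=fam, offset=offset)
    res = model.fit(maxiter=200, tol=1e-9)
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    phi = float(res.scale) if family == "tweedie" else 1.0
    ginter = params[[c for c in X.columns if c.startswith("grp:")]]
    group_var = float(np.var(np.concatenate([[0.0], ginter.to_numpy()]))) if len(ginter) else 0.0
    return params, cov, phi, np.asarray(res.mu), group_var, ginter


def _fit_ridge(y, X, Z, family, xi, offset, group, n_outer: int = 12):
    """Penalized IRLS with an empirical-Bayes update of the group variance."""
    Xa = X.to_numpy()
    Za = Z.to_numpy()
    A = np.hstack([Xa, Za])
    p, q = Xa.shape[1], Za.shape[1]
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, dtype=float)
    beta = np.zeros(p + q)
    beta[0] = np.log(np.mean(y) + 1e-8) - np.mean(off)
    sigma2 = 0.25
    phi = 1.0
    power = xi if family == "tweedie" else 1.0
    for _ in range(n_outer):
        for _ in range(25):
            eta = A @ beta + off
            mu = np.exp(np.clip(eta, -30, 30))
            w = mu ** (2.0 - power) / phi  # mu'(eta)^2 / (phi V(mu)) under log link
            z = (eta - off) + (y - mu) / mu
            P = np.concatenate([np.zeros(p), np.full(q, phi / max(sigma2, 1e-6))])
            AtW = A.T * w
            H = AtW @ A + np.diag(P)
            beta_new = np.linalg.solve(H, AtW @ z)
            if np.max(np.abs(beta_new - beta)) < 1e-8:
                beta = beta_new
                break
            beta = beta_new
        eta = A @ beta + off
        mu = np.exp(np.clip(eta, -30, 30))
        if family == "tweedie":
            phi = float(np.sum((y - mu) ** 2 / mu**power) / max(len(y) - p, 1))
        u = beta[p:]
        Hinv = np.linalg.inv(H)
        var_u = np.diag(Hinv)[p:] * phi
        sigma2_new = float(np.mean(u**2 + var_u))
        if abs(sigma2_new - sigma2) < 1e-8:
            sigma2 = sigma2_new
            break
        sigma2 = sigma2_new
    cov_full = np.linalg.inv(H) * phi
    params = pd.Series(beta[:p], index=X.columns)
    cov = pd.DataFrame(cov_full[:p, :p], index=X.columns, columns=X.columns)
    ginter = pd.Series(beta[p:], index=Z.columns)
    return params, cov, phi, mu, sigma2, ginter


@dataclass
class LikeToLikeCoef:
    metric: str
    projection: str
    slope: float
    se: float
    p: float
    p_adj: float | None = None


def conditional_slopes(fit: ModelFit, metric: str | None = None, adjust: bool = True) -> pd.DataFrame:
    """Per-projection like-to-like slope b1 + b3[level] with delta-method SEs.

    The reference level's slope is exactly b1.  Wald p-values come from the
    normal approximation; BH adjustment is applied across the reported
    family (all levels, and all metrics when the fit is joint).
    """
    if fit.cov is None or fit.cov.isna().any().any():
        raise ValueError("fit lacks a covariance matrix for slope inference")
    metrics = [metric] if metric else fit.metrics
    rows = []
    names = list(fit.params.index)
    for m in metrics:
        for lev in fit.projection_levels:
            contrast = np.zeros(len(names))
            for col in fit.slope_name(m, lev):
                if col not in names:
                    raise KeyError(f"coefficient {col!r} missing from fit")
                contrast[names.index(col)] = 1.0
            slope = float(contrast @ fit.params.to_numpy())
            se = float(np.sqrt(contrast @ fit.cov.to_numpy() @ contrast))
            pval = 2.0 * stats.norm.sf(abs(slope) / se) if se > 0 else np.nan
            rows.append(
                {"metric": m, "projection": lev, "slope": slope, "se": se, "p": pval}
            )
    out = pd.DataFrame(rows)
    if adjust:
        from .models import bh_adjust

        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def profile_xi(
    pairs: pd.DataFrame,
    metrics: list[str] | str,
    y_col: str = "ld_um",
    grid: np.ndarray | None = None,
    re_mode: str = "fixed",
) -> tuple[float, pd.DataFrame]:
    """Profile the Tweedie index over a grid in (1, 2).

    For each candidate xi the GLM is refit and the exact series
    log-likelihood is maximized over the dispersion phi; returns the best xi
    and the profile table.
    """
    if grid is None:
        grid = np.round(np.arange(1.1, 1.95, 0.05), 3)
    y = pairs[y_col].to_numpy(dtype=float)
    rows = []
    for xi in grid:
        fit = fit_glm(pairs, metrics, y_col, "tweedie", xi=float(xi), re_mode=re_mode)
        mu = fit.fitted_mu

        def nll(log_phi):
            return -tweedie_loglik(y, mu, TweedieParams(float(xi), float(np.exp(log_phi))))

        sol = optimize.minimize_scalar(nll, bounds=(-6, 6), method="bounded")
        rows.append({"xi": float(xi), "phi": float(np.exp(sol.x)), "loglik": -float(sol.fun)})
    prof = pd.DataFrame(rows)
    best = prof.loc[prof["loglik"].idxmax()]
    return float(best["xi"]), prof
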