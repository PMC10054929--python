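"""Like-to-like connectivity models at axonal and synaptic scales.

Three regression views of the same pair table distinguish where functional
similarity acts:

* ``fit_ld_model`` — Tweedie regression of the co-travel distance Ld
  (axonal scale: do similar neurons' arbors travel together more?);
* ``fit_nsyn_model`` — Poisson regression of the synapse count
  (both scales mixed);
* ``fit_density_model`` — Poisson regression of the synapse count with a
  log co-travel offset, i.e. the synapse density Nsyn/Ld (synaptic scale:
  given the opportunity, do similar neurons form more synapses?).

Supporting procedures: the projection-level data filter, presyn-paired
cohort t-tests, the two-step residual regression linking similarity to
synapse anatomy, presyn-centered binning with a pair bootstrap, and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glm import METRIC_COLUMNS, ModelFit, conditional_slopes, fit_glm, profile_xi

__all__ = [
    "fit_ld_model",
    "fit_nsyn_model",
    "fit_density_model",
    "filter_projections",
    "conditional_slopes",
    "paired_cohort_test",
    "residual_anatomy_regression",
    "center_and_bin",
    "bh_adjust",
]

UM_PER_MM = 1000.0


def fit_ld_model(
    pairs: pd.DataFrame,
    metric: str | list[str],
    xi: float | None = 1.5,
    re_mode: str = "fixed",
    **kwargs,
) -> ModelFit:
    """Axonal-scale model: Tweedie log-link regression of Ld (um) on similarity.

    Zero-Ld pairs stay in the data (the Tweedie family carries the atom at
    zero).  ``xi=None`` triggers profile estimation of the index over a grid
    in (1, 2); otherwise the index is held fixed (default 1.5).
    """
    if xi is None:
        xi, _ = profile_xi(pairs, metric, "ld_um", re_mode=re_mode)
    return fit_glm(pairs, metric, "ld_um", "tweedie", xi=xi, re_mode=re_mode, **kwargs)


def fit_nsyn_model(pairs: pd.DataFrame, metric: str | list[str], re_mode: str = "fixed", **kwargs) -> ModelFit:
    """Scale-agnostic model: Poisson log-link regression of the synapse count."""
    return fit_glm(pairs, metric, "nsyn", "poisson", re_mode=re_mode, **kwargs)


def fit_density_model(pairs: pd.DataFrame, metric: str | list[str], re_mode: str = "fixed", **kwargs) -> ModelFit:
    """Synaptic-scale model: Poisson regression of Nsyn with log Ld (mm) offset.

    Slopes read as effects on the synapse density per millimeter of
    co-travel.  Records with Ld <= 0 are rejected: density is undefined
    without co-travel.
    """
    ld = pairs["ld_um"].to_numpy(dtype=float)
    if np.any(ld <= 0):
        raise ValueError("density model requires Ld > 0 for every record; filter first")
    offset = np.log(ld / UM_PER_MM)
    return fit_glm(pairs, metric, "nsyn", "poisson_offset", offset=offset, re_mode=re_mode, **kwargs)


def filter_projections(
    pairs: pd.DataFrame,
    min_synapses: int = 30,
    min_presyns: int = 5,
    max_presyn_share: float = 0.5,
) -> list[str]:
    """Projection levels with enough, well-spread synaptic data.

    Keeps levels with strictly more than ``min_synapses`` synapses, strictly
    more than ``min_presyns`` presynaptic neurons contributing synapses, and
    no single presyn contributing more than ``max_presyn_share`` of them.
    """
    keep = []
    for lev, sub in pairs.groupby("projection", sort=False):
        total = int(sub["nsyn"].sum())
        by_pre = sub.groupby("pre_id")["nsyn"].sum()
        contributing = int((by_pre > 0).sum())
        if total <= min_synapses or contributing <= min_presyns:
            continue
        if (by_pre.max() / total) > max_presyn_share:
            continue
        keep.append(lev)
    return keep


def paired_cohort_test(
    pairs: pd.DataFrame,
    cohorts: pd.DataFrame,
    sim_col: str = "sim_signal_corr",
    min_targets: int = 10,
    by_projection: bool = True,
) -> pd.DataFrame:
    """Presyn-paired t-tests of mean similarity across control cohorts.

    For each presyn (within each projection when ``by_projection``) the mean
    similarity to its connected partners, ADP controls, and same-region
    controls is computed; presyns with more than ``min_targets`` connected
    targets qualify.  Paired t-tests compare the three cohort means across
    qualifying presyns; p-values are BH-adjusted across the reported family.
    """
    merged = pairs.merge(cohorts, on=["pre_id", "post_id"])
    group_cols = ["projection"] if by_projection else []
    comparisons = [
        ("connected", "adp_control"),
        ("connected", "same_region_control"),
        ("adp_control", "same_region_control"),
    ]
    rows = []
    for key, sub in merged.groupby(group_cols) if group_cols else [((), merged)]:
        level = key[0] if group_cols else "pooled"
        means = (
            sub.groupby(["pre_id", "cohort"])[sim_col].mean().unstack("cohort")
        )
        n_targets = (
            sub[sub["cohort"] == "connected"].groupby("pre_id").size().reindex(means.index).fillna(0)
        )
        qual = means[n_targets > min_targets]
        for a, b in comparisons:
            if a not in qual.columns or b not in qual.columns:
                continue
            paired = qual[[a, b]].dropna()
            if len(paired) < 2:
                rows.append(
                    {"projection": level, "cohort_a": a, "cohort_b": b, "n_presyn": len(paired),
                     "mean_diff": np.nan, "t": np.nan, "p": np.nan, "skipped": True}
                )
                continue
            diff = paired[a] - paired[b]
            if np.allclose(diff, diff.iloc[0]) and np.isclose(diff.iloc[0], 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(paired[a], paired[b])
            rows.append(
                {"projection": level, "cohort_a": a, "cohort_b": b, "n_presyn": len(paired),
                 "mean_diff": float(diff.mean()), "t": float(t), "p": float(p), "skipped": False}
            )
    out = pd.DataFrame(rows)
    if len(out):
        valid = ~out["p"].isna()
        out["p_adj"] = np.nan
        if valid.any():
            out.loc[valid, "p_adj"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    return out


def residual_anatomy_regression(
    pairs: pd.DataFrame,
    sim_col: str = "sim_signal_corr",
    cleft_col: str = "mean_log10_cleft_volume",
) -> pd.DataFrame:
    """Two-step regression: does synapse anatomy predict similarity beyond Ld?

    Step 1 regresses similarity on Ld (OLS) over connected pairs and keeps
    the residuals — the similarity variation that co-travel opportunity
    cannot explain.  Step 2 regresses those residuals on the synapse count
    and the mean log10 cleft volume; the reported slopes test whether
    multisynaptic connections and larger synapses carry extra similarity.
    """
    import statsmodels.api as sm

    sub = pairs[pairs["nsyn"] >= 1].dropna(subset=[sim_col, cleft_col])
    if len(sub) < 4:
        raise ValueError("too few connected records for the two-step regression")
    x1 = sm.add_constant(sub["ld_um"].to_numpy(dtype=float))
    step1 = sm.OLS(sub[sim_col].to_numpy(dtype=float), x1).fit()
    resid = step1.resid
    X2 = sm.add_constant(
        np.column_stack([sub["nsyn"].to_numpy(dtype=float), sub[cleft_col].to_numpy(dtype=float)])
    )
    step2 = sm.OLS(resid, X2).fit()
    names = ["intercept", "nsyn", cleft_col]
    return pd.DataFrame(
        {
            "term": names,
            "coef": step2.params,
            "se": step2.bse,
            "t": step2.tvalues,
            "p": step2.pvalues,
        }
    ).reset_index(drop=True)


def _center(sub: pd.DataFrame, y_col: str, x_col: str) -> pd.DataFrame:
    g = sub.groupby("pre_id")
    out = sub.copy()
    out["dy"] = sub[y_col] - g[y_col].transform("mean")
    out["dx"] = sub[x_col] - g[x_col].transform("mean")
    return out


def center_and_bin(
    pairs: pd.DataFrame,
    y: str = "ld",
    x_col: str = "sim_signal_corr",
    bins: np.ndarray | int = 8,
    n_boot: int = 1000,
    min_pairs: int = 10,
    min_presyns: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Presyn-centered bin summary of Ld or synapse density vs similarity.

    ``y="ld"`` restricts to pairs without synapses and summarizes
    Delta-Ld; ``y="density"`` restricts to Ld > 0 and summarizes
    Delta-(Nsyn per mm of Ld).  Per presyn the mean response and mean
    similarity over its eligible pairs are subtracted; pairs are binned by
    Delta-similarity; per-bin mean Delta-response and a bootstrap SD over
    pair resampling (``n_boot`` resamples) are reported.  Only bins with
    more than ``min_pairs`` pairs and ``min_presyns`` distinct presyns
    survive.
    """
    rng = rng or np.random.default_rng()
    if y == "ld":
        sub = pairs[pairs["nsyn"] == 0].copy()
        sub["yval"] = sub["ld_um"]
    elif y == "density":
        sub = pairs[pairs["ld_um"] > 0].copy()
        sub["yval"] = sub["nsyn"] / (sub["ld_um"] / UM_PER_MM)
    else:
        raise ValueError("y must be 'ld' or 'density'")
    if not len(sub):
        return pd.DataFrame(columns=["bin_left", "bin_right", "mean_dy", "sd_boot", "n_pairs", "n_presyn"])
    centered = _center(sub, "yval", x_col)
    if np.isscalar(bins):
        edges = np.linspace(centered["dx"].min(), centered["dx"].max() + 1e-12, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    idx = np.digitize(centered["dx"], edges) - 1
    idx = np.clip(idx, 0, len(edges) - 2)

    rows = []
    for b in range(len(edges) - 1):
        in_bin = idx == b
        n_pairs = int(in_bin.sum())
        n_pre = centered.loc[in_bin, "pre_id"].nunique()
        if n_pairs <= min_pairs or n_pre <= min_presyns:
            continue
        rows.append(
            {"bin": b, "bin_left": edges[b], "bin_right": edges[b + 1],
             "mean_dy": float(centered.loc[in_bin, "dy"].mean()),
             "n_pairs": n_pairs, "n_presyn": int(n_pre)}
        )
    if not rows:
        return pd.DataFrame(columns=["bin_left", "bin_right", "mean_dy", "sd_boot", "n_pairs", "n_presyn"])
    out = pd.DataFrame(rows).set_index("bin")

    # bootstrap: resample pairs with replacement, redo centering + binning
    boot = {b: [] for b in out.index}
    n = len(sub)
    for _ in range(n_boot):
        take = rng.integers(0, n, size=n)
        res = sub.iloc[take]
        cen = _center(res, "yval", x_col)
        bi = np.clip(np.digitize(cen["dx"], edges) - 1, 0, len(edges) - 2)
        means = pd.Series(cen["dy"].to_numpy()).groupby(bi).mean()
        for b in out.index:
            if b in means.index:
                boot[b].append(means.loc[b])
    out["sd_boot"] = [float(np.std(boot[b])) if boot[b] else np.nan for b in out.index]
    return out.reset_index(drop=True)[["bin_left", "bin_right", "mean_dy", "sd_boot", "n_pairs", "n_presyn"]]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
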