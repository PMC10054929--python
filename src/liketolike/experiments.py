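"""Replicate-level validation studies on synthetic populations.

Each study regenerates data from scratch under a seed and measures a
property of the full pipeline: exact agreement of the spatial-index
geometry with brute force, Tweedie sampler moment identities, coverage and
null calibration of the planted wiring-rule slopes, the axonal-vs-synaptic
dissociation, calibration and power of the common-input rho contrast, and
the qualitative RNN like-to-like results.  These are the quantities the
acceptance script reports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import common_input, geometry, models, rnn, synthetic
from .glm import conditional_slopes
from .tweedie import TweedieParams, sample_tweedie, zero_probability

__all__ = [
    "geometry_oracle_study",
    "tweedie_moment_study",
    "recovery_study",
    "dissociation_study",
    "rho_study",
    "rnn_study",
]


# ---------------------------------------------------------------------------
# geometry

def brute_force_proximities(axon: geometry.Skeleton, dend: geometry.Skeleton, radius: float):
    """O(n*m) all-pairs oracle for the proximal vertex set."""
    if axon.n_vertices == 0 or dend.n_vertices == 0:
        return np.zeros((0, 2), dtype=int)
    d = np.linalg.norm(axon.vertices[:, None, :] - dend.vertices[None, :, :], axis=2)
    ia, jd = np.nonzero(d <= radius)
    return np.column_stack([ia, jd])


def random_scene(rng: np.random.Generator, max_vertices: int = 500):
    """Random-walk axon/dendrite skeleton pair in a shared 60 um box."""

    def walk(n, compartment, name):
        steps = rng.normal(scale=0.7, size=(n - 1, 3))
        verts = np.cumsum(np.vstack([rng.uniform(0, 60, 3), steps]), axis=0)
        edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
        return geometry.discretize(geometry.Skeleton(verts, edges, compartment, name))

    na = int(rng.integers(50, max_vertices))
    nd = int(rng.integers(50, max_vertices))
    return walk(na, "axon", "pre"), walk(nd, "dendrite", "post")


def geometry_oracle_study(n_scenes: int = 50, seed: int = 0, radius: float = 5.0,
                          syn_radius: float = 3.0) -> dict:
    """Spatial-index vs brute-force equality on random scenes.

    Checks, per scene: identical proximal vertex sets, identical Ld, and
    identical synapse assignment for synapses scattered near the dendrite.
    Returns the fraction of scenes in exact agreement (expected 1.0).
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for k in range(n_scenes):
        axon, dend = random_scene(rng)
        fast = geometry.find_proximities(axon, dend, radius=radius)
        slow = brute_force_proximities(axon, dend, radius=radius)
        same_pairs = fast.shape == slow.shape and bool(
            np.array_equal(np.asarray(sorted(map(tuple, fast))), np.asarray(sorted(map(tuple, slow))))
        )
        ld_fast = geometry.compute_ld(axon, dend, radius=radius)
        ld_slow = geometry._ld_from_pairs(dend, slow)
        same_ld = ld_fast == ld_slow

        prox = geometry.make_proximity("pre", "post", axon, dend, radius=radius)
        n_syn = 15
        pts = dend.vertices[rng.integers(0, dend.n_vertices, n_syn)] + rng.normal(
            scale=3.0, size=(n_syn, 3)
        )
        syn = pd.DataFrame(
            {"synapse_id": np.arange(n_syn), "pre_id": "pre", "post_id": "post",
             "x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": pts[:, 2]}
        )
        prox = geometry.assign_synapses(syn, prox, axon, dend, radius=syn_radius)
        if prox.proximal_pairs.size:
            cloud = np.vstack(
                [axon.vertices[prox.axon_vertices], dend.vertices[prox.dendrite_vertices]]
            )
            dmin = np.linalg.norm(pts[:, None, :] - cloud[None, :, :], axis=2).min(axis=1)
            oracle_assigned = set(np.flatnonzero(dmin <= syn_radius))
        else:
            oracle_assigned = set()
        same_syn = oracle_assigned == set(prox.assigned_synapse_ids)
        agree += int(same_pairs and same_ld and same_syn)
    return {"agreement_rate": agree / n_scenes, "n": n_scenes}


# ---------------------------------------------------------------------------
# tweedie sampler

def tweedie_moment_study(n_draws: int = 100_000, seed: int = 0) -> dict:
    """Moment identities over a 3x3x3 grid of (mu, phi, xi).

    Reports the largest |z| of the sample mean vs mu and sample variance vs
    phi*mu^xi (z in Monte-Carlo standard errors), plus the largest absolute
    error of the empirical zero fraction vs exp(-lam).
    """
    rng = np.random.default_rng(seed)
    max_z_mean = max_z_var = max_z_p0 = 0.0
    for mu in (0.5, 2.0, 8.0):
        for phi in (0.5, 1.0, 4.0):
            for xi in (1.2, 1.5, 1.8):
                params = TweedieParams(xi=xi, phi=phi)
                x = sample_tweedie(np.full(n_draws, mu), params, rng)
                var = phi * mu**xi
                z_mean = abs(x.mean() - mu) / np.sqrt(var / n_draws)
                # SE of the sample variance from the empirical 4th moment
                m4 = np.mean((x - x.mean()) ** 4)
                se_var = np.sqrt(max(m4 - x.var() ** 2, 1e-12) / n_draws)
                z_var = abs(x.var(ddof=1) - var) / se_var
                p0 = zero_probability(mu, params)
                se_p0 = np.sqrt(max(p0 * (1 - p0), 1e-12) / n_draws)
                z_p0 = abs(np.mean(x == 0) - p0) / se_p0
                max_z_mean = max(max_z_mean, z_mean)
                max_z_var = max(max_z_var, z_var)
                max_z_p0 = max(max_z_p0, z_p0)
    return {
        "max_z_mean": float(max_z_mean),
        "max_z_var": float(max_z_var),
        "max_z_p0": float(max_z_p0),
        "n": n_draws,
    }


# ---------------------------------------------------------------------------
# wiring-rule recovery

def _replicate_config(seed: int, **overrides) -> synthetic.SyntheticConfig:
    base = dict(
        n_presyn=40,
        n_neurons=2000,
        n_candidates_per_presyn=100,
        feature_dim=64,
        seed=seed,
    )
    base.update(overrides)
    return synthetic.SyntheticConfig(**base)


def _one_recovery_rep(seed: int, beta_ax: float, beta_syn: float, metric: str = "signal_corr"):
    cfg = _replicate_config(
        seed,
        beta_axonal={metric: beta_ax},
        beta_synaptic={metric: beta_syn},
    )
    neurons, profiles = synthetic.generate_population(cfg)
    pairs, truth = synthetic.generate_anatomy(neurons, profiles, cfg)

    ld_fit = models.fit_ld_model(pairs, metric)
    ld_ref = conditional_slopes(ld_fit, adjust=False).iloc[0]
    pos = pairs[pairs["ld_um"] > 0]
    dens_fit = models.fit_density_model(pos, metric)
    dens_ref = conditional_slopes(dens_fit, adjust=False).iloc[0]

    def summarize(row, truth_beta):
        lo, hi = row["slope"] - 1.96 * row["se"], row["slope"] + 1.96 * row["se"]
        return {
            "slope": row["slope"],
            "se": row["se"],
            "covered": bool(lo <= truth_beta <= hi),
            "significant": bool(row["p"] < 0.05),
        }

    return summarize(ld_ref, beta_ax), summarize(dens_ref, beta_syn)


def recovery_study(n_reps: int = 100, seed: int = 0, beta_ax: float = 0.8,
                   beta_syn: float = 0.6) -> dict:
    """Coverage of planted slopes and rejection rate under the null.

    Each replicate generates a fresh population at default size, fits the
    Tweedie co-travel model and the Poisson synapse-density model, and
    checks whether the 95% CI of the reference-level conditional slope
    covers the planted value.  With ``beta_ax = beta_syn = 0`` the
    ``significant`` fractions are the empirical type-I error rates.
    """
    cov_ax = cov_syn = rej_ax = rej_syn = 0
    for r in range(n_reps):
        ax, sy = _one_recovery_rep(seed * 100_003 + r, beta_ax, beta_syn)
        cov_ax += ax["covered"]
        cov_syn += sy["covered"]
        rej_ax += ax["significant"]
        rej_syn += sy["significant"]
    return {
        "coverage_axonal": cov_ax / n_reps,
        "coverage_synaptic": cov_syn / n_reps,
        "rejection_axonal": rej_ax / n_reps,
        "rejection_synaptic": rej_syn / n_reps,
        "n": n_reps,
    }


def dissociation_study(n_reps: int = 50, seed: int = 0, beta_rf: float = -0.05) -> dict:
    """Axonal-vs-synaptic dissociation for the RF-distance metric.

    The generator plants an RF-distance effect only at the axonal scale
    (arbor placement follows retinotopy; synapse conversion does not).  The
    co-travel model should report a significant negative RF slope while the
    density model's RF slope stays null.
    """
    sig_ld = null_dens = 0
    for r in range(n_reps):
        cfg = _replicate_config(
            seed * 100_003 + r,
            beta_axonal={"rf_distance": beta_rf},
            beta_synaptic={},
        )
        neurons, profiles = synthetic.generate_population(cfg)
        pairs, _ = synthetic.generate_anatomy(neurons, profiles, cfg)
        ld_row = conditional_slopes(models.fit_ld_model(pairs, "rf_distance"), adjust=False).iloc[0]
        dens_row = conditional_slopes(
            models.fit_density_model(pairs[pairs["ld_um"] > 0], "rf_distance"), adjust=False
        ).iloc[0]
        sig_ld += int(ld_row["p"] < 0.05 and ld_row["slope"] < 0)
        null_dens += int(dens_row["p"] >= 0.05)
    return {
        "ld_significant_rate": sig_ld / n_reps,
        "density_null_rate": null_dens / n_reps,
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# common input

def _one_rho_rep(seed: int, strength: float):
    cfg = _replicate_config(seed, higher_order_strength=strength)
    neurons, profiles = synthetic.generate_population(cfg)
    pairs, _ = synthetic.generate_anatomy(neurons, profiles, cfg)
    ids = pd.unique(pd.concat([pairs["pre_id"], pairs["post_id"]]))
    sims = synthetic.similarity_lookup(profiles, ids, cfg)
    rho = common_input.rho_table(pairs, sims)
    test = common_input.compare_rho(rho)
    pooled = test[test["group"] == "pooled"].iloc[0]
    return float(pooled["mean_diff"]), float(pooled["p"]), float(pooled["t"])


def rho_study(n_reps: int = 100, seed: int = 0, strength: float = 0.0) -> dict:
    """Calibration (strength 0) or power of the rho vs rho' contrast.

    Reports the mean of mean(rho - rho') across replicates and the fraction
    of replicates where the pooled paired t-test rejects at alpha = 0.05
    with a positive mean difference.
    """
    diffs, rejects, pos_rejects = [], 0, 0
    for r in range(n_reps):
        d, p, t = _one_rho_rep(seed * 100_003 + r, strength)
        diffs.append(d)
        rejects += int(p < 0.05)
        pos_rejects += int(p < 0.05 and d > 0)
    return {
        "mean_rho_minus_rho_expected": float(np.mean(diffs)),
        "rejection_rate": rejects / n_reps,
        "positive_rejection_rate": pos_rejects / n_reps,
        "n": n_reps,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# RNN

def rnn_study(n_seeds: int = 5, seed: int = 0, n_classes: int = 10,
              ablate_ns: tuple[int, ...] = (0, 100, 200, 400, 800)) -> dict:
    """Scaled-down RNN like-to-like experiment over several seeds.

    Per seed: train on the Gaussian-blob task, then measure (a) the mean
    signal correlation of connected vs all unit pairs, (b) the trend of
    connection probability across signal-correlation bins, (c) targeted
    like-to-like vs strength-matched random ablation curves, and (d) the
    post-post rho contrast on the thresholded graph.  Returns means over
    seeds.
    """
    conn_minus_all, trends, gaps, postpost, cand_frac, accs = [], [], [], [], [], []
    for s in range(n_seeds):
        cfg = rnn.scaled_config(seed=seed * 1000 + s)
        x_tr, y_tr, x_te, y_te = rnn.make_blob_dataset(n_classes=n_classes, seed=cfg.seed)
        net, hist = rnn.train_rnn(x_tr, y_tr, n_classes, cfg, x_te, y_te)
        accs.append(float(hist["test_acc"].iloc[-1]))
        sc = rnn.hidden_signal_correlations(net, x_te)
        mask, thr, _ = rnn.classify_connections(net.w_rec, percentile=cfg.connection_percentile)
        np.fill_diagonal(mask, False)
        off = ~np.eye(mask.shape[0], dtype=bool) & np.isfinite(sc)
        conn_minus_all.append(float(sc[mask & off].mean() - sc[off].mean()))

        curve = rnn.connection_probability_curve(mask, sc, bins=8)
        trend, _ = stats.spearmanr(curve["bin_center"], curve["p_connected"])
        trends.append(float(trend))

        work_cfg = rnn.RNNConfig(**{**cfg.__dict__, "weight_threshold": thr})
        cand_frac.append(rnn.like_to_like_candidate_fraction(net, sc, work_cfg))
        like = rnn.ablate_and_evaluate(net, x_te, y_te, sc, "like_to_like", ablate_ns, work_cfg)
        rand = rnn.ablate_and_evaluate(net, x_te, y_te, sc, "random", ablate_ns, work_cfg)
        # mean accuracy gap at the intermediate (nonzero) ablation sizes
        inter = like["n_requested"] > 0
        gaps.append(float((rand["accuracy"][inter] - like["accuracy"][inter]).mean()))

        rho = rnn.post_post_analysis(net, sc, work_cfg)
        postpost.append(float((rho["rho_observed"] - rho["rho_expected"]).mean()))
    return {
        "test_accuracy": float(np.mean(accs)),
        "connected_minus_all_sigcorr": float(np.mean(conn_minus_all)),
        "conn_prob_trend_spearman": float(np.mean(trends)),
        "ablation_random_minus_like_accuracy": float(np.mean(gaps)),
        "postpost_rho_minus_expected": float(np.mean(postpost)),
        "like_candidate_weight_fraction": float(np.mean(cand_frac)),
        "n_seeds": n_seeds,
    }
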