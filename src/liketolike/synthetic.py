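"""Synthetic cortical populations with planted like-to-like structure.

The generator emulates the statistical skeleton of a functional-connectomics
volume: neurons with areas, layers and soma positions; retinotopically
organized receptive-field centers; clustered feature tuning; trial-structured
noisy responses driven through the feature weights; and pairwise anatomy in
which the co-travel distance Ld follows a compound Poisson-Gamma (Tweedie)
law whose log-mean increases with functional similarity (the axonal-scale
rule) and synapse counts are Poisson with a log-Ld offset and a
similarity-dependent rate (the synaptic-scale rule).  Optionally a latent
community structure boosts synapse rates within communities, planting
higher-order (common-input) correlations beyond any pairwise rule.

Every planted parameter is recorded in a :class:`GroundTruth` so downstream
estimators can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import Skeleton, projection_type
from .tweedie import TweedieParams, sample_tweedie

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "TuningProfiles",
    "generate_population",
    "generate_responses",
    "generate_anatomy",
    "generate_skeleton_scene",
    "generate_sparse_noise_experiment",
]

DEFAULT_AREA_LAYOUT = {
    "V1": ((0.0, 0.0), (800.0, 800.0)),
    "AL": ((800.0, 0.0), (400.0, 800.0)),
    "RL": ((1200.0, 0.0), (400.0, 800.0)),
}
LAYERS = ("L2/3", "L4", "L5")

#: documented default strength of the planted common-input structure (log
#: synapse-rate boost toward each presyn's randomly favored community);
#: calibrated so the planted effect is reliably detectable by the rho contrast
#: at the default population size, which is what the higher-order power
#: experiments require
HIGHER_ORDER_DEFAULT = 3.0


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic volume.

    Planted slopes are per-similarity dictionaries keyed by metric name
    ("signal_corr", "feature", "rf_distance"); ``beta_axonal`` acts on
    ``log E[Ld]``, ``beta_synaptic`` on the log synapse rate given Ld.
    """

    n_presyn: int = 40
    n_neurons: int = 2000
    feature_dim: int = 64
    n_clusters: int = 5
    cluster_spread: float = 0.6
    area_layout: dict = field(default_factory=lambda: dict(DEFAULT_AREA_LAYOUT))
    rf_gradient: float = 0.05  # degrees of visual angle per um of cortex
    beta_axonal: dict = field(default_factory=lambda: {"signal_corr": 0.8})
    beta_synaptic: dict = field(default_factory=lambda: {"signal_corr": 0.6})
    tweedie: TweedieParams = field(default_factory=lambda: TweedieParams(xi=1.5, phi=10.0))
    ld_base_mean_um: float = 8.0
    presyn_intercept_sd: float = 0.3
    synapse_density_per_mm: float = 50.0
    cleft_log10_mean: float = 3.3
    cleft_log10_sd: float = 0.35
    cleft_similarity_slope: float = 0.3
    higher_order_strength: float = 0.0
    n_communities: int = 5
    community_cluster_coupling: float = 0.7
    signal_var: float = 1.0
    noise_var: float = 1.0
    n_trials: int = 10
    n_timepoints: int = 480
    sampling_rate_hz: float = 8.0
    n_tuning_blocks: int = 15
    n_candidates_per_presyn: int = 100
    n_stim_bins: int = 240
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        if not (self.n_neurons > self.n_presyn >= 1):
            raise ValueError("need n_neurons > n_presyn >= 1")
        if self.signal_var < 0 or self.noise_var < 0:
            raise ValueError("variance components must be nonnegative")
        if self.higher_order_strength < 0:
            raise ValueError("higher_order_strength must be nonnegative")
        if not isinstance(self.tweedie, TweedieParams):
            self.tweedie = TweedieParams(**self.tweedie)


@dataclass
class GroundTruth:
    """Planted parameters, recorded exactly as the generator used them."""

    beta_axonal: dict
    beta_synaptic: dict
    ld_base_mean_um: float
    synapse_density_per_mm: float
    presyn_intercepts: dict
    tweedie: TweedieParams
    higher_order_strength: float
    communities: dict
    signal_var: float
    noise_var: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tweedie"] = {"xi": self.tweedie.xi, "phi": self.tweedie.phi}
        return d


@dataclass
class TuningProfiles:
    """Per-neuron functional ground truth: weights, RF centers, tuning curves."""

    neuron_ids: np.ndarray
    feature_weights: np.ndarray  # (n, feature_dim), unit rows
    rf_centers_deg: np.ndarray  # (n, 2)
    tuning_mu: np.ndarray
    tuning_kappa: np.ndarray
    tuning_p: np.ndarray
    tuning_b: np.ndarray
    noise_scale: np.ndarray


@dataclass
class ResponseSet:
    """Trial-structured movie responses plus direction-tuning block responses."""

    movie: np.ndarray  # (n_neurons, n_trials, n_timepoints)
    sampling_rate_hz: float
    tuning_blocks: np.ndarray  # (n_neurons, n_blocks, 16)
    directions_deg: np.ndarray


def generate_population(config: SyntheticConfig) -> tuple[pd.DataFrame, TuningProfiles]:
    """Neuron metadata table and functional tuning profiles.

    Presynaptic neurons are a stratified sample across areas so every
    projection type has sources.  RF centers follow a linear retinotopic
    gradient away from each area's center; feature vectors come from a
    mixture of ``n_clusters`` directions on the unit sphere.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_neurons
    areas = list(config.area_layout)
    widths = np.array([config.area_layout[a][1][0] for a in areas])
    area_p = widths / widths.sum()
    area = rng.choice(areas, size=n, p=area_p)
    layer = rng.choice(LAYERS, size=n, p=[0.45, 0.3, 0.25])

    pos = np.empty((n, 2))
    rf = np.empty((n, 2))
    for a in areas:
        mask = area == a
        (ox, oy), (wx, wy) = config.area_layout[a]
        pos[mask, 0] = ox + rng.uniform(0, wx, mask.sum())
        pos[mask, 1] = oy + rng.uniform(0, wy, mask.sum())
        center = np.array([ox + wx / 2.0, oy + wy / 2.0])
        rf[mask] = config.rf_gradient * (pos[mask] - center)

    centers = rng.standard_normal((config.n_clusters, config.feature_dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    cluster = rng.integers(0, config.n_clusters, size=n)
    # within-cluster noise scaled by 1/sqrt(dim) so the expected within-cluster
    # cosine ~ 1/(1 + spread^2) is independent of the feature dimension
    w = centers[cluster] + (
        config.cluster_spread / np.sqrt(config.feature_dim)
    ) * rng.standard_normal((n, config.feature_dim))
    w /= np.linalg.norm(w, axis=1, keepdims=True)

    # latent communities: a noisy copy of the functional clusters, so a
    # within-community synapse boost creates partner-partner similarity that
    # no function of the pairwise similarity alone can reproduce
    community = np.where(
        rng.uniform(size=n) < config.community_cluster_coupling,
        cluster % config.n_communities,
        rng.integers(0, config.n_communities, size=n),
    )
    noise_scale = rng.lognormal(mean=0.0, sigma=0.3, size=n)

    # analytic reliability given the planted variance components; the same
    # quantities are recoverable empirically from generate_responses
    s2 = config.signal_var
    sig2 = config.noise_var * noise_scale**2
    with np.errstate(divide="ignore", invalid="ignore"):
        cc_max = np.sqrt(s2 / (s2 + sig2 / config.n_trials)) if s2 > 0 else np.zeros(n)
        cc_abs_base = np.sqrt(s2 / (s2 + sig2)) if s2 > 0 else np.zeros(n)
    cc_abs = cc_abs_base * rng.beta(20, 2, size=n)

    # stratified presyn sample: half V1, half HVA where available
    idx_v1 = np.flatnonzero(area == "V1")
    idx_hva = np.flatnonzero(area != "V1")
    n_v1 = min(config.n_presyn // 2, len(idx_v1))
    pres = np.concatenate(
        [
            rng.choice(idx_v1, size=n_v1, replace=False),
            rng.choice(idx_hva, size=config.n_presyn - n_v1, replace=False),
        ]
    )
    is_presyn = np.zeros(n, dtype=bool)
    is_presyn[pres] = True

    tuning_mu = rng.uniform(0.0, 360.0, size=n)
    tuning_kappa = rng.lognormal(mean=0.7, sigma=0.5, size=n)
    tuning_p = rng.beta(5, 5, size=n)
    tuning_b = rng.uniform(0.0, 0.1, size=n)

    neurons = pd.DataFrame(
        {
            "neuron_id": np.arange(n),
            "area": area,
            "layer": layer,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "rf_x_deg": rf[:, 0],
            "rf_y_deg": rf[:, 1],
            "cluster": cluster,
            "community": community,
            "is_presyn": is_presyn,
            "cc_max": cc_max,
            "cc_abs": cc_abs,
            "proofread": np.where(is_presyn, "manual", "auto"),
        }
    )
    profiles = TuningProfiles(
        neuron_ids=np.arange(n),
        feature_weights=w,
        rf_centers_deg=rf,
        tuning_mu=tuning_mu,
        tuning_kappa=tuning_kappa,
        tuning_p=tuning_p,
        tuning_b=tuning_b,
        noise_scale=noise_scale,
    )
    return neurons, profiles


def generate_responses(profiles: TuningProfiles, config: SyntheticConfig) -> ResponseSet:
    """Low-rank factor-model responses plus direction-tuning blocks.

    A shared latent stimulus drive (feature_dim x timepoints) is projected
    through each neuron's feature weights and scaled to ``signal_var``; the
    same drive repeats across trials while Gaussian noise (``noise_var``
    scaled per neuron) is independent per trial.  Tuning blocks present 16
    equally spaced directions generated from each neuron's two-peaked von
    Mises curve plus the same noise model.
    """
    if config.n_trials < 2:
        raise ValueError("need at least 2 trials for reliability estimation")
    from .similarity import direction_grid, von_mises_curve

    rng = np.random.default_rng(config.seed + 1)
    n, d = profiles.feature_weights.shape
    latent = rng.standard_normal((d, config.n_timepoints))
    signal = profiles.feature_weights @ latent  # rows ~ N(0, ||w||^2 * 1) = N(0,1)
    signal = signal * np.sqrt(config.signal_var)
    noise_sd = np.sqrt(config.noise_var) * profiles.noise_scale
    movie = signal[:, None, :] + noise_sd[:, None, None] * rng.standard_normal(
        (n, config.n_trials, config.n_timepoints)
    )

    dirs = direction_grid(16)
    curves = np.stack(
        [
            von_mises_curve(dirs, profiles.tuning_mu[i], profiles.tuning_kappa[i],
                            profiles.tuning_p[i], profiles.tuning_b[i])
            for i in range(n)
        ]
    )
    blocks = curves[:, None, :] + 0.1 * noise_sd[:, None, None] * rng.standard_normal(
        (n, config.n_tuning_blocks, 16)
    )
    return ResponseSet(movie, config.sampling_rate_hz, blocks, dirs)


def _normalized_battery_responses(profiles: TuningProfiles, config: SyntheticConfig) -> np.ndarray:
    """Noiseless, z-scored responses to a fixed latent stimulus battery.

    The battery is a deterministic function of the config seed, so pairwise
    signal correlations computed here agree exactly wherever they appear
    (pair table, partner-partner lookup).
    """
    w = profiles.feature_weights
    stim_rng = np.random.default_rng(config.seed + 3)
    stim = stim_rng.standard_normal((w.shape[1], config.n_stim_bins))
    resp = w @ stim
    return (resp - resp.mean(axis=1, keepdims=True)) / resp.std(axis=1, keepdims=True)


def _pair_similarities(profiles: TuningProfiles, pre: np.ndarray, post: np.ndarray, config):
    """Deterministic pairwise similarities for planted rules.

    The in-silico signal correlation is the correlation of the two neurons'
    noiseless responses to a finite latent stimulus battery; with many bins
    it approaches the feature cosine but carries finite-battery jitter, so
    the two metrics are coupled without being identical.
    """
    w = profiles.feature_weights
    resp = _normalized_battery_responses(profiles, config)
    sim_signal = np.einsum("ij,ij->i", resp[pre], resp[post]) / config.n_stim_bins
    sim_feature = np.einsum("ij,ij->i", w[pre], w[post])
    rfd = np.linalg.norm(profiles.rf_centers_deg[pre] - profiles.rf_centers_deg[post], axis=1)
    return sim_signal, sim_feature, rfd


def similarity_lookup(profiles: TuningProfiles, ids, config: SyntheticConfig) -> pd.DataFrame:
    """Symmetric signal-correlation lookup over a subset of neurons.

    Uses the same latent battery as the pair table, so entries match the
    recorded ``sim_signal_corr`` values exactly.
    """
    ids = np.asarray(ids)
    resp = _normalized_battery_responses(profiles, config)[ids]
    mat = resp @ resp.T / config.n_stim_bins
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=ids, columns=ids)


def generate_anatomy(
    neurons: pd.DataFrame,
    profiles: TuningProfiles,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Pair table with planted axonal- and synaptic-scale rules.

    For each presyn, ``n_candidates_per_presyn`` candidate partners are
    sampled.  Ld is Tweedie with log-mean linear in the planted similarity
    terms plus a per (presyn x projection) random intercept; synapse counts
    given Ld > 0 are Poisson with a log-Ld offset, the synaptic-scale
    similarity term, and (when ``higher_order_strength > 0``) a log-rate
    boost toward each presyn's randomly favored latent community; cleft
    volumes are lognormal with a similarity-dependent mean.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    pres_ids = neurons.loc[neurons["is_presyn"], "neuron_id"].to_numpy()
    others = neurons.loc[~neurons["is_presyn"], "neuron_id"].to_numpy()
    area = neurons.set_index("neuron_id")["area"]
    community = neurons.set_index("neuron_id")["community"]

    pre_list, post_list = [], []
    for i in pres_ids:
        cand = rng.choice(others, size=min(config.n_candidates_per_presyn, len(others)), replace=False)
        pre_list.append(np.full(len(cand), i))
        post_list.append(cand)
    pre = np.concatenate(pre_list)
    post = np.concatenate(post_list)

    sim_signal, sim_feature, rfd = _pair_similarities(profiles, pre, post, config)
    sims = {"signal_corr": sim_signal, "feature": sim_feature, "rf_distance": rfd}
    proj = np.array([projection_type(area[a], area[b]) for a, b in zip(pre, post)])

    groups = pd.unique(pd.Series([f"{i}|{p}" for i, p in zip(pre, proj)]))
    u = {g: rng.normal(0.0, config.presyn_intercept_sd) for g in groups}
    u_pair = np.array([u[f"{i}|{p}"] for i, p in zip(pre, proj)])

    log_mu = np.log(config.ld_base_mean_um) + u_pair
    for m, beta in config.beta_axonal.items():
        log_mu = log_mu + beta * sims[m]
    ld = sample_tweedie(np.exp(log_mu), config.tweedie, rng)

    log_rate = np.full(len(pre), -np.inf)
    pos = ld > 0
    log_rate[pos] = np.log(ld[pos] / 1000.0) + np.log(config.synapse_density_per_mm)
    for m, beta in config.beta_synaptic.items():
        log_rate = log_rate + beta * sims[m]
    favored = None
    if config.higher_order_strength > 0:
        # common-input clustering: each presyn favors one latent community,
        # chosen uniformly at random, with a fixed log-rate boost.  Which
        # community a presyn favors is unpredictable from any pairwise
        # similarity, yet its partners end up functionally similar to each
        # other -- structure beyond any pairwise rule
        favored = {pid: int(rng.integers(config.n_communities)) for pid in pres_ids}
        hit = np.array(
            [favored[i] == community[j] for i, j in zip(pre, post)], dtype=float
        )
        log_rate = log_rate + config.higher_order_strength * hit
    nsyn = np.zeros(len(pre), dtype=int)
    nsyn[pos] = rng.poisson(np.exp(log_rate[pos]))

    mean_cleft = np.full(len(pre), np.nan)
    conn = nsyn > 0
    for k in np.flatnonzero(conn):
        logs = rng.normal(
            config.cleft_log10_mean + config.cleft_similarity_slope * sim_signal[k],
            config.cleft_log10_sd,
            size=nsyn[k],
        )
        mean_cleft[k] = logs.mean()

    pairs = pd.DataFrame(
        {
            "pre_id": pre,
            "post_id": post,
            "projection": proj,
            "ld_um": ld,
            "nsyn": nsyn,
            "mean_log10_cleft_volume": mean_cleft,
            "sim_signal_corr": sim_signal,
            "sim_feature": sim_feature,
            "rf_distance_deg": rfd,
            "same_community": (community[pre].to_numpy() == community[post].to_numpy()),
        }
    )
    truth = GroundTruth(
        beta_axonal=dict(config.beta_axonal),
        beta_synaptic=dict(config.beta_synaptic),
        ld_base_mean_um=config.ld_base_mean_um,
        synapse_density_per_mm=config.synapse_density_per_mm,
        presyn_intercepts=u,
        tweedie=config.tweedie,
        higher_order_strength=config.higher_order_strength,
        communities={int(k): int(v) for k, v in community.items()},
        signal_var=config.signal_var,
        noise_var=config.noise_var,
    )
    return pairs, truth


def _line_skeleton(start, direction, length, compartment, neuron_id, spacing=1.0):
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n_seg = int(round(length / spacing))
    t = np.arange(n_seg + 1) * spacing
    verts = np.asarray(start, dtype=float) + t[:, None] * direction
    edges = np.column_stack([np.arange(n_seg), np.arange(1, n_seg + 1)])
    return Skeleton(verts, edges, compartment, neuron_id)


def generate_skeleton_scene(
    n_pairs: int,
    rng: np.random.Generator | None = None,
    radius: float = 5.0,
):
    """Small axon/dendrite scenes with analytically known co-travel distance.

    Cycles through scene types: parallel runs inside the radius (Ld = full
    dendrite length), parallel runs outside (Ld = 0), disjoint runs (0), and
    perpendicular crossings where the proximal run length follows from the
    chord ``2 sqrt(r^2 - s^2)`` and the 1 um vertex spacing.  Also emits a
    synapse table with one assignable synapse (at a proximal dendrite
    vertex) and one distant, unassignable synapse per positive-Ld scene.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    scenes, syn_rows, expected = [], [], []
    syn_id = 0
    for k in range(n_pairs):
        kind = ("parallel_in", "parallel_out", "disjoint", "crossing")[k % 4]
        base = rng.uniform(-200, 200, size=3)
        if kind == "parallel_in":
            sep, dlen = 3.0, 10.0
            axon = _line_skeleton(base + [-2.0, 0, 0], [1, 0, 0], dlen + 4.0, "axon", f"pre{k}")
            dend = _line_skeleton(base + [0.0, sep, 0], [1, 0, 0], dlen, "dendrite", f"post{k}")
            exp = dlen
        elif kind == "parallel_out":
            sep, dlen = 6.0, 10.0
            axon = _line_skeleton(base + [-2.0, 0, 0], [1, 0, 0], dlen + 4.0, "axon", f"pre{k}")
            dend = _line_skeleton(base + [0.0, sep, 0], [1, 0, 0], dlen, "dendrite", f"post{k}")
            exp = 0.0
        elif kind == "disjoint":
            axon = _line_skeleton(base, [1, 0, 0], 12.0, "axon", f"pre{k}")
            dend = _line_skeleton(base + [0, 50.0, 0], [0, 1, 0], 10.0, "dendrite", f"post{k}")
            exp = 0.0
        else:  # perpendicular crossing at vertical separation s
            s = 3.5
            half = 8.0
            c = np.sqrt(radius**2 - s**2)  # ~3.57, safely between vertex positions
            axon = _line_skeleton(base + [0, -half, 0], [0, 1, 0], 2 * half, "axon", f"pre{k}")
            dend = _line_skeleton(base + [-half, 0, s], [1, 0, 0], 2 * half, "dendrite", f"post{k}")
            m = 2 * int(np.floor(c)) + 1  # proximal dendrite vertices
            exp = float(m + 1)  # edges touching the proximal run, 1 um each
        scenes.append((axon, dend))
        expected.append(exp)
        if exp > 0:
            v = dend.vertices[dend.n_vertices // 2]
            syn_rows.append(
                {"synapse_id": syn_id, "pre_id": f"pre{k}", "post_id": f"post{k}",
                 "x_um": v[0], "y_um": v[1], "z_um": v[2],
                 "cleft_volume_voxels": int(rng.integers(500, 40000)), "expected_assigned": True}
            )
            syn_id += 1
            far = dend.vertices[0] + np.array([0.0, 0.0, 50.0])
            syn_rows.append(
                {"synapse_id": syn_id, "pre_id": f"pre{k}", "post_id": f"post{k}",
                 "x_um": far[0], "y_um": far[1], "z_um": far[2],
                 "cleft_volume_voxels": int(rng.integers(500, 40000)), "expected_assigned": False}
            )
            syn_id += 1
    synapses = pd.DataFrame(
        syn_rows,
        columns=["synapse_id", "pre_id", "post_id", "x_um", "y_um", "z_um",
                 "cleft_volume_voxels", "expected_assigned"],
    )
    return scenes, synapses, np.asarray(expected)


def generate_sparse_noise_experiment(
    rf_center: tuple[float, float],
    rf_width: float = 1.2,
    grid: int = 12,
    n_frames: int = 17_280,
    noise_sd: float = 0.2,
    rng: np.random.Generator | None = None,
):
    """Sparse-noise frames plus a Gaussian-RF neuron's responses.

    One bright (+1) or dark (-1) dot per 200 ms frame on a ``grid x grid``
    field; the neuron responds to dot energy under a 2-D Gaussian receptive
    field at ``rf_center`` (grid units) plus Gaussian noise.  The default
    frame count matches the sparse-noise protocol (12 x 12 positions, two
    polarities, 60 repeats each) and keeps the in-sample STA prediction of
    a pure-noise neuron well below the inclusion threshold.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    stimuli = np.zeros((n_frames, grid, grid))
    ys = rng.integers(0, grid, n_frames)
    xs = rng.integers(0, grid, n_frames)
    pol = rng.choice([-1.0, 1.0], n_frames)
    stimuli[np.arange(n_frames), ys, xs] = pol
    yy, xx = np.mgrid[0:grid, 0:grid]
    rf = np.exp(-0.5 * (((xx - rf_center[0]) / rf_width) ** 2 + ((yy - rf_center[1]) / rf_width) ** 2))
    responses = rf[ys, xs] * np.abs(pol) + noise_sd * rng.standard_normal(n_frames)
    return stimuli, responses
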