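"""Functional similarity metrics and inclusion statistics.

Covers the per-neuron and per-pair functional measurements of the analysis:
signal correlation of binned responses, the CCmax response-reliability
ceiling and the CCabs model-prediction correlation used as inclusion
criteria, cosine similarity of readout feature-weight vectors, the visual
angle between receptive-field centers, orientation-selectivity indices
(gOSI/OSI), the two-peaked von Mises fit of direction tuning, and
spike-triggered-average receptive-field mapping on sparse-noise stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "ResponseMatrix",
    "signal_correlation",
    "signal_correlation_matrix",
    "cc_max",
    "cc_abs",
    "feature_similarity",
    "MonitorGeometry",
    "rf_center_distance",
    "gosi",
    "osi",
    "VonMisesFit",
    "von_mises_curve",
    "fit_von_mises",
    "delta_orientation",
    "StaFit",
    "sta_fit",
]

CC_MAX_THRESHOLD = 0.4
CC_ABS_THRESHOLD = 0.2
GOSI_THRESHOLD = 0.25


@dataclass
class ResponseMatrix:
    """Trial-structured responses: (neurons, trials, timepoints) at a fixed rate."""

    values: np.ndarray
    sampling_rate_hz: float
    stim_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (neurons, trials, timepoints)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("responses must be finite")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    def binned(self, bin_ms: float = 500.0) -> np.ndarray:
        """Average into non-overlapping bins per trial, concatenated across trials.

        Returns (neurons, trials * n_bins); a trailing partial bin is dropped.
        """
        per_bin = max(int(round(self.sampling_rate_hz * bin_ms / 1000.0)), 1)
        n_bins = self.values.shape[2] // per_bin
        if n_bins < 1:
            raise ValueError("fewer than one full bin after binning")
        trimmed = self.values[:, :, : n_bins * per_bin]
        binned = trimmed.reshape(self.n_neurons, self.n_trials, n_bins, per_bin).mean(axis=3)
        return binned.reshape(self.n_neurons, self.n_trials * n_bins)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def signal_correlation(a, b, sampling_rate_hz: float | None = None, bin_ms: float = 500.0):
    """Pearson correlation of two neurons' binned response traces.

    ``a`` and ``b`` are (trials, timepoints) arrays on a common time base (or
    1-D traces).  Responses are averaged in ``bin_ms`` non-overlapping bins
    per trial and concatenated across trials before correlating.  Returns NaN
    when either binned trace has zero variance.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("responses must share the same trial/time shape")
    if sampling_rate_hz is not None:
        rm = ResponseMatrix(np.stack([a, b]), sampling_rate_hz)
        ab = rm.binned(bin_ms)
        return _pearson(ab[0], ab[1])
    return _pearson(a.ravel(), b.ravel())


def signal_correlation_matrix(rm: ResponseMatrix, bin_ms: float = 500.0) -> np.ndarray:
    """All pairwise signal correlations of a response matrix (NaN for flat rows)."""
    binned = rm.binned(bin_ms)
    sd = binned.std(axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(binned)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return corr


def cc_max(trials: np.ndarray) -> float:
    """Reliability ceiling of a neuron's trial-to-trial responses.

    ``trials`` is (N trials, timepoints).  CCmax is
    ``sqrt[(N Var(ybar) - mean_t Var(y)) / ((N - 1) Var(ybar))]`` where
    Var(ybar) is the variance over time of the trial-averaged response and
    mean Var(y) averages each trial's temporal variance.  A negative
    radicand (noise-dominated neuron) is clipped to 0; a flat trial average
    yields NaN.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 2 or trials.shape[0] < 2:
        raise ValueError("need a (trials, time) array with at least 2 trials")
    n = trials.shape[0]
    var_mean = trials.mean(axis=0).var(ddof=1)
    mean_var = trials.var(axis=1, ddof=1).mean()
    if var_mean == 0:
        return np.nan
    radicand = (n * var_mean - mean_var) / ((n - 1) * var_mean)
    return float(np.sqrt(max(radicand, 0.0)))


def cc_abs(pred: np.ndarray, obs: np.ndarray) -> float:
    """Prediction performance: Pearson r of model prediction vs trial-mean response."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size or pred.size < 2:
        raise ValueError("prediction and observation must be equal length >= 2")
    return _pearson(pred, obs)


def feature_similarity(wa: np.ndarray, wb: np.ndarray) -> float:
    """Cosine similarity of two readout feature-weight vectors."""
    wa = np.asarray(wa, dtype=float).ravel()
    wb = np.asarray(wb, dtype=float).ravel()
    if wa.shape != wb.shape:
        raise ValueError("feature vectors must have equal dimension")
    na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
    if na == 0 or nb == 0:
        raise ValueError("feature vectors must be nonzero")
    return float(np.clip(wa @ wb / (na * nb), -1.0, 1.0))


@dataclass(frozen=True)
class MonitorGeometry:
    """Viewing geometry: eye on the monitor normal through its center."""

    distance_cm: float = 15.0

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise ValueError("viewing distance must be positive")


def rf_center_distance(pa, pb, geom: MonitorGeometry = MonitorGeometry()) -> float:
    """Visual angle (degrees) between two monitor points seen from the eye.

    Points are 2-D monitor-plane coordinates in cm relative to the monitor
    center; the eye sits on the normal through the center at
    ``geom.distance_cm``.
    """
    ra = np.array([pa[0], pa[1], geom.distance_cm], dtype=float)
    rb = np.array([pb[0], pb[1], geom.distance_cm], dtype=float)
    cosang = ra @ rb / (np.linalg.norm(ra) * np.linalg.norm(rb))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _check_curve(responses) -> np.ndarray:
    r = np.asarray(responses, dtype=float).ravel()
    if r.size != 16:
        raise ValueError("tuning curve must have 16 directions")
    return r


def direction_grid(n: int = 16) -> np.ndarray:
    """Equally spaced stimulus directions in degrees, [0, 360)."""
    return np.arange(n) * 360.0 / n


def gosi(responses) -> float:
    """Global orientation selectivity index: |sum R e^{2i theta}| / sum R."""
    r = _check_curve(responses)
    total = r.sum()
    if total <= 0:
        return np.nan
    theta = np.radians(direction_grid(r.size))
    return float(np.abs(np.sum(r * np.exp(2j * theta))) / total)


def osi(responses, preferred_orientation: float) -> float:
    """(R_po - R_ortho) / (R_po + R_ortho) around a preferred orientation.

    R_po averages the responses at the two opposite directions nearest the
    preferred orientation; R_ortho does the same 90 degrees away.
    """
    r = _check_curve(responses)
    theta = direction_grid(r.size)

    def _resp_at(ori):
        d = np.abs((theta - ori + 90.0) % 180.0 - 90.0)  # orientation distance
        nearest = d.min()
        return r[np.isclose(d, nearest)].mean()

    r_po = _resp_at(preferred_orientation % 180.0)
    r_ortho = _resp_at((preferred_orientation + 90.0) % 180.0)
    if r_po + r_ortho == 0:
        return np.nan
    return float((r_po - r_ortho) / (r_po + r_ortho))


def von_mises_curve(theta_deg, mu, kappa, p, b):
    """Two-peaked von Mises direction-tuning curve with an offset.

    ``(1 / (2 pi I0(kappa))) * (p exp(kappa cos(t - mu))
    + (1 - p) exp(-kappa cos(t - mu))) + b`` with angles in degrees.
    """
    t = np.radians(np.asarray(theta_deg, dtype=float) - mu)
    norm = 1.0 / (2.0 * np.pi * special.i0(kappa))
    return norm * (p * np.exp(kappa * np.cos(t)) + (1.0 - p) * np.exp(-kappa * np.cos(t))) + b


@dataclass
class VonMisesFit:
    mu: float
    kappa: float
    p: float
    b: float
    sse: float
    r_squared: float
    converged: bool
    degenerate: bool

    @property
    def preferred_orientation(self) -> float:
        return self.mu % 180.0


def fit_von_mises(responses, n_starts: int = 8, kappa_max: float = 20.0) -> VonMisesFit:
    """Least-squares fit of the two-peaked von Mises curve to 16 mean responses.

    Multi-start over ``n_starts`` equally spaced preferred directions with box
    constraints kappa in [0, kappa_max], p in [0, 1].  A fit whose curve is
    effectively flat (kappa ~ 0 or no variance explained) is flagged
    degenerate: its preferred direction is unidentifiable.
    """
    r = _check_curve(responses)
    theta = direction_grid(r.size)

    def residuals(params):
        mu, kappa, p, b = params
        return von_mises_curve(theta, mu, kappa, p, b) - r

    best = None
    for mu0 in np.arange(n_starts) * 360.0 / n_starts:
        x0 = [mu0, 2.0, 0.6, float(r.min())]
        try:
            sol = optimize.least_squares(
                residuals,
                x0,
                bounds=([-360.0, 0.0, 0.0, -np.inf], [720.0, kappa_max, 1.0, np.inf]),
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return VonMisesFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, True)
    mu, kappa, p, b = best.x
    sse = float(2.0 * best.cost)
    tss = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else 0.0
    degenerate = kappa < 1e-3 or tss == 0 or r2 < 1e-6
    # p and mu are exchangeable under mu -> mu + 180, p -> 1 - p; canonicalize
    mu = mu % 360.0
    return VonMisesFit(float(mu), float(kappa), float(p), float(b), sse, r2, True, bool(degenerate))


def delta_orientation(oa: float, ob: float) -> float:
    """Circular distance between preferred orientations on the 180-degree circle."""
    d = abs(oa - ob) % 180.0
    return float(min(d, 180.0 - d))


@dataclass
class StaFit:
    """Spike-triggered-average receptive field and its 2-D Gaussian fit."""

    on_sta: np.ndarray
    off_sta: np.ndarray
    combined: np.ndarray
    center: tuple[float, float] | None
    widths: tuple[float, float] | None
    r_squared: float
    prediction_correlation: float
    well_characterized: bool
    well_fit: bool


def _fit_gaussian_2d(img: np.ndarray):
    """Least-squares 2-D Gaussian (amplitude, center, widths, offset) on a grid."""
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    peak = np.unravel_index(np.argmax(img), img.shape)
    x0 = [img.max() - img.min(), peak[1], peak[0], 1.0, 1.0, img.min()]

    def model(params):
        a, cx, cy, sx, sy, off = params
        return a * np.exp(-0.5 * (((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2)) + off

    def residuals(params):
        return (model(params) - img).ravel()

    lb = [0.0, -1.0, -1.0, 0.2, 0.2, -np.inf]
    ub = [np.inf, nx, ny, nx, ny, np.inf]
    sol = optimize.least_squares(residuals, x0, bounds=(lb, ub))
    sse = float(np.sum(sol.fun**2))
    tss = float(np.sum((img - img.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else 0.0
    a, cx, cy, sx, sy, off = sol.x
    return (cx, cy), (sx, sy), r2


def sta_fit(
    stimuli: np.ndarray,
    responses: np.ndarray,
    pred_threshold: float = 0.2,
    r2_threshold: float = 0.5,
) -> StaFit:
    """STA receptive-field estimate from sparse-noise frames.

    ``stimuli`` is (frames, ny, nx) with +1 for a bright dot, -1 for a dark
    dot, 0 for background; ``responses`` is the per-frame response trace.
    On- and off-STAs are the mean response given a bright/dark dot at each
    pixel (baseline-subtracted), combined by pixelwise maximum.  The STA
    predicts responses by correlating each frame with the on/off maps; a
    neuron is well-characterized when that prediction correlates > 0.2 with
    the observed trace, and well-fit when the 2-D Gaussian explains r2 > 0.5.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    responses = np.asarray(responses, dtype=float).ravel()
    if stimuli.ndim != 3 or stimuli.shape[0] != responses.size:
        raise ValueError("stimuli must be (frames, ny, nx) aligned with responses")
    baseline = responses.mean()
    bright = stimuli > 0
    dark = stimuli < 0
    with np.errstate(invalid="ignore", divide="ignore"):
        on = np.tensordot(responses, bright, axes=1) / np.maximum(bright.sum(axis=0), 1)
        off = np.tensordot(responses, dark, axes=1) / np.maximum(dark.sum(axis=0), 1)
    on = on - baseline
    off = off - baseline
    combined = np.maximum(on, off)

    pred = np.tensordot(bright, on, axes=([1, 2], [0, 1])) + np.tensordot(
        dark, off, axes=([1, 2], [0, 1])
    )
    pred_corr = _pearson(pred, responses)
    well_char = bool(np.isfinite(pred_corr) and pred_corr > pred_threshold)

    if not np.any(combined != 0):
        return StaFit(on, off, combined, None, None, np.nan, pred_corr, well_char, False)
    try:
        center, widths, r2 = _fit_gaussian_2d(combined)
    except Exception:
        return StaFit(on, off, combined, None, None, np.nan, pred_corr, well_char, False)
    return StaFit(on, off, combined, center, widths, r2, pred_corr, well_char, bool(r2 > r2_threshold))
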