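"""Morlet time-frequency analysis of feedback-locked epochs.

Single-trial oscillatory power is computed by convolution with complex
Morlet wavelets (c = 6 cycles, unit-energy normalization) on a 25-layer
logarithmic grid from 2 to 50 Hz, normalized trial-by-trial to the 200 ms
pre-stimulus baseline, and summarized by the maximum peak power in a
post-stimulus search window (100–600 ms for theta, 100–500 ms for
high-beta). Condition effects on averaged peak power are assessed with a
linear mixed model (valence + magnitude fixed effects, random subject
intercept, condition-specific residual variances, ML estimation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal as sps, stats

from .preprocess import EpochSet

THETA_WINDOW_MS = (100.0, 600.0)
BETA_WINDOW_MS = (100.0, 500.0)


@dataclass
class FrequencyGrid:
    """Logarithmically spaced wavelet layer centers with adjacent-layer band edges."""

    f_min: float = 2.0
    f_max: float = 50.0
    n_layers: int = 25
    morlet_c: float = 6.0
    centers: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("need at least 2 layers")
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        k = np.arange(self.n_layers)
        self.centers = self.f_min * (self.f_max / self.f_min) ** (k / (self.n_layers - 1))

    def band_edges(self, layer: int) -> tuple[float, float]:
        """Band of a layer = the centers of its neighbouring layers."""
        lo = self.centers[layer - 1] if layer > 0 else self.f_min
        hi = self.centers[layer + 1] if layer < self.n_layers - 1 else self.f_max
        return float(lo), float(hi)

    def layer_near(self, freq: float) -> int:
        return int(np.argmin(np.abs(np.log(self.centers) - math.log(freq))))

    @property
    def theta_layer(self) -> int:
        return self.layer_near(5.1)

    @property
    def beta_layer(self) -> int:
        return self.layer_near(25.5)

    @staticmethod
    def truncate1(x: float) -> float:
        """Truncate (not round) to one decimal, the display convention."""
        return math.floor(x * 10) / 10


def build_frequency_grid(
    f_min: float = 2.0, f_max: float = 50.0, n: int = 25, c: float = 6.0
) -> FrequencyGrid:
    return FrequencyGrid(f_min=f_min, f_max=f_max, n_layers=n, morlet_c=c)


def morlet_wavelet(freq: float, sfreq: float, c: float = 6.0, n_sigmas: float = 5.0) -> np.ndarray:
    """Complex Morlet wavelet with c cycles, unit-energy (Gabor) normalization.

    The Gaussian envelope has time s.d. sigma_t = c / (2 pi f); support is
    truncated at +-n_sigmas * sigma_t.
    """
    sigma_t = c / (2 * np.pi * freq)
    half = int(np.ceil(n_sigmas * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(-(t**2) / (2 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / sfreq)  # unit energy
    return w


@dataclass
class PowerSeries:
    """Single-trial power time courses at one frequency layer and channel."""

    power: np.ndarray  # trials x samples
    times_ms: np.ndarray
    layer: int
    freq: float
    channel: str
    metadata: pd.DataFrame
    normalized: bool = False
    baseline_norm: np.ndarray | None = None  # per-trial n (microvolt^2)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.power.shape[0], dtype=bool)


def morlet_power(
    epochs: EpochSet,
    grid: FrequencyGrid,
    layer: int,
    channel: str = "Fz",
    retained_only: bool = True,
) -> PowerSeries:
    """Squared magnitude of the Morlet convolution, per retained trial.

    Power is in microvolt^2 (up to the unit-energy wavelet scaling); the
    epoch time base is preserved (same-length convolution).
    """
    freq = float(grid.centers[layer])
    if freq >= epochs.sfreq / 2:
        raise ValueError(f"layer frequency {freq:.1f} Hz at/above Nyquist")
    es = epochs.retained() if retained_only else epochs
    ci = es.ch_names.index(channel)
    w = morlet_wavelet(freq, es.sfreq, c=grid.morlet_c)
    # calibrate the analytic amplitude: a unit-energy wavelet has an
    # arbitrary passband gain, so rescale such that a sinusoid of
    # amplitude A at the layer center yields plateau power A^2
    t = np.arange(len(w)) / es.sfreq
    gain = np.abs(np.sum(w * np.exp(-2j * np.pi * freq * t)))
    w = w * (2.0 / gain)
    x = es.data[:, ci, :]
    conv = sps.fftconvolve(x, w[None, :], mode="same", axes=1)
    return PowerSeries(
        power=np.abs(conv) ** 2,
        times_ms=es.times_ms,
        layer=layer,
        freq=freq,
        channel=channel,
        metadata=es.metadata.copy(),
    )


def baseline_normalize(
    p: PowerSeries,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    floor: float = 1e-12,
    weighted_sum: bool = False,
) -> PowerSeries:
    """Divide each trial's power by its baseline norm value n.

    By default n is the mean power over the baseline samples, so a
    stationary signal normalizes to 1. With ``weighted_sum=True`` n is
    instead the baseline sum scaled by the baseline/segment length ratio
    (an alternative reading of the same vendor convention). Trials whose
    n falls at/below the numerical floor are flagged invalid rather than
    silently producing NaN.
    """
    sel = (p.times_ms >= baseline_ms[0]) & (p.times_ms < baseline_ms[1])
    if not sel.any():
        raise ValueError("baseline window outside the epoch")
    base = p.power[:, sel]
    if weighted_sum:
        n = base.sum(axis=1) * (sel.sum() / p.power.shape[1])
    else:
        n = base.mean(axis=1)
    valid = n > floor
    safe = np.where(valid, n, 1.0)
    return PowerSeries(
        power=p.power / safe[:, None],
        times_ms=p.times_ms,
        layer=p.layer,
        freq=p.freq,
        channel=p.channel,
        metadata=p.metadata,
        normalized=True,
        baseline_norm=n,
        valid=p.valid & valid,
    )


def extract_peak_power(p: PowerSeries, window_ms: tuple[float, float]) -> pd.DataFrame:
    """Maximum normalized power and its latency inside a post-stimulus window.

    Returns a table with one row per valid trial: peak power, peak latency
    (ms), the search window, layer, plus whatever metadata the trials
    carry. Ties break toward the earliest latency (argmax convention).
    """
    sel = (p.times_ms >= window_ms[0]) & (p.times_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("empty peak search window")
    t_win = p.times_ms[sel]
    x = p.power[:, sel]
    idx = np.argmax(x, axis=1)
    table = p.metadata.copy().reset_index(drop=True)
    table["peak_power"] = x[np.arange(x.shape[0]), idx]
    table["peak_latency_ms"] = t_win[idx]
    table["window_lo_ms"] = window_ms[0]
    table["window_hi_ms"] = window_ms[1]
    table["layer"] = p.layer
    table["layer_freq"] = p.freq
    return table[np.asarray(p.valid)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# linear mixed model on subject x condition mean peak power
# ---------------------------------------------------------------------------


@dataclass
class LMMResult:
    """ML fit of cell-mean ~ valence + magnitude with a random subject
    intercept and condition-specific (diagonal) residual variances."""

    fixed_effects: dict[str, float]
    f_stats: dict[str, float]
    df_num: dict[str, float]
    df_den: dict[str, float]
    p_values: dict[str, float]
    subject_var: float
    residual_vars: dict[str, float]
    loglik: float
    converged: bool


def aggregate_cell_means(peaks: pd.DataFrame, value_col: str = "peak_power") -> pd.DataFrame:
    """Average peak power over trials within subject x condition."""
    out = (
        peaks.groupby(["subject", "condition"], as_index=False)[value_col]
        .mean()
        .rename(columns={value_col: "mean_peak"})
    )
    out["valence"] = np.where(out["condition"].str.endswith("gain"), "gain", "loss")
    out["magnitude"] = np.where(out["condition"].str.startswith("large"), 25, 5)
    return out


def _lmm_design(cells: pd.DataFrame, include_interaction: bool) -> tuple[np.ndarray, list[str]]:
    val = (cells["valence"] == "loss").to_numpy(float) - 0.5  # effect-coded
    mag = (cells["magnitude"] == 25).to_numpy(float) - 0.5
    cols = [np.ones(len(cells)), val, mag]
    names = ["intercept", "valence", "magnitude"]
    if include_interaction:
        cols.append(val * mag)
        names.append("valence_x_magnitude")
    return np.column_stack(cols), names


def fit_power_lmm(
    cells: pd.DataFrame,
    include_interaction: bool = False,
    method: str = "reml",
) -> LMMResult:
    """Fit the repeated-measures mixed model on subject x condition means.

    Model: y_sc = Xb + u_s + e_sc with u_s ~ N(0, s2_u) and
    e_sc ~ N(0, s2_c) depending on the condition c (diagonal residual
    covariance). Variance components by REML (default; unbiased, keeps
    the type-I error of the Wald tests at its nominal level) or plain ML
    (``method="ml"``). Fixed effects tested with Wald F (numerator df 1)
    and Satterthwaite-approximated denominator df computed by the delta
    method from the estimated covariance of the variance parameters.
    """
    if method not in ("reml", "ml"):
        raise ValueError(f"unknown method {method!r}")
    subjects = cells["subject"].unique()
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    conditions = sorted(cells["condition"].unique())
    cond_index = {c: i for i, c in enumerate(conditions)}
    X, names = _lmm_design(cells, include_interaction)
    y = cells["mean_peak"].to_numpy(float)
    cidx = cells["condition"].map(cond_index).to_numpy()
    groups = [np.flatnonzero((cells["subject"] == s).to_numpy()) for s in subjects]

    n_res = len(conditions)

    def unpack(theta):
        s2_u = np.exp(theta[0])
        s2_c = np.exp(theta[1:])
        return s2_u, s2_c

    # balanced case: every subject has the same condition pattern, so the
    # per-subject covariance (and whitened design) is shared — one Cholesky
    patterns = {tuple(cidx[g]) for g in groups}
    balanced = len(patterns) == 1 and len({len(g) for g in groups}) == 1
    if balanced:
        g0 = groups[0]
        Y = np.stack([y[g] for g in groups])  # subjects x cells
        X0 = X[g0]
        c0 = cidx[g0]

    def gls(theta):
        s2_u, s2_c = unpack(theta)
        if balanced:
            V = np.full((len(g0), len(g0)), s2_u) + np.diag(s2_c[c0])
            L = np.linalg.cholesky(V)
            logdet = len(groups) * 2 * np.sum(np.log(np.diag(L)))
            Xi = np.linalg.solve(L, X0)
            Yi = np.linalg.solve(L, Y.T).T  # subjects x cells, whitened
            XtVX = len(groups) * (Xi.T @ Xi)
            XtVy = Xi.T @ Yi.sum(axis=0)
            beta = np.linalg.solve(XtVX, XtVy)
            resid = Yi - (Xi @ beta)[None, :]
            rss = float(np.sum(resid**2))
            n = len(y)
            nll = 0.5 * (n * np.log(2 * np.pi) + logdet + rss)
            return nll, beta, XtVX
        XtVX = np.zeros((X.shape[1], X.shape[1]))
        XtVy = np.zeros(X.shape[1])
        logdet = 0.0
        quad_parts = []
        for g in groups:
            V = np.full((len(g), len(g)), s2_u) + np.diag(s2_c[cidx[g]])
            L = np.linalg.cholesky(V)
            logdet += 2 * np.sum(np.log(np.diag(L)))
            Xi = np.linalg.solve(L, X[g])
            yi = np.linalg.solve(L, y[g])
            XtVX += Xi.T @ Xi
            XtVy += Xi.T @ yi
            quad_parts.append((Xi, yi))
        beta = np.linalg.solve(XtVX, XtVy)
        rss = sum(float((yi - Xi @ beta) @ (yi - Xi @ beta)) for Xi, yi in quad_parts)
        n = len(y)
        nll = 0.5 * (n * np.log(2 * np.pi) + logdet + rss)
        return nll, beta, XtVX

    def nll_only(theta):
        try:
            nll, _, XtVX = gls(theta)
            if method == "reml":
                sign, logdet = np.linalg.slogdet(XtVX)
                if sign <= 0:
                    return 1e12
                nll += 0.5 * logdet
            return nll
        except np.linalg.LinAlgError:
            return 1e12

    if np.ptp(y) < 1e-10 * (1.0 + abs(float(np.mean(y)))):
        # degenerate data: nothing to explain, report flat zero effects
        names_eff = [n for n in names if n != "intercept"]
        return LMMResult(
            fixed_effects={n: (float(np.mean(y)) if n == "intercept" else 0.0) for n in names},
            f_stats={n: 0.0 for n in names_eff},
            df_num={n: 1.0 for n in names_eff},
            df_den={n: float(len(y) - len(names)) for n in names_eff},
            p_values={n: 1.0 for n in names_eff},
            subject_var=0.0,
            residual_vars={c: 0.0 for c in conditions},
            loglik=float("nan"),
            converged=False,
        )

    theta0 = np.log(np.full(1 + n_res, max(y.var() / 2, 1e-6)))
    res = optimize.minimize(nll_only, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    converged = bool(res.success)
    theta = res.x
    _, beta, XtVX = gls(theta)
    cov_beta = np.linalg.inv(XtVX)

    # ML covariance of variance parameters from the numerical Hessian
    def num_hessian(f, x, h=1e-4):
        k = len(x)
        H = np.zeros((k, k))
        f0 = f(x)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h
                ej = np.zeros(k); ej[j] = h
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei) - f(x + ej) + f0
                ) / h**2
        return H

    H = num_hessian(nll_only, theta)
    try:
        theta_cov = np.linalg.inv(H)
        if not np.all(np.isfinite(theta_cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        theta_cov = np.diag(np.full(len(theta), 1e6))
        converged = False

    s2_u, s2_c = unpack(theta)
    fixed = dict(zip(names, beta))
    f_stats, p_values, df_num, df_den = {}, {}, {}, {}

    def cvar(theta_):
        _, _, XtVX_ = gls(theta_)
        return np.linalg.inv(XtVX_)

    for k, name in enumerate(names):
        if name == "intercept":
            continue
        c = np.zeros(len(names)); c[k] = 1.0
        v = float(c @ cov_beta @ c)
        F = float(beta[k] ** 2 / v) if v > 0 else 0.0
        # Satterthwaite: nu = 2 v^2 / Var(v), gradient by central differences
        grad = np.zeros(len(theta))
        h = 1e-4
        for j in range(len(theta)):
            e = np.zeros(len(theta)); e[j] = h
            vp = float(c @ cvar(theta + e) @ c)
            vm = float(c @ cvar(theta - e) @ c)
            grad[j] = (vp - vm) / (2 * h)
        var_v = float(grad @ theta_cov @ grad)
        if var_v > 0:
            nu = 2 * v**2 / var_v
        else:
            nu = float(len(y) - len(names))
        nu = max(nu, 1.0)
        f_stats[name] = F
        df_num[name] = 1.0
        df_den[name] = nu
        p_values[name] = float(stats.f.sf(F, 1, nu))

    return LMMResult(
        fixed_effects=fixed,
        f_stats=f_stats,
        df_num=df_num,
        df_den=df_den,
        p_values=p_values,
        subject_var=float(s2_u),
        residual_vars={c: float(s2_c[i]) for c, i in cond_index.items()},
        loglik=float(-res.fun),
        converged=converged,
    )
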