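"""EEG-informed fMRI general linear model and cluster inference.

First level: event regressors (four feedback conditions, stimulus, motor
response, anticipation, account balance) convolved with the canonical
double-gamma HRF, plus one parametric modulator per condition carrying
the single-trial oscillatory power (mean-centered within block and
condition so it shares no variance with its onset regressor), six motion
nuisance columns and per-block intercepts. Voxelwise least squares with
optional AR(1) prewhitening.

Second level: the within-subject valence/magnitude factorial with subject
as a random effect, implemented as a partitioned-error contrast — each
single-df contrast is computed per subject and tested across subjects,
which for two conditions reduces exactly to a paired t-test.

Cluster inference: supra-threshold voxels (26-connectivity) with an
extent threshold; cluster-level p-values from a sign-flip permutation
null of the maximum cluster size, Benjamini–Hochberg corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import CONDITIONS

SECOND_LEVEL_CONTRASTS = {
    "gain_gt_loss": {"large_gain": 0.5, "small_gain": 0.5, "large_loss": -0.5, "small_loss": -0.5},
    "loss_gt_gain": {"large_gain": -0.5, "small_gain": -0.5, "large_loss": 0.5, "small_loss": 0.5},
    "large_gt_small": {"large_gain": 0.5, "large_loss": 0.5, "small_gain": -0.5, "small_loss": -0.5},
    "small_gt_large": {"large_gain": -0.5, "large_loss": -0.5, "small_gain": 0.5, "small_loss": 0.5},
}


class NullRegressorError(ValueError):
    """A condition never occurs, leaving an all-zero design column."""


class RankDeficientError(ValueError):
    """The design matrix is not of full column rank."""


# ---------------------------------------------------------------------------
# canonical HRF
# ---------------------------------------------------------------------------


@dataclass
class HRFKernel:
    values: np.ndarray
    dt: float  # microtime resolution in seconds

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt


def canonical_hrf(tr: float, oversampling: int = 16, duration: float = 32.0) -> HRFKernel:
    """Canonical double-gamma HRF sampled at tr/oversampling.

    Peak delay 6 s, undershoot delay 16 s, both dispersions 1 s,
    peak-to-undershoot ratio 6, 32 s support; peak-normalized. The
    response is exactly 0 at t = 0 (gamma shapes > 1).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    dt = tr / oversampling
    t = np.arange(0, duration, dt)
    h = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(t, a=16.0, scale=1.0) / 6.0
    h /= h.max()
    return HRFKernel(values=h, dt=dt)


def sample_regressor(
    onsets: np.ndarray,
    weights: np.ndarray,
    frame_times: np.ndarray,
    tr: float,
    oversampling: int = 16,
) -> np.ndarray:
    """HRF-convolved weighted impulse train evaluated at frame times.

    Events are binned on a microtime grid (tr/oversampling), convolved
    with the canonical HRF and linearly interpolated at the frame times.
    """
    onsets = np.asarray(onsets, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(onsets) == 0:
        return np.zeros(len(frame_times))
    hrf = canonical_hrf(tr, oversampling)
    dt = hrf.dt
    t_end = max(frame_times.max(), onsets.max()) + 33.0
    n_hi = int(np.ceil(t_end / dt)) + 1
    train = np.zeros(n_hi)
    idx = np.round(onsets / dt).astype(int)
    np.add.at(train, idx, weights)
    conv = np.convolve(train, hrf.values)[:n_hi]
    return np.interp(frame_times, np.arange(n_hi) * dt, conv)


# ---------------------------------------------------------------------------
# modulators and design
# ---------------------------------------------------------------------------


def orthogonalize_modulators(
    peaks: pd.DataFrame, value_col: str = "peak_power"
) -> pd.DataFrame:
    """Mean-center single-trial power within each block x condition cell.

    The centered weights are orthogonal (zero-sum) to the corresponding
    onset regressor within every cell by construction; a cell with a
    single trial yields weight 0.
    """
    out = peaks.copy()
    cell_mean = out.groupby(["block", "condition"])[value_col].transform("mean")
    out["modulator_weight"] = out[value_col] - cell_mean
    return out


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # frames x columns
    columns: list[str]
    frame_times: np.ndarray  # seconds on the per-block clock, concatenated
    blocks: np.ndarray  # block index per frame

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(name)]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def build_first_level_design(
    trials: pd.DataFrame,
    weights: pd.DataFrame | None,
    n_scans: int,
    tr: float,
    motion: dict[int, np.ndarray] | None = None,
    discard: int = 5,
    modulator_col: str = "modulator_weight",
    oversampling: int = 16,
) -> DesignMatrix:
    """First-level design for one subject, blocks concatenated.

    Per block: the four condition onset regressors, stimulus/motor/
    anticipation/balance regressors (all impulse events convolved with
    the canonical HRF), one parametric modulator per condition using the
    centered ``weights``, six motion columns if provided, and a per-block
    intercept. The first ``discard`` volumes of each block are dropped,
    so frame times start at ``discard * tr``.
    """
    if n_scans <= discard:
        raise ValueError(f"n_scans={n_scans} must exceed discard={discard}")
    blocks = sorted(trials["block"].unique())
    for cond in CONDITIONS:
        if not (trials["condition"] == cond).any():
            raise NullRegressorError(
                f"condition {cond!r} never occurs: null regressor in the design"
            )

    frame_times_block = (discard + np.arange(n_scans - discard)) * tr
    n_frames = len(frame_times_block)

    event_cols = [
        ("stimulus", "trial_onset"),
        ("response", "response_onset"),
        ("anticipation", "bold_onset"),
        ("balance", "balance_onset"),
    ]
    col_names = (
        list(CONDITIONS)
        + [name for name, _ in event_cols]
        + [f"mod_{c}" for c in CONDITIONS]
        + ([f"motion_{i}" for i in range(6)] if motion is not None else [])
        + [f"block_{b}_intercept" for b in blocks]
    )
    X = np.zeros((n_frames * len(blocks), len(col_names)))
    frame_times = np.concatenate([frame_times_block] * len(blocks))
    block_of_frame = np.repeat(blocks, n_frames)

    w = None
    if weights is not None:
        w = weights.set_index(["block", "trial"])[modulator_col]

    for bi, b in enumerate(blocks):
        rows = trials[trials["block"] == b]
        sl = slice(bi * n_frames, (bi + 1) * n_frames)
        for cond in CONDITIONS:
            sel = rows[rows["condition"] == cond]
            if len(sel) == 0:
                continue
            ci = col_names.index(cond)
            X[sl, ci] = sample_regressor(
                sel["feedback_onset"].to_numpy(), np.ones(len(sel)),
                frame_times_block, tr, oversampling,
            )
            if w is not None:
                keys = list(zip(sel["block"], sel["trial"]))
                have = [k in w.index for k in keys]
                if any(have):
                    ons = sel["feedback_onset"].to_numpy()[have]
                    ww = np.array([w.loc[k] for k, h in zip(keys, have) if h], dtype=float)
                    mi = col_names.index(f"mod_{cond}")
                    X[sl, mi] = sample_regressor(ons, ww, frame_times_block, tr, oversampling)
        for name, onset_col in event_cols:
            ci = col_names.index(name)
            X[sl, ci] = sample_regressor(
                rows[onset_col].to_numpy(), np.ones(len(rows)),
                frame_times_block, tr, oversampling,
            )
        if motion is not None:
            m = np.asarray(motion[b], dtype=float)[discard:]
            for i in range(6):
                X[sl, col_names.index(f"motion_{i}")] = m[:, i]
        X[sl, col_names.index(f"block_{b}_intercept")] = 1.0

    if weights is None:
        keep = [i for i, c in enumerate(col_names) if not c.startswith("mod_")]
        X = X[:, keep]
        col_names = [col_names[i] for i in keep]
    else:
        # a modulator that is identically zero (every cell had <= 1 trial)
        # carries no information and would make the design rank-deficient
        keep = [
            i for i, c in enumerate(col_names)
            if not (c.startswith("mod_") and not np.any(X[:, i]))
        ]
        X = X[:, keep]
        col_names = [col_names[i] for i in keep]

    return DesignMatrix(
        matrix=X, columns=col_names, frame_times=frame_times, blocks=block_of_frame
    )


# ---------------------------------------------------------------------------
# first-level fit
# ---------------------------------------------------------------------------


@dataclass
class GLMResult:
    betas: np.ndarray  # voxels x columns
    columns: list[str]
    residual_var: np.ndarray
    df: float
    xtx_inv: np.ndarray
    ar_coefficient: np.ndarray | None = None
    shape: tuple | None = None
    mask: np.ndarray | None = None

    def contrast(self, weights: dict[str, float] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Contrast estimate and t map for a named-column weight vector."""
        if isinstance(weights, dict):
            c = np.zeros(len(self.columns))
            for name, wv in weights.items():
                c[self.columns.index(name)] = wv
        else:
            c = np.asarray(weights, dtype=float)
        est = self.betas @ c
        var = self.residual_var * float(c @ self.xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, est / np.sqrt(var), 0.0)
        return est, t

    def beta_map(self, name: str) -> np.ndarray:
        b = self.betas[:, self.columns.index(name)]
        return b.reshape(self.shape) if self.shape else b


def smooth_volumes(data: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing of a 4D (x, y, z, t) array, FWHM in mm."""
    sigma_vox = fwhm_mm / voxel_size_mm / (2 * np.sqrt(2 * np.log(2)))
    return ndimage.gaussian_filter(data, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0))


def fit_first_level_glm(
    data: np.ndarray,
    design: DesignMatrix,
    prewhiten: bool = False,
    smoothing_fwhm_mm: float = 0.0,
    voxel_size_mm: float = 3.0,
    discard: int = 5,
) -> GLMResult:
    """Voxelwise least squares on 4D data (x, y, z, t) or (voxels, t).

    ``data`` must contain ALL acquired frames per block (concatenated on
    the last axis); the first ``discard`` frames of each block are
    dropped here to match the design. Optional isotropic Gaussian
    smoothing is applied to the volumes first. With ``prewhiten`` a
    two-pass AR(1) scheme is used: estimate the pooled lag-1 residual
    autocorrelation, quasi-difference data and design within blocks,
    refit.
    """
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, design.columns)
        raise RankDeficientError(f"design rank {rank} < {X.shape[1]}; collinear: {bad}")

    if data.ndim == 4:
        shape = data.shape[:3]
        if smoothing_fwhm_mm > 0:
            data = smooth_volumes(data, smoothing_fwhm_mm, voxel_size_mm)
        Y = data.reshape(-1, data.shape[3])
    else:
        shape = None
        Y = data

    # drop the discarded frames block-wise
    blocks = np.unique(design.blocks)
    n_total = Y.shape[1]
    frames_per_block = n_total // len(blocks)
    keep = np.concatenate(
        [b * frames_per_block + np.arange(discard, frames_per_block) for b in range(len(blocks))]
    )
    if len(keep) != X.shape[0]:
        raise ValueError(
            f"data frames after discard ({len(keep)}) do not match design rows ({X.shape[0]})"
        )
    Y = Y[:, keep]

    betas, resvar, xtx_inv, df = _ols(Y, X)
    ar = None
    if prewhiten:
        resid = Y - betas @ X.T
        num = np.sum(resid[:, 1:] * resid[:, :-1], axis=1)
        den = np.sum(resid**2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ar = np.where(den > 0, num / den, 0.0)
        phi = float(np.median(ar))
        Yw = Y.copy()
        Xw = X.copy()
        block_ids = design.blocks
        for b in blocks:
            sel = np.flatnonzero(block_ids == b)
            Yw[:, sel[1:]] = Y[:, sel[1:]] - phi * Y[:, sel[:-1]]
            Yw[:, sel[0]] = Y[:, sel[0]] * np.sqrt(1 - phi**2)
            Xw[sel[1:]] = X[sel[1:]] - phi * X[sel[:-1]]
            Xw[sel[0]] = X[sel[0]] * np.sqrt(1 - phi**2)
        betas, resvar, xtx_inv, df = _ols(Yw, Xw)

    return GLMResult(
        betas=betas,
        columns=design.columns,
        residual_var=resvar,
        df=df,
        xtx_inv=xtx_inv,
        ar_coefficient=ar,
        shape=shape,
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(d < tol)]


def _ols(Y: np.ndarray, X: np.ndarray):
    pinv = np.linalg.pinv(X)
    betas = Y @ pinv.T
    resid = Y - betas @ X.T
    df = X.shape[0] - np.linalg.matrix_rank(X)
    resvar = np.sum(resid**2, axis=1) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return betas, resvar, xtx_inv, df


# ---------------------------------------------------------------------------
# second level
# ---------------------------------------------------------------------------


@dataclass
class SecondLevelResult:
    """Group map for one single-df within-subject contrast."""

    contrast_name: str
    subject_scores: np.ndarray  # subjects x voxels, per-subject contrast values
    t_map: np.ndarray  # flat, voxels
    df: int
    no_variance: np.ndarray  # flag where the error term vanished

    @property
    def z_map(self) -> np.ndarray:
        p = stats.t.sf(self.t_map, self.df)
        p = np.clip(p, 1e-300, 1 - 1e-16)
        return stats.norm.isf(p)


def second_level_contrast(
    condition_maps: dict[int, dict[str, np.ndarray]],
    contrast: str | dict[str, float],
) -> SecondLevelResult:
    """Partitioned-error within-subject factorial contrast.

    ``condition_maps[subject][condition]`` are first-level contrast
    (beta) images, one per condition per subject — all four required.
    The contrast is evaluated per subject and the resulting score maps
    tested against zero across subjects (the partitioned error of the
    repeated-measures factorial; identical to a paired t-test for a
    two-condition contrast). Voxels with zero between-subject score
    variance are flagged instead of producing infinities.
    """
    if isinstance(contrast, str):
        name = contrast
        cvec = SECOND_LEVEL_CONTRASTS[contrast]
    else:
        name = "custom"
        cvec = contrast
    subjects = sorted(condition_maps)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    scores = []
    for s in subjects:
        maps = condition_maps[s]
        for cond in cvec:
            if cond not in maps:
                raise ValueError(f"missing condition image {cond!r} for subject {s}")
        score = sum(wv * np.asarray(maps[cond], dtype=float).reshape(-1)
                    for cond, wv in cvec.items())
        scores.append(score)
    S = np.stack(scores)
    n = S.shape[0]
    mean = S.mean(axis=0)
    sd = S.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    no_var = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(~no_var, mean / np.where(no_var, 1.0, se), 0.0)
    return SecondLevelResult(
        contrast_name=name, subject_scores=S, t_map=t, df=n - 1, no_variance=no_var
    )


# ---------------------------------------------------------------------------
# cluster inference
# ---------------------------------------------------------------------------

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


def label_clusters(binary_map: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components of a 3D binary map with 26-connectivity."""
    return ndimage.label(binary_map, structure=CONNECTIVITY_26)


def bh_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``m`` is the family size; it may exceed the number of supplied
    p-values when the family contains untested/unreported members.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of tests {k}")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.minimum.accumulate((m / np.arange(k, 0, -1)) * ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(k)
    out[order] = adj
    return out


def cluster_inference(
    result: SecondLevelResult,
    shape: tuple[int, int, int],
    voxel_p: float = 0.001,
    extent_k: int = 0,
    n_permutations: int = 1000,
    seed: int = 0,
    affine: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cluster table with sign-flip permutation p-values and BH correction.

    Voxels with one-sided p < ``voxel_p`` (t distribution, group df) are
    labeled with 26-connectivity; clusters below ``extent_k`` voxels are
    dropped. The cluster-level null is the maximum supra-threshold
    cluster size under random sign flips of the per-subject score maps
    (exchangeability under the null of no effect); surviving clusters'
    permutation p-values are BH-adjusted.
    """
    t_thresh = stats.t.isf(voxel_p, result.df)
    t3 = result.t_map.reshape(shape)
    supra = t3 > t_thresh
    if mask is not None:
        supra &= mask
    labels, n_lab = label_clusters(supra)
    rows = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        size = int(sel.sum())
        if size < extent_k:
            continue
        flat = np.flatnonzero(sel.reshape(-1))
        peak_flat = flat[np.argmax(result.t_map[flat])]
        peak_vox = np.unravel_index(peak_flat, shape)
        peak_mm = (
            (affine @ np.array([*peak_vox, 1.0]))[:3] if affine is not None else np.array(peak_vox, float)
        )
        z = SecondLevelResult(
            result.contrast_name, result.subject_scores, result.t_map, result.df, result.no_variance
        ).z_map[peak_flat]
        rows.append(
            {
                "label": lab,
                "size": size,
                "peak_x": int(peak_vox[0]),
                "peak_y": int(peak_vox[1]),
                "peak_z": int(peak_vox[2]),
                "peak_mm_x": float(peak_mm[0]),
                "peak_mm_y": float(peak_mm[1]),
                "peak_mm_z": float(peak_mm[2]),
                "peak_t": float(result.t_map[peak_flat]),
                "peak_z_stat": float(z),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "size", "peak_x", "peak_y", "peak_z",
            "peak_mm_x", "peak_mm_y", "peak_mm_z", "peak_t", "peak_z_stat",
        ],
    )
    if table.empty:
        table["cluster_p"] = pd.Series(dtype=float)
        table["cluster_q"] = pd.Series(dtype=float)
        return table

    rng = np.random.default_rng(seed)
    S = result.subject_scores
    n_sub = S.shape[0]
    max_sizes = np.zeros(n_permutations, dtype=int)
    flat_mask = mask.reshape(-1) if mask is not None else None
    for i in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        Sp = S * signs[:, None]
        mean = Sp.mean(axis=0)
        sd = Sp.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tp = np.where(sd > 0, mean / (sd / np.sqrt(n_sub)), 0.0)
        if flat_mask is not None:
            tp = np.where(flat_mask, tp, 0.0)
        lab_p, n_p = label_clusters((tp > t_thresh).reshape(shape))
        if n_p:
            sizes = ndimage.sum_labels(np.ones(shape), lab_p, index=np.arange(1, n_p + 1))
            max_sizes[i] = int(sizes.max())
    pvals = np.array(
        [(1 + np.sum(max_sizes >= s)) / (1 + n_permutations) for s in table["size"]]
    )
    table["cluster_p"] = pvals
    table["cluster_q"] = bh_adjust(pvals)
    return table.sort_values("size", ascending=False).reset_index(drop=True)
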