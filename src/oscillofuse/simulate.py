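"""Synthetic simultaneous-EEG/fMRI generator for the two-choice gambling task.

The generator produces three linked artifacts with a shared ground truth:

* a trial table for the 2-choice gambling paradigm (gain/loss feedback on
  a chosen 25- or 5-point stake),
* continuous multi-channel EEG in which every feedback event elicits a
  Gaussian-windowed theta burst (larger after losses) and a high-beta
  burst (larger after gains), on a 1/f background, optionally corrupted
  by MR-gradient and cardioballistic artifacts,
* per-block 4D BOLD volumes in which designated voxel clusters respond to
  condition onsets and, additionally, carry a linear coupling to the
  mean-centered single-trial oscillatory power of the very same bursts.

Because EEG bursts and BOLD coupling draw from one set of per-trial
amplitudes (stored in :class:`GroundTruth`), the downstream fusion
analysis has a known answer to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    CONDITIONS,
    InvalidConfigError,
    SimConfig,
    condition_label,
)
from .preprocess import EEGRecording
from .glm import canonical_hrf

TRIAL_COLUMNS = [
    "subject",
    "block",
    "trial",
    "trial_onset",
    "bold_onset",
    "feedback_onset",
    "balance_onset",
    "response_onset",
    "magnitude",
    "valence",
    "condition",
    "response_made",
]

# burst scalp topography; zero-sum so a common-average re-reference
# leaves the burst waveform at Fz untouched
EEG_CHANNELS = ("Fz", "F3", "F4", "Cz", "C3", "C4", "Pz", "Oz")
BURST_TOPOGRAPHY = {
    "Fz": 1.0,
    "F3": 0.6,
    "F4": 0.6,
    "Cz": 0.2,
    "C3": -0.3,
    "C4": -0.3,
    "Pz": -0.8,
    "Oz": -1.0,
}


@dataclass
class GroundTruth:
    """Latent quantities the analysis pipeline tries to estimate.

    ``theta_amp``/``beta_amp`` are per-trial burst amplitudes (microvolts,
    aligned with the trial table); ``theta_power``/``beta_power`` are their
    squares, the quantity the BOLD forward model couples to. Maps are 3D
    arrays on the simulation grid; voxels outside the designated clusters
    have coupling exactly zero.
    """

    trials: pd.DataFrame
    theta_amp: np.ndarray
    beta_amp: np.ndarray
    condition_beta_maps: dict[str, np.ndarray]
    gamma_theta_map: np.ndarray
    gamma_beta_map: np.ndarray
    active_mask: np.ndarray
    theta_coupled_mask: np.ndarray
    beta_coupled_mask: np.ndarray
    affine: np.ndarray
    subject_coupling_scale: np.ndarray | None = None  # per-subject multiplier
    gradient_template: np.ndarray | None = None
    bcg_templates: dict[str, np.ndarray] = field(default_factory=dict)
    pulse_times: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    @property
    def theta_power(self) -> np.ndarray:
        return self.theta_amp**2

    @property
    def beta_power(self) -> np.ndarray:
        return self.beta_amp**2


def simulate_task(cfg: SimConfig) -> pd.DataFrame:
    """Draw the trial table of the gambling task.

    Valence is a fair coin (gains and losses equiprobable, as instructed
    to the participants); the chosen magnitude follows
    ``cfg.magnitude_policy``. Onsets are on the within-block scanner
    clock: the choice stimulus opens the trial, the selection is shown in
    bold at +2 s, feedback arrives at +4 s and the account balance at
    +6 s. Trials repeat every ``cfg.trial_pitch`` seconds plus optional
    uniform jitter.
    """
    rng = cfg.rng("task")
    rows = []
    for subject in range(cfg.n_subjects):
        for block in range(cfg.n_blocks):
            onset = cfg.block_lead_in
            for trial in range(cfg.trials_per_block):
                jitter = rng.uniform(0.0, cfg.onset_jitter) if cfg.onset_jitter > 0 else 0.0
                t0 = onset + jitter
                valence = "gain" if rng.random() < 0.5 else "loss"
                if cfg.magnitude_policy == "fair-coin":
                    magnitude = 25 if rng.random() < 0.5 else 5
                elif cfg.magnitude_policy == "always-25":
                    magnitude = 25
                else:
                    magnitude = 5
                rt = rng.uniform(0.3, 0.9)  # button press inside the 1 s window
                rows.append(
                    {
                        "subject": subject,
                        "block": block,
                        "trial": trial,
                        "trial_onset": t0,
                        "bold_onset": t0 + 2.0,
                        "feedback_onset": t0 + 4.0,
                        "balance_onset": t0 + 6.0,
                        "response_onset": t0 + rt,
                        "magnitude": magnitude,
                        "valence": valence,
                        "condition": condition_label(valence, magnitude),
                        "response_made": True,
                    }
                )
                onset += cfg.trial_pitch
    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    if table.empty:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return table


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Normal draws truncated below at 0 by redrawing (amplitudes are physical)."""
    mean = np.asarray(mean, dtype=float)
    if sd == 0:
        return mean.copy()
    out = rng.normal(mean, sd)
    bad = out < 0
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean[bad], sd)
        bad = out < 0
    return np.clip(out, 0.0, None)


def draw_burst_amplitudes(trials: pd.DataFrame, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    loss = (trials["valence"] == "loss").to_numpy()
    theta_mean = cfg.theta_amp_base + cfg.valence_effect_theta * loss
    beta_mean = cfg.beta_amp_base + cfg.valence_effect_beta * (~loss)
    rng = cfg.rng("amplitudes")
    theta = _truncated_normal(rng, theta_mean, cfg.trial_amp_sd)
    beta = _truncated_normal(rng, beta_mean, cfg.trial_amp_sd)
    return theta, beta


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, rms: float) -> np.ndarray:
    """1/f ("pink") noise via spectral shaping of white Gaussian noise."""
    if rms == 0 or n_samples == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    shaped *= rms / np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    return shaped


def _default_masks(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three disjoint cuboid clusters scaled to the grid."""
    nx, ny, nz = shape
    active = np.zeros(shape, dtype=bool)
    theta = np.zeros(shape, dtype=bool)
    beta = np.zeros(shape, dtype=bool)
    lo = [max(1, n // 6) for n in shape]
    hi = [max(2, n // 3 + 1) for n in shape]
    up_lo = [max(hi[i], n - n // 3) for i, n in enumerate(shape)]
    up_hi = [n - 1 for n in shape]
    active[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    theta[up_lo[0]:up_hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    beta[lo[0]:hi[0], up_lo[1]:up_hi[1], up_lo[2]:up_hi[2]] = True
    return active, theta, beta


def build_ground_truth(trials: pd.DataFrame, cfg: SimConfig) -> GroundTruth:
    """Draw per-trial burst amplitudes and lay out effect maps on the grid."""
    theta_amp, beta_amp = draw_burst_amplitudes(trials, cfg)
    active, theta_mask, beta_mask = _default_masks(cfg.grid_shape)
    beta_maps = {}
    for cond in CONDITIONS:
        m = np.zeros(cfg.grid_shape)
        value = cfg.condition_betas.get(cond, 0.0)
        m[active | theta_mask | beta_mask] = value
        beta_maps[cond] = m
    g_theta = np.zeros(cfg.grid_shape)
    g_theta[theta_mask] = cfg.coupling_gamma_theta
    g_beta = np.zeros(cfg.grid_shape)
    g_beta[beta_mask] = cfg.coupling_gamma_beta
    scale_rng = cfg.rng("subject-coupling")
    scale = np.clip(
        scale_rng.normal(1.0, cfg.subject_coupling_sd, cfg.n_subjects), 0.1, None
    )
    return GroundTruth(
        subject_coupling_scale=scale,
        trials=trials,
        theta_amp=theta_amp,
        beta_amp=beta_amp,
        condition_beta_maps=beta_maps,
        gamma_theta_map=g_theta,
        gamma_beta_map=g_beta,
        active_mask=active,
        theta_coupled_mask=theta_mask,
        beta_coupled_mask=beta_mask,
        affine=cfg.affine,
    )


def simulate_eeg(
    trials: pd.DataFrame,
    cfg: SimConfig,
    ground_truth: GroundTruth | None = None,
    subject: int = 0,
) -> tuple[EEGRecording, GroundTruth]:
    """Synthesize one subject's continuous EEG across all blocks.

    Blocks are laid end-to-end on a single recording clock; every task
    event gets a marker. Each feedback event adds Gaussian-windowed
    sinusoidal bursts at the theta and high-beta frequencies whose
    amplitudes come from the shared ground truth. Optional artifacts: an
    exactly TR-periodic gradient template (with per-volume markers) and a
    pulse-locked cardioballistic template following each synthetic ECG
    beat with timing jitter.
    """
    sub = trials[trials["subject"] == subject].reset_index(drop=True)
    if sub.empty:
        raise InvalidConfigError(f"no trials for subject {subject}")
    if cfg.burst_center_s + 5 * cfg.burst_sigma_s > cfg.trial_pitch:
        raise InvalidConfigError("burst window exceeds the inter-trial gap")
    if ground_truth is None:
        ground_truth = build_ground_truth(trials, cfg)

    sf = cfg.eeg_sfreq
    block_dur = cfg.block_duration
    n_block_samples = int(round(block_dur * sf))
    n_samples = cfg.n_blocks * n_block_samples
    channels = list(EEG_CHANNELS) + ["ECG"]
    ch_types = ["eeg"] * len(EEG_CHANNELS) + ["ecg"]

    rng = cfg.rng(f"eeg-{subject}")
    data = _pink_noise(rng, len(EEG_CHANNELS), n_samples, cfg.noise.eeg_pink_rms)
    data = np.vstack([data, np.zeros(n_samples)])  # ECG row
    time = np.arange(n_samples) / sf

    events: list[tuple[int, str]] = []
    sub_index = sub.index.to_numpy()
    mask = (trials["subject"] == subject).to_numpy()
    theta_amp = ground_truth.theta_amp[mask]
    beta_amp = ground_truth.beta_amp[mask]

    topo = np.array([BURST_TOPOGRAPHY[ch] for ch in EEG_CHANNELS])
    for i, row in sub.iterrows():
        base = row["block"] * block_dur
        for label, col in (
            ("stimulus", "trial_onset"),
            ("response", "response_onset"),
            ("bold", "bold_onset"),
            ("feedback", "feedback_onset"),
            ("balance", "balance_onset"),
        ):
            s = int(round((base + row[col]) * sf))
            if 0 <= s < n_samples:
                tag = label if label != "feedback" else f"feedback/{row['condition']}"
                events.append((s, tag))
        t_fb = base + row["feedback_onset"] + cfg.burst_center_s
        lo = int(max(0, (t_fb - 5 * cfg.burst_sigma_s) * sf))
        hi = int(min(n_samples, (t_fb + 5 * cfg.burst_sigma_s) * sf))
        tt = time[lo:hi] - t_fb
        env = np.exp(-(tt**2) / (2 * cfg.burst_sigma_s**2))
        burst = theta_amp[i] * env * np.cos(2 * np.pi * cfg.theta_freq * tt) + beta_amp[
            i
        ] * env * np.cos(2 * np.pi * cfg.beta_freq * tt)
        data[: len(EEG_CHANNELS), lo:hi] += topo[:, None] * burst[None, :]

    # synthetic ECG: sharp biphasic beats at the configured heart rate
    beat_period = 60.0 / cfg.artifact.heart_rate_bpm
    ecg_rng = cfg.rng(f"ecg-{subject}")
    pulse_times_all = {}
    for block in range(cfg.n_blocks):
        t = cfg.block_lead_in * 0.2
        beats = []
        while t < block_dur - 1.0:
            beats.append(block * block_dur + t)
            t += beat_period * (1 + 0.02 * ecg_rng.standard_normal())
        beats = np.asarray(beats)
        pulse_times_all[(subject, block)] = beats
        for tb in beats:
            s0 = int(round(tb * sf))
            w = int(0.02 * sf) or 1
            seg = np.arange(max(0, s0 - 3 * w), min(n_samples, s0 + 3 * w))
            shape = np.exp(-((seg - s0) ** 2) / (2 * w**2))
            data[-1, seg] += 800.0 * shape - 150.0 * np.roll(shape, w)[: len(seg)]

    bcg_templates: dict[str, np.ndarray] = {}
    if cfg.artifact.bcg:
        tmpl_len = int(0.7 * sf)
        tmpl_rng = cfg.rng(f"bcg-template-{subject}")
        tt = np.arange(tmpl_len) / sf
        base_shape = np.sin(2 * np.pi * tt / 0.7) * np.exp(-((tt - 0.2) ** 2) / (2 * 0.12**2))
        for ci, ch in enumerate(EEG_CHANNELS):
            scale = cfg.artifact.bcg_amp * (0.6 + 0.8 * tmpl_rng.random())
            bcg_templates[ch] = scale * base_shape
        jitter_sd = cfg.artifact.bcg_jitter_ms / 1000.0
        for beats in pulse_times_all.values():
            for tb in beats:
                t_on = tb + 0.21 + jitter_sd * tmpl_rng.standard_normal()
                s0 = int(round(t_on * sf))
                if s0 < 0 or s0 + tmpl_len > n_samples:
                    continue
                for ci, ch in enumerate(EEG_CHANNELS):
                    data[ci, s0 : s0 + tmpl_len] += bcg_templates[ch]

    gradient_template = None
    if cfg.artifact.gradient:
        n_tr = int(round(cfg.tr * sf))
        grad_rng = cfg.rng("gradient-template")
        # deterministic sum of sharp harmonics of the slice frequency
        tt = np.arange(n_tr) / sf
        gradient_template = np.zeros(n_tr)
        for k, f in enumerate((12.5, 25.0, 37.5, 62.5)):
            gradient_template += np.cos(2 * np.pi * f * tt + grad_rng.uniform(0, 2 * np.pi)) / (
                k + 1
            )
        gradient_template *= cfg.artifact.gradient_amp / np.max(np.abs(gradient_template))
        for v in range(n_samples // n_tr):
            s0 = v * n_tr
            data[: len(EEG_CHANNELS), s0 : s0 + n_tr] += gradient_template
            events.append((s0, "volume"))

    ground_truth.gradient_template = gradient_template
    ground_truth.bcg_templates = bcg_templates
    ground_truth.pulse_times.update(pulse_times_all)

    events.sort(key=lambda e: e[0])
    rec = EEGRecording(
        data=data,
        sfreq=sf,
        ch_names=channels,
        ch_types=ch_types,
        events=events,
        reference="original",
    )
    return rec, ground_truth


def _convolve_train(
    onsets: np.ndarray,
    weights: np.ndarray,
    frame_times: np.ndarray,
    tr: float,
    oversampling: int = 16,
) -> np.ndarray:
    """HRF-convolved impulse train evaluated at frame times (one block)."""
    from .glm import sample_regressor

    return sample_regressor(onsets, weights, frame_times, tr, oversampling)


def simulate_bold(
    trials: pd.DataFrame,
    ground_truth: GroundTruth,
    cfg: SimConfig,
    subject: int = 0,
) -> list[np.ndarray]:
    """Forward-model 4D BOLD data for one subject, one array per block.

    Voxel signal = sum over conditions of beta_c * (HRF * onset train)
    plus gamma_theta/gamma_beta times HRF-convolved trains weighted by
    the *mean-centered* (within block x condition) true single-trial
    power, plus a per-voxel linear drift and AR(1) Gaussian noise. The
    first volumes are NOT discarded here — that is the pipeline's job.
    """
    sub = trials[trials["subject"] == subject]
    if sub.empty:
        raise InvalidConfigError(f"no trials for subject {subject}")
    last_event = sub["balance_onset"].max()
    if cfg.block_duration < last_event + cfg.trial_pitch / 2:
        raise InvalidConfigError(
            f"block of {cfg.block_duration:.0f} s too short for task ending at {last_event:.0f} s"
        )
    mask = (trials["subject"] == subject).to_numpy()
    theta_pow = ground_truth.theta_power[mask]
    beta_pow = ground_truth.beta_power[mask]
    sub = sub.reset_index(drop=True)

    frame_times = np.arange(cfg.n_scans_per_block) * cfg.tr
    shape = cfg.grid_shape
    n_vox = int(np.prod(shape))
    rng = cfg.rng(f"bold-{subject}")

    blocks = []
    for block in range(cfg.n_blocks):
        in_block = (sub["block"] == block).to_numpy()
        rows = sub[in_block]
        onsets = rows["feedback_onset"].to_numpy()
        conds = rows["condition"].to_numpy()
        th = theta_pow[in_block].astype(float).copy()
        be = beta_pow[in_block].astype(float).copy()
        # center true power within block x condition (matches the
        # orthogonalization the estimation pipeline applies)
        for cond in CONDITIONS:
            sel = conds == cond
            if sel.any():
                th[sel] -= th[sel].mean()
                be[sel] -= be[sel].mean()

        signal = np.zeros((n_vox, len(frame_times)))
        flat_beta = {c: ground_truth.condition_beta_maps[c].reshape(-1) for c in CONDITIONS}
        scale = 1.0
        if ground_truth.subject_coupling_scale is not None:
            scale = float(ground_truth.subject_coupling_scale[subject])
        g_th = scale * ground_truth.gamma_theta_map.reshape(-1)
        g_be = scale * ground_truth.gamma_beta_map.reshape(-1)
        for cond in CONDITIONS:
            sel = conds == cond
            if not sel.any():
                continue
            reg = _convolve_train(onsets[sel], np.ones(sel.sum()), frame_times, cfg.tr)
            signal += np.outer(flat_beta[cond], reg)
        th_sel = np.isin(conds, cfg.coupling_theta_conditions)
        be_sel = np.isin(conds, cfg.coupling_beta_conditions)
        if np.any(g_th) and th_sel.any():
            reg = _convolve_train(onsets[th_sel], th[th_sel], frame_times, cfg.tr)
            signal += np.outer(g_th, reg)
        if np.any(g_be) and be_sel.any():
            reg = _convolve_train(onsets[be_sel], be[be_sel], frame_times, cfg.tr)
            signal += np.outer(g_be, reg)

        # drift: per-voxel random linear slope
        ramp = np.linspace(-0.5, 0.5, len(frame_times))
        if cfg.noise.drift_amp > 0:
            slopes = rng.uniform(-cfg.noise.drift_amp, cfg.noise.drift_amp, n_vox)
            signal += np.outer(slopes, ramp)
        # AR(1) noise with marginal sd = bold_sd
        if cfg.noise.bold_sd > 0:
            phi = cfg.noise.bold_ar1
            innov_sd = cfg.noise.bold_sd * np.sqrt(max(1e-12, 1 - phi**2))
            eps = rng.normal(0.0, innov_sd, (n_vox, len(frame_times)))
            eps[:, 0] = rng.normal(0.0, cfg.noise.bold_sd, n_vox)
            noise = np.empty_like(eps)
            noise[:, 0] = eps[:, 0]
            for t in range(1, eps.shape[1]):
                noise[:, t] = phi * noise[:, t - 1] + eps[:, t]
            signal += noise

        blocks.append(signal.reshape(*shape, len(frame_times)))
    return blocks


def simulate_motion(cfg: SimConfig, subject: int = 0) -> dict[int, np.ndarray]:
    """Random-walk motion-parameter nuisance columns (6 per block).

    These stand in for realignment parameters; the simulator does not
    move the head, so they carry no signal and act purely as nuisance
    regressors.
    """
    rng = cfg.rng(f"motion-{subject}")
    out = {}
    for block in range(cfg.n_blocks):
        steps = rng.normal(0.0, 0.02, (cfg.n_scans_per_block, 6))
        out[block] = np.cumsum(steps, axis=0)
    return out


def simulate_trait_scores(
    ground_truth: GroundTruth,
    cfg: SimConfig,
    rho: float = 0.6,
    subscales: tuple[str, ...] = ("attentional", "motor", "non_planning"),
    correlated_subscale: str = "non_planning",
) -> pd.DataFrame:
    """Trait questionnaire subscale scores, one correlated with coupling.

    The ``correlated_subscale`` is built to have population correlation
    ``rho`` with the subject coupling scale (the quantity the ROI summary
    estimates); the remaining subscales are independent noise. Scores are
    mapped onto a plausible questionnaire scale (mean 20, s.d. 4).
    """
    n = cfg.n_subjects
    rng = cfg.rng("traits")
    scale = ground_truth.subject_coupling_scale
    z = (scale - scale.mean()) / (scale.std() if scale.std() > 0 else 1.0)
    cols = {}
    for sub in subscales:
        noise = rng.standard_normal(n)
        if sub == correlated_subscale and abs(rho) > 0:
            latent = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * noise
        else:
            latent = noise
        cols[sub] = 20.0 + 4.0 * latent
    return pd.DataFrame(cols, index=pd.RangeIndex(n, name="subject"))


def simulate_session(cfg: SimConfig):
    """Convenience wrapper: task + ground truth + EEG + BOLD for all subjects.

    Returns ``(trials, ground_truth, eeg_by_subject, bold_by_subject)``.
    """
    trials = simulate_task(cfg)
    gt = build_ground_truth(trials, cfg)
    eeg = {}
    bold = {}
    for subject in range(cfg.n_subjects):
        eeg[subject], _ = simulate_eeg(trials, cfg, ground_truth=gt, subject=subject)
        bold[subject] = simulate_bold(trials, gt, cfg, subject=subject)
    return trials, gt, eeg, bold
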