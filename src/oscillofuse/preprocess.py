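"""Cleanup of EEG recorded inside the MR scanner.

Stages, in the order the pipeline applies them:

1. gradient-artifact removal by sliding-average template subtraction
   (baseline-corrected template per volume epoch),
2. cardioballistic-artifact removal by pulse-locked sliding-average
   template subtraction at automatically detected ECG beats,
3. zero-phase Butterworth band limiting (0.1–50 Hz), resampling to
   500 Hz and common-average re-referencing,
4. segmentation into 3 s feedback-locked epochs (−1800 … +1200 ms) with
   200 ms pre-stimulus baseline correction,
5. automatic artifact screening with four amplitude criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

TARGET_SFREQ = 500.0
EPOCH_START_MS = -1800.0
EPOCH_END_MS = 1200.0
BASELINE_MS = (-200.0, 0.0)

#: screening thresholds in microvolts
STEP_THRESHOLD = 50.0
AMPLITUDE_THRESHOLD = 95.0
RANGE_MAX = 200.0
RANGE_MIN = 0.5


class AlignmentError(RuntimeError):
    """Volume markers drift relative to the nominal TR."""


@dataclass
class EEGRecording:
    """Continuous multi-channel EEG with event markers.

    ``data`` is channels x samples in microvolts. ``events`` is a list of
    ``(sample_index, label)``. ``reference`` records whether the data are
    still in the original reference or common-average re-referenced.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    ch_types: list[str]
    events: list[tuple[int, str]]
    reference: str = "original"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        n = self.data.shape[1]
        for s, label in self.events:
            if not (0 <= s < n):
                raise ValueError(f"event {label!r} at sample {s} outside recording")

    @property
    def eeg_picks(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.ch_types) if t == "eeg"])

    def channel_index(self, name: str) -> int:
        return self.ch_names.index(name)

    def event_samples(self, label_prefix: str) -> np.ndarray:
        return np.array(
            [s for s, lab in self.events if lab == label_prefix or lab.startswith(label_prefix + "/")],
            dtype=int,
        )

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(), events=list(self.events))


@dataclass
class EpochSet:
    """Feedback-locked EEG segments with a rejection mask.

    ``data`` is trials x channels x samples; time runs from
    ``tmin_ms`` in steps of 1000/sfreq. ``metadata`` has one row per
    epoch (subject/block/trial/condition). ``rejected`` marks screened-out
    trials; ``reasons`` holds the per-trial criterion names.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    ch_types: list[str]
    tmin_ms: float
    metadata: pd.DataFrame
    rejected: np.ndarray
    reasons: list[list[str]]
    baseline_ms: tuple[float, float] = BASELINE_MS

    def __post_init__(self) -> None:
        if len(self.rejected) != self.data.shape[0]:
            raise ValueError("rejection mask length must equal trial count")

    @property
    def times_ms(self) -> np.ndarray:
        return self.tmin_ms + 1000.0 * np.arange(self.data.shape[2]) / self.sfreq

    @property
    def n_retained(self) -> int:
        return int((~self.rejected).sum())

    def retained(self) -> "EpochSet":
        keep = ~self.rejected
        return EpochSet(
            data=self.data[keep],
            sfreq=self.sfreq,
            ch_names=self.ch_names,
            ch_types=self.ch_types,
            tmin_ms=self.tmin_ms,
            metadata=self.metadata[keep].reset_index(drop=True),
            rejected=np.zeros(keep.sum(), dtype=bool),
            reasons=[[] for _ in range(int(keep.sum()))],
            baseline_ms=self.baseline_ms,
        )


def remove_gradient_artifact(
    rec: EEGRecording,
    volume_label: str = "volume",
    half_window: int = 15,
) -> EEGRecording:
    """Subtract a sliding-average MR gradient template at each volume.

    For every volume epoch the template is the mean of the surrounding
    ``2*half_window + 1`` epochs, each first corrected by its own mean
    (baseline correction); at the edges the window is one-sided/truncated.
    Event labels and counts are untouched.
    """
    vols = rec.event_samples(volume_label)
    if len(vols) < 2 * half_window + 1:
        raise ValueError(
            f"need at least {2 * half_window + 1} volume events, got {len(vols)}"
        )
    ivi = np.diff(vols)
    if ivi.max() - ivi.min() > 1:
        raise AlignmentError(
            f"inter-volume interval drifts by {ivi.max() - ivi.min()} samples"
        )
    epoch_len = int(ivi.min())
    out = rec.copy()
    picks = rec.eeg_picks
    n = rec.data.shape[1]
    starts = [s for s in vols if s + epoch_len <= n]
    # stack epochs and baseline-correct each by its own mean
    stack = np.stack([rec.data[picks, s : s + epoch_len] for s in starts])  # (V, C, L)
    stack_bc = stack - stack.mean(axis=2, keepdims=True)
    csum = np.concatenate(
        [np.zeros((1,) + stack_bc.shape[1:]), np.cumsum(stack_bc, axis=0)], axis=0
    )
    n_vols = len(starts)
    for v, s in enumerate(starts):
        lo = max(0, v - half_window)
        hi = min(n_vols, v + half_window + 1)
        template = (csum[hi] - csum[lo]) / (hi - lo)
        out.data[picks, s : s + epoch_len] -= template
    return out


def detect_pulse_peaks(
    ecg: np.ndarray, sfreq: float, min_rate_bpm: float = 40.0
) -> np.ndarray:
    """Automatic R-peak detection on the ECG channel.

    First pass: high-prominence candidate peaks seed a beat template;
    second pass: normalized cross-correlation of the ECG against that
    template, peak-picked with a refractory period set by the physiological
    maximum heart rate.
    """
    x = ecg - np.median(ecg)
    min_dist = int(sfreq * 60.0 / 180.0)  # no faster than 180 bpm
    prominence = 4 * np.median(np.abs(x)) + 0.25 * np.max(np.abs(x))
    cand, _ = sps.find_peaks(np.abs(x), distance=min_dist, prominence=prominence)
    if len(cand) == 0:
        return cand
    half = int(0.1 * sfreq)
    seeds = [c for c in cand if half <= c < len(x) - half]
    if not seeds:
        return np.asarray(cand)
    template = x[seeds[0] - half : seeds[0] + half]
    template = template - template.mean()
    denom = np.linalg.norm(template)
    if denom == 0:
        return np.asarray(cand)
    corr = sps.fftconvolve(x, template[::-1] / denom, mode="same")
    local = sps.fftconvolve(x**2, np.ones(len(template)), mode="same")
    ncc = corr / np.sqrt(np.maximum(local, 1e-12))
    peaks, _ = sps.find_peaks(ncc, distance=min_dist, height=0.6 * np.max(ncc))
    return peaks


def remove_bcg(
    rec: EEGRecording,
    ecg_channel: str = "ECG",
    half_window: int = 10,
) -> tuple[EEGRecording, dict]:
    """Pulse-locked sliding-average subtraction of the cardioballistic artifact.

    Beats are detected on the ECG channel; around each beat a window of
    the median inter-beat interval is extracted per EEG channel, and the
    mean of the surrounding ``2*half_window + 1`` beat epochs (each
    baseline-corrected) is subtracted. Returns the corrected recording
    and a status dict (number of beats, or a skipped-with-warning flag).
    """
    try:
        ecg_idx = rec.channel_index(ecg_channel)
    except ValueError:
        warnings.warn(f"no ECG channel {ecg_channel!r}; BCG correction skipped")
        return rec.copy(), {"status": "skipped", "reason": "no-ecg-channel", "n_beats": 0}
    peaks = detect_pulse_peaks(rec.data[ecg_idx], rec.sfreq)
    if len(peaks) < 2 * half_window + 1:
        warnings.warn("too few pulse peaks detected; BCG correction skipped")
        return rec.copy(), {"status": "skipped", "reason": "too-few-peaks", "n_beats": len(peaks)}
    ibi = int(np.median(np.diff(peaks)))
    out = rec.copy()
    picks = rec.eeg_picks
    n = rec.data.shape[1]
    # beat epochs span [peak, peak + IBI): the artifact trails the R wave
    starts = np.array([p for p in peaks if p + ibi <= n], dtype=int)
    stack = np.stack([rec.data[picks, s : s + ibi] for s in starts])
    stack_bc = stack - stack.mean(axis=2, keepdims=True)

    # subtract only on channels with a pulse-locked component clearly above
    # the averaging noise floor, so clean channels pass through unchanged
    grand = stack_bc.mean(axis=0)  # channels x ibi
    epoch_var = stack_bc.var(axis=2).mean(axis=0)  # per channel
    floor = epoch_var / len(starts)
    locked = np.mean(grand**2, axis=1) > 4.0 * floor
    if not locked.any():
        return out, {
            "status": "skipped", "reason": "no-pulse-locked-component",
            "n_beats": len(peaks),
        }

    # the artifact latency after the R wave varies beat to beat; refine each
    # beat's position by cross-correlating against the grand template
    max_shift = int(0.04 * rec.sfreq)
    ref = grand[locked]
    refined = starts.copy()
    for b, s in enumerate(starts):
        best_val, best_s = -np.inf, s
        for sh in range(-max_shift, max_shift + 1):
            s2 = s + sh
            if s2 < 0 or s2 + ibi > n:
                continue
            seg = rec.data[picks[locked], s2 : s2 + ibi]
            val = float(np.sum(seg * ref))
            if val > best_val:
                best_val, best_s = val, s2
        refined[b] = best_s

    stack = np.stack([rec.data[picks, s : s + ibi] for s in refined])
    stack_bc = stack - stack.mean(axis=2, keepdims=True)
    csum = np.concatenate(
        [np.zeros((1,) + stack_bc.shape[1:]), np.cumsum(stack_bc, axis=0)], axis=0
    )
    apply = picks[locked]
    for b, s in enumerate(refined):
        lo = max(0, b - half_window)
        hi = min(len(refined), b + half_window + 1)
        template = (csum[hi] - csum[lo])[locked] / (hi - lo)
        out.data[apply, s : s + ibi] -= template
    return out, {
        "status": "ok", "n_beats": len(peaks), "ibi_samples": ibi,
        "n_channels_corrected": int(locked.sum()),
    }


def preprocess_continuous(
    rec: EEGRecording,
    l_freq: float = 0.1,
    h_freq: float = 50.0,
    target_sfreq: float = TARGET_SFREQ,
    rereference: bool = True,
) -> EEGRecording:
    """Band limit, resample to 500 Hz and common-average re-reference.

    Filters are zero-phase (forward-backward) Butterworth: low-pass of
    order 2 (a 12 dB/oct single-pass design slope) and high-pass of
    order 8 (48 dB/oct). Resampling is polyphase with anti-aliasing.
    The common average is the instantaneous mean over EEG channels only
    (ECG excluded) and is subtracted from the EEG channels.
    """
    if rec.sfreq < target_sfreq:
        raise ValueError(
            f"input sfreq {rec.sfreq} Hz below resampling target {target_sfreq} Hz"
        )
    data = rec.data.copy()
    nyq = rec.sfreq / 2
    sos_lp = sps.butter(2, h_freq / nyq, btype="low", output="sos")
    sos_hp = sps.butter(8, l_freq / nyq, btype="high", output="sos")
    data = sps.sosfiltfilt(sos_lp, data, axis=1)
    data = sps.sosfiltfilt(sos_hp, data, axis=1)

    if rec.sfreq != target_sfreq:
        from fractions import Fraction

        frac = Fraction(target_sfreq / rec.sfreq).limit_denominator(10000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=1)
        ratio = target_sfreq / rec.sfreq
    else:
        ratio = 1.0

    n_new = data.shape[1]
    events = []
    for s, label in rec.events:
        ns = int(round(s * ratio))
        if 0 <= ns < n_new:
            events.append((ns, label))

    reference = rec.reference
    if rereference:
        picks = rec.eeg_picks
        data[picks] -= data[picks].mean(axis=0, keepdims=True)
        reference = "common-average"

    return EEGRecording(
        data=data,
        sfreq=target_sfreq,
        ch_names=list(rec.ch_names),
        ch_types=list(rec.ch_types),
        events=events,
        reference=reference,
    )


def segment_and_baseline(
    rec: EEGRecording,
    feedback_label: str = "feedback",
    metadata: pd.DataFrame | None = None,
    tmin_ms: float = EPOCH_START_MS,
    tmax_ms: float = EPOCH_END_MS,
    baseline_ms: tuple[float, float] = BASELINE_MS,
) -> EpochSet:
    """Cut feedback-locked epochs and subtract the pre-stimulus baseline.

    Epochs span [tmin, tmax) ms around each feedback marker (default
    −1800 … +1200 ms, i.e. 1500 samples at 500 Hz). The per-channel mean
    over the baseline window (default [−200, 0) ms) is subtracted per
    trial. Events too close to a recording edge are dropped and logged in
    the returned metadata attribute ``dropped``.
    """
    samples = rec.event_samples(feedback_label)
    labels = [
        lab for s, lab in rec.events if lab == feedback_label or lab.startswith(feedback_label + "/")
    ]
    n_pre = int(round(-tmin_ms / 1000.0 * rec.sfreq))
    n_post = int(round(tmax_ms / 1000.0 * rec.sfreq))
    n_len = n_pre + n_post
    n = rec.data.shape[1]

    epochs = []
    rows = []
    dropped = []
    for i, (s, lab) in enumerate(zip(samples, labels)):
        if s - n_pre < 0 or s + n_post > n:
            dropped.append({"event_sample": int(s), "reason": "recording-edge"})
            continue
        epochs.append(rec.data[:, s - n_pre : s + n_post].copy())
        cond = lab.split("/", 1)[1] if "/" in lab else ""
        rows.append({"event_sample": int(s), "condition": cond})
    if epochs:
        data = np.stack(epochs)
    else:
        data = np.zeros((0, rec.data.shape[0], n_len))
    meta = pd.DataFrame(rows, columns=["event_sample", "condition"])
    if metadata is not None and len(metadata) >= len(meta):
        extra = metadata.reset_index(drop=True)
        kept = [i for i, (s, _) in enumerate(zip(samples, labels)) if n_pre <= s <= n - n_post]
        extra = extra.iloc[kept].reset_index(drop=True)
        for col in extra.columns:
            if col not in meta.columns:
                meta[col] = extra[col].to_numpy()

    # baseline correction on the half-open window [b0, b1)
    times = tmin_ms + 1000.0 * np.arange(n_len) / rec.sfreq
    bsl = (times >= baseline_ms[0]) & (times < baseline_ms[1])
    if data.size:
        data -= data[:, :, bsl].mean(axis=2, keepdims=True)

    es = EpochSet(
        data=data,
        sfreq=rec.sfreq,
        ch_names=list(rec.ch_names),
        ch_types=list(rec.ch_types),
        tmin_ms=tmin_ms,
        metadata=meta,
        rejected=np.zeros(len(meta), dtype=bool),
        reasons=[[] for _ in range(len(meta))],
        baseline_ms=baseline_ms,
    )
    es.dropped = pd.DataFrame(dropped, columns=["event_sample", "reason"])
    return es


def reject_artifacts(epochs: EpochSet) -> EpochSet:
    """Screen epochs with four amplitude criteria over all EEG channels.

    A trial is rejected if ANY EEG channel shows: a consecutive-sample
    voltage step > 50 µV; any absolute amplitude > 95 µV; a peak-to-peak
    range > 200 µV; or a peak-to-peak range < 0.5 µV (flat/low activity).
    Screening is idempotent and records reasons per trial.
    """
    picks = [i for i, t in enumerate(epochs.ch_types) if t == "eeg"]
    rejected = epochs.rejected.copy()
    reasons = [list(r) for r in epochs.reasons]
    for t in range(epochs.data.shape[0]):
        x = epochs.data[t][picks]
        trial_reasons = []
        if x.shape[1] > 1 and np.max(np.abs(np.diff(x, axis=1))) > STEP_THRESHOLD:
            trial_reasons.append("step")
        if np.max(np.abs(x)) > AMPLITUDE_THRESHOLD:
            trial_reasons.append("amplitude")
        ptp = np.max(x.max(axis=1) - x.min(axis=1))
        if ptp > RANGE_MAX:
            trial_reasons.append("range")
        if ptp < RANGE_MIN:
            trial_reasons.append("low activity")
        if trial_reasons:
            rejected[t] = True
            reasons[t] = sorted(set(reasons[t]) | set(trial_reasons))
    return EpochSet(
        data=epochs.data,
        sfreq=epochs.sfreq,
        ch_names=epochs.ch_names,
        ch_types=epochs.ch_types,
        tmin_ms=epochs.tmin_ms,
        metadata=epochs.metadata,
        rejected=rejected,
        reasons=reasons,
        baseline_ms=epochs.baseline_ms,
    )


def preprocess_recording(
    rec: EEGRecording,
    gradient: bool = True,
    bcg: bool = True,
    metadata: pd.DataFrame | None = None,
    gradient_half_window: int = 15,
) -> EpochSet:
    """Full cleanup chain: gradient -> BCG -> filter/resample/CAR -> epochs -> screening."""
    r = rec
    if gradient and len(rec.event_samples("volume")) > 0:
        r = remove_gradient_artifact(r, half_window=gradient_half_window)
    if bcg:
        r, _ = remove_bcg(r)
    r = preprocess_continuous(r)
    es = segment_and_baseline(r, metadata=metadata)
    return reject_artifacts(es)
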