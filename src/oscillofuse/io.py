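"""Standard-format I/O: EDF, marker TSV, NIfTI-1, tables, epoch containers.

EEG goes out as 16-bit EDF (written here, since only a reader is bundled
with MNE) plus a sidecar marker TSV (onset, duration, label); it comes
back in through :func:`mne.io.read_raw_edf`. BOLD volumes and effect
maps are NIfTI-1 via nibabel. Tables are plain TSV. Epoch sets use a
NumPy ``.npz`` container with a TSV sidecar for trial metadata and
rejection reasons.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib

from .preprocess import EEGRecording, EpochSet


class FormatError(ValueError):
    """Malformed input file; message carries the offending location."""


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as EDF (16-bit), one data record per second.

    Physical units are microvolts; the per-channel physical range is the
    observed signal range (quantization error is therefore bounded by
    range / 2^16 per sample). The sampling rate must be an integer.
    """
    path = Path(path)
    sf = rec.sfreq
    if abs(sf - round(sf)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    sf = int(round(sf))
    n_ch = rec.data.shape[0]
    n_records = rec.data.shape[1] // sf
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * sf]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min[:, None]) / gain[:, None] + dig_min).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),
            f("Startdate X", 80),
            f("01.01.00", 8),
            f("00.00.00", 8),
            f(str(256 * (n_ch + 1)), 8),
            f("", 44),
            f(str(n_records), 8),
            f("1", 8),
            f(str(n_ch), 4),
        ]
    )
    labels = b"".join(f(name, 16) for name in rec.ch_names)
    transducer = b"".join(f("", 80) for _ in range(n_ch))
    dim = b"".join(f("uV", 8) for _ in range(n_ch))
    pmin = b"".join(f(f"{v:.6g}"[:8], 8) for v in phys_min)
    pmax = b"".join(f(f"{v:.6g}"[:8], 8) for v in phys_max)
    dmin = b"".join(f(str(dig_min), 8) for _ in range(n_ch))
    dmax = b"".join(f(str(dig_max), 8) for _ in range(n_ch))
    prefilter = b"".join(f("", 80) for _ in range(n_ch))
    n_samp = b"".join(f(str(sf), 8) for _ in range(n_ch))
    reserved = b"".join(f("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + pmin + pmax + dmin + dmax
                 + prefilter + n_samp + reserved)
        for r in range(n_records):
            for c in range(n_ch):
                fh.write(digital[c, r * sf : (r + 1) * sf].tobytes())


def read_edf(path: str | Path, ecg_names: tuple[str, ...] = ("ECG",)) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    names = raw.ch_names
    types = ["ecg" if n in ecg_names else "eeg" for n in names]
    return EEGRecording(
        data=data, sfreq=float(raw.info["sfreq"]), ch_names=list(names),
        ch_types=types, events=[], reference="original",
    )


def write_markers(events: list[tuple[int, str]], sfreq: float, path: str | Path) -> None:
    """Marker TSV with columns onset (s), duration (s), label."""
    df = pd.DataFrame(
        {"onset": [s / sfreq for s, _ in events],
         "duration": 0.0,
         "label": [lab for _, lab in events]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_markers(path: str | Path, sfreq: float) -> list[tuple[int, str]]:
    """Read a marker TSV back to (sample, label) pairs, validating onsets."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    events = []
    for i, row in df.iterrows():
        try:
            onset = float(row["onset"])
        except (TypeError, ValueError):
            raise FormatError(f"{path}: line {i + 2}: non-numeric onset {row['onset']!r}")
        events.append((int(round(onset * sfreq)), str(row["label"])))
    return events


# ---------------------------------------------------------------------------
# NIfTI and tables
# ---------------------------------------------------------------------------


def write_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# epoch container
# ---------------------------------------------------------------------------


def write_epochs(epochs: EpochSet, stem: str | Path) -> None:
    """Write an EpochSet as <stem>.npz plus <stem>_trials.tsv sidecar."""
    stem = Path(stem)
    np.savez_compressed(
        stem.with_suffix(".npz"),
        data=epochs.data,
        sfreq=epochs.sfreq,
        tmin_ms=epochs.tmin_ms,
        baseline_ms=np.asarray(epochs.baseline_ms),
        ch_names=np.asarray(epochs.ch_names),
        ch_types=np.asarray(epochs.ch_types),
    )
    meta = epochs.metadata.copy()
    meta["rejected"] = epochs.rejected
    meta["rejection_reasons"] = [";".join(r) for r in epochs.reasons]
    meta.to_csv(stem.parent / (stem.name + "_trials.tsv"), sep="\t", index=False)


def read_epochs(stem: str | Path) -> EpochSet:
    stem = Path(stem)
    z = np.load(stem.with_suffix(".npz"), allow_pickle=False)
    meta = pd.read_csv(stem.parent / (stem.name + "_trials.tsv"), sep="\t")
    rejected = meta.pop("rejected").to_numpy(bool)
    reasons_raw = meta.pop("rejection_reasons").fillna("")
    reasons = [r.split(";") if r else [] for r in reasons_raw]
    return EpochSet(
        data=z["data"],
        sfreq=float(z["sfreq"]),
        ch_names=[str(c) for c in z["ch_names"]],
        ch_types=[str(c) for c in z["ch_types"]],
        tmin_ms=float(z["tmin_ms"]),
        metadata=meta,
        rejected=rejected,
        reasons=reasons,
        baseline_ms=tuple(z["baseline_ms"]),
    )
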