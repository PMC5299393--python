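"""Configuration objects for the simulator and the analysis pipeline.

Defaults mirror the gambling-task acquisition the package emulates:
four blocks of 100 trials, 2 s TR with 530 volumes per block, EEG sampled
at 5000 Hz. Desk-scale analyses shrink these explicitly (fewer
blocks/trials, coarser EEG rate); the defaults themselves stay at the
study conditions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

VALENCES = ("gain", "loss")
MAGNITUDES = (25, 5)
#: the four feedback conditions: valence crossed with chosen magnitude
CONDITIONS = ("large_gain", "large_loss", "small_gain", "small_loss")


def condition_label(valence: str, magnitude: int) -> str:
    size = "large" if magnitude == 25 else "small"
    return f"{size}_{valence}"


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class NoiseConfig:
    """Noise levels for the synthetic recordings.

    eeg_pink_rms : RMS amplitude (microvolts) of the 1/f EEG background.
    bold_ar1 : lag-1 autocorrelation of the BOLD noise process.
    bold_sd : marginal s.d. of the BOLD noise (signal units).
    drift_amp : maximum absolute slope endpoint of the per-voxel linear
        drift over a block (signal units).
    """

    eeg_pink_rms: float = 2.0
    bold_ar1: float = 0.3
    bold_sd: float = 1.0
    drift_amp: float = 0.5


@dataclass
class ArtifactConfig:
    """Scanner artifact injection switches and amplitudes (microvolts)."""

    gradient: bool = False
    bcg: bool = False
    gradient_amp: float = 300.0
    bcg_amp: float = 25.0
    heart_rate_bpm: float = 60.0
    bcg_jitter_ms: float = 20.0


@dataclass
class SimConfig:
    """Full description of one synthetic simultaneous-EEG/fMRI session.

    Timing of a trial (seconds from trial onset): choice stimulus at 0,
    selected number turns bold at +2, feedback at +4, account balance at
    +6 for 2 s, then a 2 s fixation — a 10 s pitch unless jittered.
    """

    n_subjects: int = 1
    n_blocks: int = 4
    trials_per_block: int = 100
    eeg_sfreq: float = 5000.0
    tr: float = 2.0
    n_scans_per_block: int = 530
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0

    # trial timing
    trial_pitch: float = 10.0
    onset_jitter: float = 0.0  # uniform [0, jitter) added per trial
    block_lead_in: float = 10.0  # quiet seconds before the first trial

    # oscillatory responses
    theta_freq: float = 5.1
    beta_freq: float = 25.5
    theta_amp_base: float = 3.0  # microvolt burst amplitude for gain trials
    beta_amp_base: float = 2.0  # microvolt burst amplitude for loss trials
    valence_effect_theta: float = 1.5  # loss minus gain mean amplitude
    valence_effect_beta: float = 1.0  # gain minus loss mean amplitude
    trial_amp_sd: float = 0.75
    burst_center_s: float = 0.3  # burst envelope center after feedback
    burst_sigma_s: float = 0.1  # Gaussian envelope s.d.

    # BOLD effects
    coupling_gamma_theta: float = 0.5
    coupling_gamma_beta: float = 0.5
    # conditions in which each coupling is expressed (the theta coupling
    # rides on loss feedback, the high-beta coupling on gain feedback);
    # set both to all four conditions for valence-unspecific coupling
    coupling_theta_conditions: tuple = ("large_loss", "small_loss")
    coupling_beta_conditions: tuple = ("large_gain", "small_gain")
    # per-subject multiplicative variability of coupling strength
    subject_coupling_sd: float = 0.3
    condition_betas: dict = field(
        default_factory=lambda: {
            "large_gain": 1.0,
            "large_loss": 0.8,
            "small_gain": 0.6,
            "small_loss": 0.5,
        }
    )

    noise: NoiseConfig = field(default_factory=NoiseConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)

    magnitude_policy: str = "fair-coin"  # or "always-25", "always-5"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_blocks", "trials_per_block", "n_scans_per_block"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.tr <= 0:
            raise InvalidConfigError("tr must be positive")
        if self.eeg_sfreq <= 2 * self.beta_freq:
            raise InvalidConfigError(
                "eeg_sfreq must exceed twice the beta frequency "
                f"({self.eeg_sfreq} Hz vs beta {self.beta_freq} Hz)"
            )
        if self.magnitude_policy not in ("fair-coin", "always-25", "always-5"):
            raise InvalidConfigError(f"unknown magnitude_policy {self.magnitude_policy!r}")
        unknown = set(self.condition_betas) - set(CONDITIONS)
        if unknown:
            raise InvalidConfigError(f"unknown conditions in condition_betas: {sorted(unknown)}")

    @property
    def block_duration(self) -> float:
        return self.n_scans_per_block * self.tr

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-mm affine: isotropic scaling, origin at the grid corner."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def to_dict(self) -> dict:
        return asdict(self)

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic child generator for a named randomness stream."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _stream_id(stream)])
        )


def _stream_id(stream: str) -> int:
    # process-independent (unlike hash()) so seeding is reproducible
    return zlib.crc32(stream.encode("utf-8")) % (2**31)


def child_seed(seed: int, stream: str) -> int:
    """Derive a deterministic sub-seed below 2**31 from a global seed."""
    ss = np.random.SeedSequence([int(seed), _stream_id(stream)])
    return int(ss.generate_state(1)[0] % (2**31))
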