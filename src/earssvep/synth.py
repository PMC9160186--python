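"""Synthetic multi-subject SSVEP trial generator.

Emulates the structure of a steady-state visual evoked potential recording
session: each trial is a stack of harmonic sinusoids at the stimulus
frequency (fundamental plus two harmonics, amplitudes decaying as 1/(h+1))
buried in 1/f^alpha colored background noise, sampled at 250 Hz for 5 s.
Channel profiles reproduce the characteristic channel-quality contrast of
scalp recordings: a strong occipital channel (Oz, narrowband SNR around
7.5 dB) and weak temporal channels near the ears (T7/T8, around 0.35 dB),
with intermediate parieto-occipital channels in between.

Subjects differ in evoked-response phase, overall response gain, and
harmonic decay, so models trained on one set of subjects generalize
imperfectly to unseen ones — the property that separates subject-dependent
from subject-independent training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.io import savemat

from .metrics import DEFAULT_SNR_K, narrowband_snr_db
from .spectro import FRAME_SAMPLES, frame_fft

__all__ = [
    "ChannelProfile",
    "SimConfig",
    "MultiChannelTrial",
    "CalibrationError",
    "default_channel_profiles",
    "generate_trial",
    "generate_dataset",
    "calibrate_snr",
    "measure_profile_snr",
    "write_benchmark_mat",
]

#: Channels used by the evaluation harness, occipital midline plus the
#: parieto-occipital / temporal chain down to the ear positions.
HARNESS_CHANNELS = ("Oz", "P7", "P8", "PO7", "PO8", "TP7", "TP8", "T7", "T8")

# Fundamental amplitudes (uV, relative to unit-SD pink noise) calibrated so
# the mean narrowband SNR over 1 s segments hits the per-channel set-points:
# Oz 7.54 dB, T7/T8 0.35 dB, with PO/P/TP channels log-spaced in between.
_CALIBRATED_FUNDAMENTALS = {
    "Oz": 0.3942,
    "PO7": 0.3193,
    "PO8": 0.3193,
    "P7": 0.2557,
    "P8": 0.2557,
    "TP7": 0.1899,
    "TP8": 0.1899,
    "T7": 0.1324,
    "T8": 0.1324,
}


class CalibrationError(RuntimeError):
    """Raised when an SNR target cannot be reached by amplitude scaling."""


@dataclass(frozen=True)
class ChannelProfile:
    """Spectral profile of one simulated electrode.

    ``harmonic_amplitudes[h]`` is the amplitude (uV) of the (h+1)-th multiple
    of the stimulus frequency; ``noise_sd`` scales the broadband background
    and ``noise_color`` is the exponent alpha of its 1/f^alpha shaping.
    """

    name: str
    harmonic_amplitudes: tuple[float, ...]
    noise_sd: float = 1.0
    noise_color: float = 1.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.harmonic_amplitudes):
            raise ValueError("harmonic amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.noise_color <= 2.0):
            raise ValueError("noise_color alpha must lie in [0, 2]")

    def scaled(self, factor: float) -> "ChannelProfile":
        """Return a copy with every harmonic amplitude multiplied by ``factor``."""
        return replace(
            self,
            harmonic_amplitudes=tuple(a * factor for a in self.harmonic_amplitudes),
        )


def _decay_amplitudes(fundamental: float, n_harmonics: int = 3) -> tuple[float, ...]:
    return tuple(fundamental / (h + 1) for h in range(n_harmonics))


def default_channel_profiles() -> dict[str, ChannelProfile]:
    """Nine-channel profile set with the occipital-to-temporal SNR gradient."""
    return {
        name: ChannelProfile(name=name, harmonic_amplitudes=_decay_amplitudes(a))
        for name, a in _CALIBRATED_FUNDAMENTALS.items()
    }


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a simulated recording session."""

    fs: int = 250
    stim_freqs: tuple[float, ...] = (8.0, 11.0, 14.0)
    trial_seconds: float = 5.0
    n_subjects: int = 10
    n_blocks: int = 6
    channel_profiles: Mapping[str, ChannelProfile] = field(
        default_factory=default_channel_profiles
    )
    seed: int = 0
    #: sd (log scale) of the per-subject evoked-response gain
    subject_gain_log_sd: float = 0.2
    #: half-range of the per-subject harmonic-decay tilt exponent
    subject_tilt_range: float = 0.3

    def __post_init__(self) -> None:
        if len(set(self.stim_freqs)) != len(self.stim_freqs):
            raise ValueError("stimulus frequencies must be distinct")
        n_samples = self.trial_seconds * self.fs
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("trial_seconds * fs must be an integer sample count")
        n_harm = max(
            (len(p.harmonic_amplitudes) for p in self.channel_profiles.values()),
            default=0,
        )
        top = max(self.stim_freqs) * n_harm
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} Hz cannot represent the highest retained harmonic "
                f"({top} Hz); need fs > {2 * top}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.fs))

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.channel_profiles)


@dataclass
class MultiChannelTrial:
    """One labeled trial: per-channel sample vectors plus identifiers."""

    samples: dict[str, np.ndarray]
    label_freq: float
    subject_id: int
    block_id: int

    def __post_init__(self) -> None:
        lengths = {v.size for v in self.samples.values()}
        if len(lengths) > 1:
            raise ValueError("all channel vectors must have equal length")


def _colored_noise(
    rng: np.random.Generator, n: int, sd: float, alpha: float, fs: float
) -> np.ndarray:
    """Gaussian noise spectrally shaped to 1/f^alpha with unit-gain filter."""
    white = rng.standard_normal(n)
    if sd == 0.0:
        return np.zeros(n)
    if alpha == 0.0:
        return sd * white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-alpha / 2.0)
    gain /= math.sqrt(float(np.mean(gain[1:] ** 2)))
    return sd * np.fft.irfft(spec * gain, n)


def _subject_rng(cfg: SimConfig, subject: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729, int(subject)]))


def _subject_params(cfg: SimConfig, subject: int, n_harmonics: int):
    """Phases, response gain and harmonic tilt drawn once per subject."""
    rng = _subject_rng(cfg, subject)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harmonics)
    gain = float(np.exp(rng.normal(0.0, cfg.subject_gain_log_sd)))
    tilt = float(rng.uniform(-cfg.subject_tilt_range, cfg.subject_tilt_range))
    return phases, gain, tilt


def _evoked_waveform(
    profile: ChannelProfile,
    label: float,
    t: np.ndarray,
    phases: np.ndarray,
    gain: float,
    tilt: float,
) -> np.ndarray:
    sig = np.zeros_like(t)
    for h, amp in enumerate(profile.harmonic_amplitudes):
        sig += amp * gain * (h + 1) ** (-tilt) * np.sin(
            2.0 * np.pi * (h + 1) * label * t + phases[h]
        )
    return sig


def generate_trial(
    cfg: SimConfig,
    subject: int,
    block: int,
    label: float,
    rng: np.random.Generator | None = None,
) -> MultiChannelTrial:
    """Generate one multi-channel trial, deterministic given (seed, ids, label).

    Each channel is the subject's evoked harmonic stack at the stimulus
    frequency plus an independent colored-noise draw. Passing ``rng``
    overrides the derived per-trial noise stream (used by calibration).
    """
    if label not in cfg.stim_freqs:
        raise ValueError(
            f"label {label} Hz is not a stimulus frequency; valid set: {sorted(cfg.stim_freqs)}"
        )
    freq_index = cfg.stim_freqs.index(label)
    t = np.arange(cfg.n_samples) / cfg.fs
    n_harm = max(len(p.harmonic_amplitudes) for p in cfg.channel_profiles.values())
    phases, gain, tilt = _subject_params(cfg, subject, n_harm)
    samples: dict[str, np.ndarray] = {}
    for ci, (name, profile) in enumerate(cfg.channel_profiles.items()):
        trial_rng = rng or np.random.default_rng(
            np.random.SeedSequence([cfg.seed, int(subject), int(block), freq_index, ci])
        )
        noise = _colored_noise(
            trial_rng, cfg.n_samples, profile.noise_sd, profile.noise_color, cfg.fs
        )
        samples[name] = _evoked_waveform(profile, label, t, phases, gain, tilt) + noise
    return MultiChannelTrial(
        samples=samples, label_freq=label, subject_id=int(subject), block_id=int(block)
    )


def generate_dataset(cfg: SimConfig) -> list[MultiChannelTrial]:
    """All (subject, block, frequency) combinations, each exactly once."""
    return [
        generate_trial(cfg, subject, block, freq)
        for subject in range(cfg.n_subjects)
        for block in range(cfg.n_blocks)
        for freq in cfg.stim_freqs
    ]


def _segment_snr(
    profile: ChannelProfile,
    cfg: SimConfig,
    trial_index: int,
    k: int,
) -> float:
    """Narrowband SNR of one simulated 1 s segment (deterministic per index)."""
    freq = cfg.stim_freqs[trial_index % len(cfg.stim_freqs)]
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 15485863, trial_index])
    )
    t = np.arange(FRAME_SAMPLES) / cfg.fs
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(profile.harmonic_amplitudes))
    sig = _evoked_waveform(profile, freq, t, phases, gain=1.0, tilt=0.0)
    sig = sig + _colored_noise(
        rng, FRAME_SAMPLES, profile.noise_sd, profile.noise_color, cfg.fs
    )
    return narrowband_snr_db(frame_fft(sig, cfg.fs), freq, k=k)


def measure_profile_snr(
    profile: ChannelProfile,
    cfg: SimConfig,
    n_trials: int = 100,
    k: int = DEFAULT_SNR_K,
) -> float:
    """Mean narrowband SNR (dB) of the profile over simulated 1 s segments."""
    return float(
        np.mean([_segment_snr(profile, cfg, i, k) for i in range(n_trials)])
    )


def calibrate_snr(
    profile: ChannelProfile,
    target_snr_db: float,
    cfg: SimConfig,
    n_trials: int = 100,
    *,
    tolerance_db: float = 1.0,
) -> ChannelProfile:
    """Scale a profile's harmonic stack so its mean narrowband SNR hits a target.

    The realized SNR is measured over ``n_trials`` simulated 1 s segments
    (common random numbers, so the search is deterministic) and the amplitude
    scale is bisected until the mean lies within ``tolerance_db`` of
    ``target_snr_db``.
    """
    if not math.isfinite(target_snr_db):
        raise ValueError("target SNR must be finite")
    if n_trials < 10:
        raise ValueError("calibration needs at least 10 trials")
    if profile.noise_sd == 0.0 or not any(profile.harmonic_amplitudes):
        raise CalibrationError(
            f"profile {profile.name!r} has no noise or no signal; "
            "SNR cannot be steered by amplitude scaling"
        )

    def realized(log_scale: float) -> float:
        return measure_profile_snr(profile.scaled(10.0**log_scale), cfg, n_trials)

    lo, hi = -4.0, 4.0
    if realized(lo) > target_snr_db or realized(hi) < target_snr_db:
        raise CalibrationError(
            f"target {target_snr_db} dB outside reachable range for {profile.name!r}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target_snr_db:
            lo = mid
        else:
            hi = mid
    scale = 10.0 ** (0.5 * (lo + hi))
    result = profile.scaled(scale)
    achieved = measure_profile_snr(result, cfg, n_trials)
    if abs(achieved - target_snr_db) > tolerance_db:
        raise CalibrationError(
            f"calibration of {profile.name!r} converged to {achieved:.2f} dB, "
            f"outside {target_snr_db} +/- {tolerance_db} dB"
        )
    return result


def write_benchmark_mat(trials: Iterable[MultiChannelTrial], path) -> None:
    """Write one subject's trials in the benchmark-compatible MAT layout.

    The array is ``channels x samples x targets x blocks`` with the channel
    names, stimulus frequencies, sampling rate and subject id stored
    alongside, so synthetic fixtures and the real-data adapter share one
    reader path.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to write")
    subjects = {tr.subject_id for tr in trials}
    if len(subjects) != 1:
        raise ValueError("write_benchmark_mat expects trials of a single subject")
    channels = list(trials[0].samples)
    freqs = sorted({tr.label_freq for tr in trials})
    blocks = sorted({tr.block_id for tr in trials})
    n_samples = next(iter(trials[0].samples.values())).size
    data = np.zeros((len(channels), n_samples, len(freqs), len(blocks)))
    for tr in trials:
        fi = freqs.index(tr.label_freq)
        bi = blocks.index(tr.block_id)
        for ci, ch in enumerate(channels):
            data[ci, :, fi, bi] = tr.samples[ch]
    savemat(
        str(path),
        {
            "data": data,
            "channels": np.array(channels, dtype=object),
            "freqs": np.array(freqs, dtype=float),
            "blocks": np.array(blocks, dtype=float),
            "fs": 250.0,
            "subject": float(trials[0].subject_id),
        },
    )
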