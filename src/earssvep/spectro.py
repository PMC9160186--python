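"""FFT-spectrogram preprocessing for SSVEP classification.

A single EEG channel sampled at 250 Hz is high-pass filtered (5 Hz edge of
the nominal 5-125 Hz passband; the upper edge coincides with Nyquist, so only
the lower edge is realized), cut into consecutive non-overlapping 1 s frames,
and each frame is transformed with a 250-point FFT. The 125 magnitude bins
covering 1-125 Hz at 1 Hz resolution form one image column, giving a
``125 x W`` spectrogram for a window of ``W`` seconds (W in 1..5).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

FRAME_SAMPLES = 250
N_BINS = 125
HIGHPASS_HZ = 5.0
_MAX_WINDOW_SECONDS = 5

__all__ = [
    "Spectrogram",
    "bandpass",
    "frame_fft",
    "build_spectrogram",
    "normalize_image",
    "preprocess",
]


@dataclass(frozen=True)
class Spectrogram:
    """A frequency-by-time magnitude image.

    ``values`` has exactly 125 rows (1 Hz bins spanning 1-125 Hz; the DC bin
    is dropped) and ``window_seconds`` columns, one per 1 s frame.
    """

    values: np.ndarray
    window_seconds: int
    channel: str | None = None
    label_freq: float | None = None
    freq_resolution: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != N_BINS:
            raise ValueError(
                f"spectrogram must have exactly {N_BINS} rows, got shape {v.shape}"
            )
        if v.shape[1] != self.window_seconds:
            raise ValueError(
                f"expected {self.window_seconds} columns for a "
                f"{self.window_seconds} s window, got {v.shape[1]}"
            )
        if np.any(v < 0):
            raise ValueError("spectrogram magnitudes must be non-negative")

    @property
    def freqs(self) -> np.ndarray:
        """Center frequency of each row in Hz (1..125)."""
        return np.arange(1, N_BINS + 1) * self.freq_resolution


def _highpass_sos(fs: float) -> np.ndarray:
    return sps.butter(4, HIGHPASS_HZ, btype="highpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, fs: float = 250.0) -> np.ndarray:
    """Zero-phase 5 Hz high-pass (lower edge of the 5-125 Hz passband).

    At fs = 250 Hz the nominal 125 Hz upper edge sits at Nyquist, so the
    passband is realized as a 4th-order Butterworth high-pass applied
    forward-backward (``sosfiltfilt``), which preserves in-band content
    within 1 dB while attenuating sub-5 Hz drift.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("bandpass expects a 1-D sample vector")
    sos = _highpass_sos(fs)
    # sosfiltfilt needs enough samples for its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if x.size <= padlen:
        raise ValueError(
            f"signal too short for zero-phase filtering: {x.size} samples, "
            f"need more than {padlen}"
        )
    return sps.sosfiltfilt(sos, x)


def frame_fft(window: np.ndarray, fs: float = 250.0) -> np.ndarray:
    """Magnitude of the 250-point FFT of a 1 s frame, bins 1-125 Hz.

    The DC bin is dropped so the 125 retained bins span 1 Hz .. fs/2 at
    1 Hz spacing; magnitudes follow the unnormalized transform convention
    (a unit sinusoid at an integer frequency yields N/2 = 125 at its bin).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size != FRAME_SAMPLES:
        raise ValueError(
            f"frame_fft requires exactly {FRAME_SAMPLES} samples, got {window.size}"
        )
    spec = np.fft.rfft(window)  # 126 bins: DC .. Nyquist
    return np.abs(spec[1 : N_BINS + 1])


def build_spectrogram(
    trial_channel: np.ndarray,
    fs: float = 250.0,
    window_seconds: int = 5,
    *,
    channel: str | None = None,
    label_freq: float | None = None,
) -> Spectrogram:
    """Stack ``window_seconds`` consecutive 1 s frame spectra into an image.

    Frames are non-overlapping, rectangular-windowed, and anchored at the
    start of the valid data, so a ``W`` s window yields a 125 x W image.
    """
    if not (1 <= int(window_seconds) <= _MAX_WINDOW_SECONDS) or int(window_seconds) != window_seconds:
        raise ValueError(
            f"window_seconds must be an integer in 1..{_MAX_WINDOW_SECONDS}, got {window_seconds}"
        )
    window_seconds = int(window_seconds)
    x = np.asarray(trial_channel, dtype=float)
    needed = window_seconds * int(fs)
    if x.size < needed:
        raise ValueError(
            f"need at least {needed} samples for a {window_seconds} s window, got {x.size}"
        )
    cols = [frame_fft(x[i * FRAME_SAMPLES : (i + 1) * FRAME_SAMPLES], fs) for i in range(window_seconds)]
    return Spectrogram(
        values=np.column_stack(cols),
        window_seconds=window_seconds,
        channel=channel,
        label_freq=label_freq,
    )


def normalize_image(s: Spectrogram) -> Spectrogram:
    """Scale magnitudes to [0, 1] by the per-image maximum.

    Removes inter-channel amplitude differences the classifier should not
    exploit. An all-zero image passes through unchanged.
    """
    peak = float(np.max(s.values))
    if peak == 0.0:
        return s
    return replace(s, values=s.values / peak)


def preprocess(
    trial_channel: np.ndarray,
    fs: float = 250.0,
    window_seconds: int = 5,
    *,
    normalize: bool = True,
    channel: str | None = None,
    label_freq: float | None = None,
) -> Spectrogram:
    """Full single-channel pipeline: band-pass, frame FFT, normalization."""
    filtered = bandpass(trial_channel, fs)
    s = build_spectrogram(
        filtered, fs, window_seconds, channel=channel, label_freq=label_freq
    )
    return normalize_image(s) if normalize else s
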