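"""Canonical correlation analysis baseline for SSVEP frequency detection.

The classical training-free detector: a signal window is correlated with a
bank of sine/cosine references at each candidate stimulus frequency and its
harmonics; the frequency whose reference set attains the largest leading
canonical correlation wins. Canonical correlations are computed by the
standard QR-plus-SVD route, which degenerates gracefully to the absolute
Pearson correlation for a single channel against a single reference column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

__all__ = ["ReferenceSet", "make_references", "leading_canonical_correlation", "cca_classify"]


@dataclass(frozen=True)
class ReferenceSet:
    """Per-frequency sine/cosine reference matrices (n_samples x 2*n_harmonics)."""

    refs: Mapping[float, np.ndarray]
    fs: float
    window_seconds: float
    n_harmonics: int

    @property
    def n_samples(self) -> int:
        return next(iter(self.refs.values())).shape[0]


def make_references(
    freqs: Sequence[float],
    fs: float = 250.0,
    window_seconds: float = 1.0,
    n_harmonics: int = 3,
) -> ReferenceSet:
    """Unit-amplitude sin/cos pairs at each frequency and its harmonics."""
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic in the reference set")
    n = int(round(window_seconds * fs))
    t = np.arange(n) / fs
    refs: dict[float, np.ndarray] = {}
    for f in freqs:
        top = f * n_harmonics
        if top >= fs / 2:
            raise ValueError(
                f"harmonic {top} Hz of {f} Hz aliases at fs={fs} Hz; "
                "reduce n_harmonics"
            )
        cols = []
        for h in range(1, n_harmonics + 1):
            cols.append(np.sin(2 * np.pi * h * f * t))
            cols.append(np.cos(2 * np.pi * h * f * t))
        refs[float(f)] = np.column_stack(cols)
    return ReferenceSet(
        refs=refs, fs=fs, window_seconds=window_seconds, n_harmonics=n_harmonics
    )


def leading_canonical_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Largest canonical correlation between column spaces of ``x`` and ``y``.

    Both inputs are centered; the correlation is the leading singular value
    of Qx' Qy where Q are thin QR factors, clipped into [0, 1].
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    if y.shape[0] == 1:
        y = y.T
    if x.shape[0] != y.shape[0]:
        raise ValueError("signal and reference must have the same sample count")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    if not np.any(np.ptp(xc, axis=0) > 0):
        raise ValueError("signal window has zero variance; correlation undefined")
    qx, _ = linalg.qr(xc, mode="economic")
    qy, _ = linalg.qr(yc, mode="economic")
    s = linalg.svd(qx.T @ qy, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def cca_classify(
    signal: np.ndarray, refs: ReferenceSet
) -> tuple[float, dict[float, float]]:
    """Detect the stimulus frequency of one window.

    ``signal`` is (n_samples,) for a single channel or (n_samples,
    n_channels); returns the winning frequency (ties break to the lowest)
    and the leading canonical correlation per candidate.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = signal[:, None]
    if signal.shape[0] != refs.n_samples:
        raise ValueError(
            f"window has {signal.shape[0]} samples but references expect {refs.n_samples}"
        )
    corrs = {
        f: leading_canonical_correlation(signal, ref) for f, ref in refs.refs.items()
    }
    best = max(sorted(corrs), key=lambda f: corrs[f])
    return best, corrs
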