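"""Evaluation metrics: information transfer rate, narrowband SNR, accuracy,
and paired significance testing.

ITR follows the standard BCI formula

    ITR = (log2 N + P log2 P + (1 - P) log2[(1 - P)/(N - 1)]) * 60 / T

in bits per minute, where P is classification accuracy, N the number of
stimuli and T the selection time in seconds (stimulation window plus the
gaze-shifting period, 0.55 s by convention here).

Narrowband SNR compares the magnitude at the stimulus frequency with the
mean magnitude of the 2K adjacent bins:

    SNR = 20 log10( 2K * y(f) / sum_{k=1..K} [y(f - k df) + y(f + k df)] )
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import stats

GAZE_SHIFT_SECONDS = 0.55
DEFAULT_SNR_K = 5
DEFAULT_SNR_DELTA_HZ = 1.0

__all__ = [
    "GAZE_SHIFT_SECONDS",
    "itr_bits_per_min",
    "narrowband_snr_db",
    "accuracy",
    "paired_comparison",
]


def itr_bits_per_min(p: float, n_stimuli: int, t_seconds: float) -> float:
    """Information transfer rate in bits per minute.

    Uses the convention ``x log2 x = 0`` at ``x = 0`` so the endpoints
    P = 0 and P = 1 are well defined. The bracketed term is a
    Kullback-Leibler divergence, so the rate is never negative; it is zero
    exactly at chance P = 1/N. Below-chance accuracies are flagged with a
    warning, since there the positive rate reflects systematic confusions
    rather than usable throughput.
    """
    p = float(p)
    n_stimuli = int(n_stimuli)
    t_seconds = float(t_seconds)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"accuracy P must lie in [0, 1], got {p}")
    if n_stimuli < 2:
        raise ValueError(f"number of stimuli N must be >= 2, got {n_stimuli}")
    if t_seconds <= 0:
        raise ValueError(f"selection time T must be positive, got {t_seconds}")

    def _xlog2x(x: float) -> float:
        return 0.0 if x == 0.0 else x * np.log2(x)

    bits = np.log2(n_stimuli) + _xlog2x(p)
    if p < 1.0:
        bits += (1.0 - p) * np.log2((1.0 - p) / (n_stimuli - 1))
    if p < 1.0 / n_stimuli:
        warnings.warn(
            f"accuracy {p:.4f} is below chance 1/{n_stimuli}; the rate "
            "reflects systematic confusions, not usable throughput",
            stacklevel=2,
        )
    return float(bits * 60.0 / t_seconds)


def narrowband_snr_db(
    y: np.ndarray,
    f: float,
    k: int = DEFAULT_SNR_K,
    delta_f: float = DEFAULT_SNR_DELTA_HZ,
    *,
    first_bin_hz: float = 1.0,
) -> float:
    """Narrowband SNR (dB) of a magnitude spectrum at stimulus frequency ``f``.

    ``y`` is a magnitude spectrum sampled every ``delta_f`` Hz with its first
    entry at ``first_bin_hz`` (the layout of a :class:`~earssvep.spectro.Spectrogram`
    column). ``k`` is half the number of adjacent bands.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("spectrum must be a 1-D magnitude vector")
    if np.any(y < 0):
        raise ValueError("magnitude spectrum must be non-negative")
    if k < 1:
        raise ValueError("K must be at least 1")
    idx = (f - first_bin_hz) / delta_f
    i = int(round(idx))
    if abs(idx - i) > 1e-9:
        raise ValueError(f"stimulus frequency {f} Hz is not on the {delta_f} Hz bin grid")
    if i - k < 0 or i + k >= y.size:
        raise ValueError(
            f"f +/- K*delta_f must stay inside the spectrum: f={f}, K={k}, "
            f"spectrum spans {first_bin_hz}..{first_bin_hz + delta_f * (y.size - 1)} Hz"
        )
    neighbors = y[i - k : i].sum() + y[i + 1 : i + k + 1].sum()
    if neighbors == 0.0:
        warnings.warn(
            "all adjacent bands are zero; narrowband SNR is unbounded",
            stacklevel=2,
        )
        return float("inf")
    return float(20.0 * np.log10(2 * k * y[i] / neighbors))


def accuracy(predictions: Sequence, labels: Sequence) -> float:
    """Proportion of predictions matching labels."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0:
        raise ValueError("cannot compute accuracy of an empty prediction set")
    if predictions.shape != labels.shape:
        raise ValueError(
            f"predictions and labels differ in shape: {predictions.shape} vs {labels.shape}"
        )
    return float(np.mean(predictions == labels))


def paired_comparison(
    acc_a: Sequence[float],
    acc_b: Sequence[float],
    *,
    method: str = "ttest",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sided paired comparison of per-subject accuracies.

    Returns ``(mean_difference, p_value)`` for ``acc_a - acc_b``. The default
    is a paired t-test across subjects; ``method='permutation'`` runs a
    sign-flip permutation test instead. Exactly tied vectors yield p = 1;
    a constant non-zero shift (zero-variance differences) yields p = 0 under
    the t-test limit.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired accuracies must be equal-length 1-D vectors")
    if a.size < 2:
        raise ValueError("need at least two paired observations")
    diffs = a - b
    mean_diff = float(np.mean(diffs))
    if np.std(diffs) == 0.0:
        return mean_diff, 1.0 if mean_diff == 0.0 else 0.0
    if method == "ttest":
        result = stats.ttest_rel(a, b)
        return mean_diff, float(result.pvalue)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        result = stats.permutation_test(
            (a, b),
            lambda x, y: np.mean(x - y),
            permutation_type="samples",
            n_resamples=n_permutations,
            alternative="two-sided",
            rng=rng,
        )
        return mean_diff, float(result.pvalue)
    raise ValueError(f"unknown method {method!r}; use 'ttest' or 'permutation'")
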