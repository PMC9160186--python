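"""Evaluation harness: subject-dependent and subject-independent schemes.

Both schemes follow the same recipe. Spectrograms from all nine channels
(Oz plus the parieto-occipital/temporal chain down to T7/T8) are pooled for
CNN training; testing uses only single-channel inputs from Oz, T7 or T8 to
emulate a single-electrode device. A validation partition held out from the
training trials serves two purposes: monitoring and fitting the binaural
(T7, T8) -> Oz softmax regression. Reported conditions are Oz, T7, T8, the
single-ear baseline avT7T8 (mean of the T7-only and T8-only accuracies per
subject) and the regressed binaural classifier.

Splits are performed at the trial level, so all channel views of a trial
fall on the same side of every partition; this keeps the paired softmax
samples intact for the fusion fit and rules out cross-channel leakage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import loadmat

from .cnn import SsvepCnn, TrainConfig
from .fusion import PairedSoftmaxSample, apply_fusion_batch, fit_fusion
from .metrics import GAZE_SHIFT_SECONDS, itr_bits_per_min, paired_comparison
from .spectro import preprocess
from .synth import HARNESS_CHANNELS, MultiChannelTrial

__all__ = [
    "SchemeConfig",
    "ConditionResult",
    "EvalReport",
    "run_subject_dependent",
    "run_subject_independent",
    "sweep_windows",
    "load_benchmark_mat",
]

TEST_CHANNELS = ("Oz", "T7", "T8")
CONDITIONS = ("Oz", "T7", "T8", "avT7T8", "regressed")
REQUIRED_FREQS = (8.0, 11.0, 14.0)
VALID_SAMPLES = 1250  # 5 s at 250 Hz
_MIN_VAL_TRIALS = 4  # fusion needs at least intercept + 2 slopes + 1 df


@dataclass(frozen=True)
class SchemeConfig:
    """Settings shared by the two training schemes."""

    scheme: str = "subject-dependent"
    window_seconds: int = 2
    n_folds: int = 5
    train_fraction: float = 0.9
    val_fraction: float = 0.1
    n_groups: int = 5
    channels_train: tuple[str, ...] = HARNESS_CHANNELS
    channels_test: tuple[str, ...] = TEST_CHANNELS
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.scheme not in ("subject-dependent", "subject-independent"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if not set(self.channels_test) <= set(self.channels_train):
            raise ValueError("test channels must be a subset of training channels")


@dataclass
class ConditionResult:
    condition: str
    mean_accuracy: float
    per_subject: dict[int, float]
    itr: float
    p_value_vs_avt7t8: float | None = None


@dataclass
class EvalReport:
    """Accuracies, ITRs and significance results for one scheme and window."""

    scheme: str
    window_seconds: int
    seed: int
    n_models: int
    conditions: dict[str, ConditionResult]

    def accuracy(self, condition: str) -> float:
        return self.conditions[condition].mean_accuracy

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scheme": self.scheme,
                "condition": c.condition,
                "window_seconds": self.window_seconds,
                "accuracy": c.mean_accuracy,
                "itr_bits_per_min": c.itr,
                "p_value_vs_avT7T8": c.p_value_vs_avt7t8,
            }
            for c in self.conditions.values()
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        for cond in payload["conditions"].values():
            cond["per_subject"] = {str(k): v for k, v in cond["per_subject"].items()}
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------


def _check_channels(trials: Sequence[MultiChannelTrial], channels: Sequence[str]) -> None:
    for tr in trials:
        missing = [ch for ch in channels if ch not in tr.samples]
        if missing:
            raise ValueError(
                f"subject {tr.subject_id} block {tr.block_id} is missing "
                f"channel(s) {missing}"
            )


def _spectrogram_arrays(
    trials: Sequence[MultiChannelTrial],
    channels: Sequence[str],
    window_seconds: int,
    fs: float = 250.0,
) -> dict[str, np.ndarray]:
    """Per-channel image stacks (n_trials, 125, W), preprocessed once."""
    return {
        ch: np.stack(
            [preprocess(tr.samples[ch], fs, window_seconds).values for tr in trials]
        ).astype(np.float32)
        for ch in channels
    }


def _stratified_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator, min_right: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into (left, right) with ``fraction`` on the left,
    stratified by label; every class keeps at least ``min_right`` on the right."""
    left, right = [], []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        n_left = min(int(round(fraction * idx.size)), idx.size - min_right)
        left.extend(idx[:n_left])
        right.extend(idx[n_left:])
    return np.sort(np.asarray(left, dtype=int)), np.sort(np.asarray(right, dtype=int))


def _validation_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Hold out the validation partition for the fusion fit, guaranteeing
    enough trials per class that the per-node regressions are solvable."""
    n_classes = np.unique(labels).size
    min_per_class = max(1, int(np.ceil(_MIN_VAL_TRIALS / n_classes)))
    return _stratified_split(labels, 1.0 - val_fraction, rng, min_right=min_per_class)


def _fit_and_score_fold(
    images: Mapping[str, np.ndarray],
    y: np.ndarray,
    subjects: np.ndarray,
    fit_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
    cfg: SchemeConfig,
    fold_seed: int,
) -> dict[str, list[tuple[int, bool]]]:
    """Train one CNN, fit fusion on the validation trials, score the test trials.

    Returns per condition a list of (subject, correct) pairs.
    """
    x_train = np.concatenate([images[ch][fit_idx] for ch in cfg.channels_train])
    y_train = np.tile(y[fit_idx], len(cfg.channels_train))
    model = SsvepCnn(input_width=cfg.window_seconds, seed=fold_seed)
    x_val = np.concatenate([images[ch][val_idx] for ch in cfg.channels_train])
    y_val = np.tile(y[val_idx], len(cfg.channels_train))
    model.fit(x_train, y_train, replace(cfg.train, seed=fold_seed), validation=(x_val, y_val))

    val_probs = {ch: model.predict_proba(images[ch][val_idx]) for ch in TEST_CHANNELS}
    fusion = fit_fusion(
        [
            PairedSoftmaxSample(
                s_oz=val_probs["Oz"][i],
                s_t7=val_probs["T7"][i],
                s_t8=val_probs["T8"][i],
                trial_id=int(val_idx[i]),
            )
            for i in range(val_idx.size)
        ]
    )

    test_probs = {ch: model.predict_proba(images[ch][test_idx]) for ch in TEST_CHANNELS}
    preds = {ch: test_probs[ch].argmax(axis=1) for ch in TEST_CHANNELS}
    preds["regressed"] = apply_fusion_batch(
        fusion, test_probs["T7"], test_probs["T8"]
    ).argmax(axis=1)

    outcome: dict[str, list[tuple[int, bool]]] = {}
    for cond, p in preds.items():
        outcome[cond] = [
            (int(subjects[ti]), bool(p[i] == y[ti]))
            for i, ti in enumerate(test_idx)
        ]
    return outcome


def _aggregate(
    outcomes: dict[str, list[tuple[int, bool]]],
    cfg: SchemeConfig,
    n_classes: int,
    n_models: int,
) -> EvalReport:
    t_select = cfg.window_seconds + GAZE_SHIFT_SECONDS
    per_subject: dict[str, dict[int, float]] = {}
    for cond in ("Oz", "T7", "T8", "regressed"):
        tally: dict[int, list[bool]] = {}
        for subj, ok in outcomes[cond]:
            tally.setdefault(subj, []).append(ok)
        per_subject[cond] = {s: float(np.mean(v)) for s, v in sorted(tally.items())}
    per_subject["avT7T8"] = {
        s: 0.5 * (per_subject["T7"][s] + per_subject["T8"][s])
        for s in per_subject["T7"]
        if s in per_subject["T8"]
    }

    conditions: dict[str, ConditionResult] = {}
    for cond in CONDITIONS:
        if cond == "avT7T8":
            mean_acc = 0.5 * (
                float(np.mean([ok for _, ok in outcomes["T7"]]))
                + float(np.mean([ok for _, ok in outcomes["T8"]]))
            )
        else:
            mean_acc = float(np.mean([ok for _, ok in outcomes[cond]]))
        conditions[cond] = ConditionResult(
            condition=cond,
            mean_accuracy=mean_acc,
            per_subject=per_subject[cond],
            itr=itr_bits_per_min(mean_acc, n_classes, t_select),
        )

    shared = sorted(
        set(per_subject["regressed"]) & set(per_subject["avT7T8"])
    )
    if len(shared) >= 2:
        a = [per_subject["regressed"][s] for s in shared]
        b = [per_subject["avT7T8"][s] for s in shared]
        _, p = paired_comparison(a, b)
        conditions["regressed"].p_value_vs_avt7t8 = p
    return EvalReport(
        scheme=cfg.scheme,
        window_seconds=cfg.window_seconds,
        seed=cfg.seed,
        n_models=n_models,
        conditions=conditions,
    )


def _merge(
    total: dict[str, list[tuple[int, bool]]], part: dict[str, list[tuple[int, bool]]]
) -> None:
    for cond, pairs in part.items():
        total.setdefault(cond, []).extend(pairs)


def run_subject_dependent(
    trials: Sequence[MultiChannelTrial], cfg: SchemeConfig
) -> EvalReport:
    """Pooled-subject evaluation: five stratified 90/10 trial resamples.

    Per fold, 90 percent of the trials (all nine channel views) train the
    CNN with a slice held out as validation for the fusion fit; the
    remaining 10 percent are tested through Oz, T7, T8 and the regressed
    binaural classifier.
    """
    cfg = replace(cfg, scheme="subject-dependent")
    trials = list(trials)
    _check_channels(trials, cfg.channels_train)
    class_labels = sorted({tr.label_freq for tr in trials})
    y = np.array([class_labels.index(tr.label_freq) for tr in trials])
    subjects = np.array([tr.subject_id for tr in trials])
    images = _spectrogram_arrays(trials, cfg.channels_train, cfg.window_seconds)

    outcomes: dict[str, list[tuple[int, bool]]] = {}
    for fold in range(cfg.n_folds):
        fold_seed = int(
            np.random.SeedSequence([cfg.seed, 271, fold]).generate_state(1)[0] % (2**31)
        )
        rng = np.random.default_rng(fold_seed)
        train_idx, test_idx = _stratified_split(y, cfg.train_fraction, rng)
        fit_rel, val_rel = _validation_split(y[train_idx], cfg.val_fraction, rng)
        fit_idx, val_idx = train_idx[fit_rel], train_idx[val_rel]
        _merge(
            outcomes,
            _fit_and_score_fold(
                images, y, subjects, fit_idx, val_idx, test_idx, cfg, fold_seed
            ),
        )
    return _aggregate(outcomes, cfg, len(class_labels), cfg.n_folds)


def run_subject_independent(
    trials: Sequence[MultiChannelTrial], cfg: SchemeConfig
) -> EvalReport:
    """Leave-one-group-out evaluation over disjoint subject groups.

    Subjects are shuffled into ``n_groups`` equal groups; each group is
    tested against a model trained (and fusion-fitted) exclusively on the
    other groups, so no test subject's data ever enters training.
    """
    cfg = replace(cfg, scheme="subject-independent")
    trials = list(trials)
    _check_channels(trials, cfg.channels_train)
    class_labels = sorted({tr.label_freq for tr in trials})
    y = np.array([class_labels.index(tr.label_freq) for tr in trials])
    subjects = np.array([tr.subject_id for tr in trials])
    subject_set = sorted(set(subjects.tolist()))
    if len(subject_set) % cfg.n_groups:
        raise ValueError(
            f"{len(subject_set)} subjects cannot be divided into "
            f"{cfg.n_groups} equal groups"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 9176]))
    order = rng.permutation(subject_set)
    groups = [
        sorted(order[i :: cfg.n_groups].tolist()) for i in range(cfg.n_groups)
    ]
    flat = [s for g in groups for s in g]
    if len(set(flat)) != len(flat):
        raise ValueError("a subject appears in more than one group")
    images = _spectrogram_arrays(trials, cfg.channels_train, cfg.window_seconds)

    outcomes: dict[str, list[tuple[int, bool]]] = {}
    for gi, group in enumerate(groups):
        test_mask = np.isin(subjects, group)
        test_idx = np.flatnonzero(test_mask)
        train_pool = np.flatnonzero(~test_mask)
        assert not set(subjects[train_pool]) & set(subjects[test_idx]), "subject leakage"
        fold_seed = int(
            np.random.SeedSequence([cfg.seed, 653, gi]).generate_state(1)[0] % (2**31)
        )
        grng = np.random.default_rng(fold_seed)
        fit_rel, val_rel = _validation_split(y[train_pool], cfg.val_fraction, grng)
        fit_idx, val_idx = train_pool[fit_rel], train_pool[val_rel]
        _merge(
            outcomes,
            _fit_and_score_fold(
                images, y, subjects, fit_idx, val_idx, test_idx, cfg, fold_seed
            ),
        )
    return _aggregate(outcomes, cfg, len(class_labels), cfg.n_groups)


def sweep_windows(
    trials: Sequence[MultiChannelTrial],
    cfg: SchemeConfig,
    windows: Iterable[int] = (1, 2, 3, 4, 5),
) -> dict[int, EvalReport]:
    """One report per window length; ITR uses T = window + 0.55 s gaze shift."""
    windows = sorted(set(int(w) for w in windows))
    if any(w < 1 or w > 5 for w in windows):
        raise ValueError("window lengths must lie in 1..5 seconds")
    runner = (
        run_subject_dependent
        if cfg.scheme == "subject-dependent"
        else run_subject_independent
    )
    return {w: runner(trials, replace(cfg, window_seconds=w)) for w in windows}


# ---------------------------------------------------------------------------
# benchmark-compatible MAT adapter


def load_benchmark_mat(
    path,
    channels: Sequence[str] | None = None,
    freqs: Sequence[float] = REQUIRED_FREQS,
    fs: float = 250.0,
) -> list[MultiChannelTrial]:
    """Read one subject's trials from the channels x samples x targets x blocks
    MAT layout, restricted to the nine harness channels and the three target
    frequencies, keeping the 1250-sample valid segment of each trial."""
    mat = loadmat(str(path), squeeze_me=True)
    for key in ("data", "channels", "freqs"):
        if key not in mat:
            raise ValueError(f"MAT file {path} lacks required variable {key!r}")
    data = np.asarray(mat["data"], dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"expected a channels x samples x targets x blocks array, got shape {data.shape}"
        )
    file_channels = [str(c) for c in np.atleast_1d(mat["channels"])]
    file_freqs = [float(f) for f in np.atleast_1d(mat["freqs"])]
    if len(file_channels) != data.shape[0]:
        raise ValueError("channel name table does not match the data array")
    wanted = list(channels) if channels is not None else list(HARNESS_CHANNELS)
    missing_ch = [c for c in wanted if c not in file_channels]
    if missing_ch:
        raise ValueError(f"MAT file {path} is missing channel(s) {missing_ch}")
    missing_f = [f for f in freqs if f not in file_freqs]
    if missing_f:
        raise ValueError(
            f"MAT file {path} is missing target frequencies {missing_f} Hz"
        )
    n_samples = data.shape[1]
    if n_samples < VALID_SAMPLES:
        raise ValueError(
            f"trials have {n_samples} samples; need at least {VALID_SAMPLES}"
        )
    start = min(int(2 * fs), n_samples - VALID_SAMPLES)
    subject = int(mat.get("subject", 0))
    ch_rows = {c: file_channels.index(c) for c in wanted}
    trials = []
    for bi in range(data.shape[3]):
        for f in freqs:
            fi = file_freqs.index(f)
            samples = {
                c: data[r, start : start + VALID_SAMPLES, fi, bi].copy()
                for c, r in ch_rows.items()
            }
            trials.append(
                MultiChannelTrial(
                    samples=samples,
                    label_freq=float(f),
                    subject_id=subject,
                    block_id=bi,
                )
            )
    return trials
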