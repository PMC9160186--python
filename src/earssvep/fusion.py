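"""Binaural softmax fusion by linear regression.

For each of the three output nodes, an ordinary-least-squares model maps the
(T7, T8) softmax readings of a trial to the Oz softmax of the same trial:

    s_oz[j] ~ b0_j + b1_j * s_t7[j] + b2_j * s_t8[j]

The fit uses paired samples from the validation partition only. At test
time the T7/T8 softmax outputs are pushed through the fitted maps to form
"re-estimated" Oz-like scores; only their argmax is consumed downstream, so
the scores are neither clipped nor renormalized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cnn import SoftmaxTriple

__all__ = [
    "PairedSoftmaxSample",
    "FusionModel",
    "fit_fusion",
    "apply_fusion",
    "apply_fusion_batch",
    "classify_binaural",
]

_MIN_SAMPLES = 4  # intercept + 2 slopes per node, plus one residual df


def _probs(s) -> np.ndarray:
    return np.asarray(s.probs if isinstance(s, SoftmaxTriple) else s, dtype=float)


@dataclass(frozen=True)
class PairedSoftmaxSample:
    """Softmax triples of the same trial seen through Oz, T7 and T8."""

    s_oz: np.ndarray | SoftmaxTriple
    s_t7: np.ndarray | SoftmaxTriple
    s_t8: np.ndarray | SoftmaxTriple
    trial_id: object = None


@dataclass(frozen=True)
class FusionModel:
    """Per-node linear coefficients (intercept, T7 weight, T8 weight)."""

    coef: np.ndarray  # (n_nodes, 3)
    residual_var: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        c = np.asarray(self.coef, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coef must be (n_nodes, 3): intercept, T7, T8 per node")
        if not np.all(np.isfinite(c)):
            raise ValueError("fusion coefficients must be finite")

    @property
    def n_nodes(self) -> int:
        return self.coef.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                f"node_{j}": {
                    "intercept": self.coef[j, 0],
                    "t7": self.coef[j, 1],
                    "t8": self.coef[j, 2],
                    "residual_var": (
                        None
                        if self.residual_var is None
                        else float(self.residual_var[j])
                    ),
                }
                for j in range(self.n_nodes)
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FusionModel":
        d = json.loads(text)
        nodes = sorted(d, key=lambda k: int(k.split("_")[1]))
        coef = np.array(
            [[d[k]["intercept"], d[k]["t7"], d[k]["t8"]] for k in nodes]
        )
        rv = [d[k].get("residual_var") for k in nodes]
        rvar = None if any(v is None for v in rv) else np.asarray(rv, dtype=float)
        return cls(coef=coef, residual_var=rvar)


def fit_fusion(samples: Iterable[PairedSoftmaxSample]) -> FusionModel:
    """Least-squares fit of the per-node (T7, T8) -> Oz maps.

    Rank-deficient designs (for instance T7 identical to T8 on every
    sample) are solved by the pseudoinverse, giving the minimum-norm
    coefficient vector rather than a failure.
    """
    samples = list(samples)
    if len(samples) < _MIN_SAMPLES:
        raise ValueError(
            f"fusion needs at least {_MIN_SAMPLES} paired samples, got {len(samples)}"
        )
    oz = np.stack([_probs(s.s_oz) for s in samples])
    t7 = np.stack([_probs(s.s_t7) for s in samples])
    t8 = np.stack([_probs(s.s_t8) for s in samples])
    if not (np.isfinite(oz).all() and np.isfinite(t7).all() and np.isfinite(t8).all()):
        raise ValueError("paired softmax inputs must be finite")
    n_nodes = oz.shape[1]
    coef = np.empty((n_nodes, 3))
    rvar = np.empty(n_nodes)
    for j in range(n_nodes):
        design = np.column_stack([np.ones(len(samples)), t7[:, j], t8[:, j]])
        beta, _, _, _ = np.linalg.lstsq(design, oz[:, j], rcond=None)
        coef[j] = beta
        resid = oz[:, j] - design @ beta
        rvar[j] = float(np.mean(resid**2))
    return FusionModel(coef=coef, residual_var=rvar)


def apply_fusion(model: FusionModel, s_t7, s_t8) -> np.ndarray:
    """Re-estimated per-node scores; unbounded, argmax-only semantics."""
    if model is None:
        raise ValueError("fusion model is not fitted")
    t7 = _probs(s_t7)
    t8 = _probs(s_t8)
    return model.coef[:, 0] + model.coef[:, 1] * t7 + model.coef[:, 2] * t8


def apply_fusion_batch(model: FusionModel, t7: np.ndarray, t8: np.ndarray) -> np.ndarray:
    """Vectorized :func:`apply_fusion` over (n_samples, n_nodes) arrays."""
    t7 = np.asarray(t7, dtype=float)
    t8 = np.asarray(t8, dtype=float)
    return model.coef[:, 0] + model.coef[:, 1] * t7 + model.coef[:, 2] * t8


def classify_binaural(model: FusionModel, s_t7, s_t8) -> int:
    """Predicted class index from re-estimated scores (ties to lowest index)."""
    return int(np.argmax(apply_fusion(model, s_t7, s_t8)))
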