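"""Cross-entropy and class-weighted focal loss.

For a beat whose true class receives softmax probability ``p_t``, the
cross-entropy loss is ``CE = -log p_t`` and the focal loss is

    L_f = -a_t * (1 - p_t)**gamma * log p_t

where ``a_t`` is the weight of the true class and ``gamma >= 0`` the
focusing exponent.  The modulating factor ``(1 - p_t)**gamma`` shrinks
the loss of confidently-correct (easy) beats, steering training toward
the hard ones — here chiefly the supraventricular ectopic beats, whose
morphology is nearly normal.  Defaults: ``gamma = 2.35`` and weights
N:S:V:F:Q = 1.6 : 1.8 : 0.8 : 1.0 : 1.0 (a stated ratio; the global
scale is immaterial, it only rescales the learning rate).

With ``gamma = 0`` and unit weights the focal loss reduces exactly to
cross-entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import AAMI_CLASSES, AamiClass

__all__ = [
    "FocalLossParams",
    "DEFAULT_CLASS_WEIGHTS",
    "EPSILON",
    "cross_entropy",
    "focal_loss",
    "batch_focal_loss",
    "focal_loss_and_grad",
]

#: Numerical floor applied to p_t before the log, so a degenerate
#: probability yields a large finite loss instead of infinity.
EPSILON = 1e-12

DEFAULT_CLASS_WEIGHTS: dict[AamiClass, float] = {
    AamiClass.N: 1.6,
    AamiClass.S: 1.8,
    AamiClass.V: 0.8,
    AamiClass.F: 1.0,
    AamiClass.Q: 1.0,
}


@dataclass(frozen=True)
class FocalLossParams:
    """Focusing exponent gamma and per-class weights a_t."""

    gamma: float = 2.35
    class_weights: Mapping[AamiClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )

    def __post_init__(self) -> None:
        if not np.isfinite(self.gamma) or self.gamma < 0:
            raise ValueError("gamma must be finite and >= 0")
        for cls in AAMI_CLASSES:
            w = self.class_weights.get(cls)
            if w is None or w <= 0:
                raise ValueError(f"class weight for {cls.value} must be > 0")

    def weight_vector(self) -> np.ndarray:
        """Weights as a length-5 array in canonical N,S,V,F,Q order."""
        return np.array([self.class_weights[c] for c in AAMI_CLASSES])

    @classmethod
    def cross_entropy_equivalent(cls) -> "FocalLossParams":
        """gamma=0, unit weights: focal loss degenerates to cross-entropy."""
        return cls(gamma=0.0, class_weights={c: 1.0 for c in AAMI_CLASSES})


def _floor_probability(p_true: float | np.ndarray) -> np.ndarray:
    p = np.asarray(p_true, dtype=np.float64)
    if np.any(p <= 0):
        warnings.warn(
            f"true-class probability <= 0 clamped to {EPSILON}",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.clip(p, EPSILON, 1.0)


def cross_entropy(p_true: float | np.ndarray) -> float | np.ndarray:
    """``-log p_t`` (natural log), with ``p_t`` floored at :data:`EPSILON`."""
    out = -np.log(_floor_probability(p_true))
    return float(out) if np.isscalar(p_true) else out


def focal_loss(
    p_true: float, true_class: AamiClass, params: FocalLossParams
) -> float:
    """``a_t * (1 - p_t)**gamma * (-log p_t)`` for one beat."""
    p = float(_floor_probability(p_true))
    a_t = params.class_weights[true_class]
    return a_t * (1.0 - p) ** params.gamma * -np.log(p)


def batch_focal_loss(
    batch: list[tuple[Mapping[AamiClass, float], AamiClass]],
    params: FocalLossParams,
) -> float:
    """Mean focal loss over ``(class-probabilities, true label)`` pairs."""
    if not batch:
        raise ValueError("batch_focal_loss requires a non-empty batch")
    total = 0.0
    for probs, label in batch:
        total += focal_loss(probs[label], label, params)
    return total / len(batch)


def focal_loss_and_grad(
    probs: np.ndarray, true_idx: np.ndarray, params: FocalLossParams
) -> tuple[float, np.ndarray]:
    """Mean focal loss of a batch and its gradient w.r.t. the logits.

    ``probs`` is the (batch, 5) softmax output and ``true_idx`` the true
    class index per row.  Writing ``g(p) = a_t (1-p)^gamma (-log p)``,

        dL/dp_t = a_t [ gamma (1-p_t)^(gamma-1) log p_t - (1-p_t)^gamma / p_t ]
        dL/dz_j = dL/dp_t * p_t (delta_tj - p_j)

    which reduces to the familiar softmax-CE gradient ``p - onehot`` at
    gamma=0 with unit weights.
    """
    n = len(true_idx)
    rows = np.arange(n)
    p_t = np.clip(probs[rows, true_idx], EPSILON, 1.0)
    a = params.weight_vector()[true_idx]
    gamma = params.gamma
    one_minus = 1.0 - p_t
    loss = float(np.mean(a * one_minus**gamma * -np.log(p_t)))

    if gamma == 0.0:
        dldp = -a / p_t
    else:
        # (1-p)^(gamma-1) diverges at p=1 only for gamma<1; clamp the base
        base = np.maximum(one_minus, EPSILON)
        dldp = a * (gamma * base ** (gamma - 1.0) * np.log(p_t) - one_minus**gamma / p_t)
    # chain through softmax: dz_j = dldp * p_t * (delta_tj - p_j)
    grad = -probs * (dldp * p_t)[:, None]
    grad[rows, true_idx] += dldp * p_t
    return loss, grad / n
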