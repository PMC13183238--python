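"""Slide-weighted classification loss for imbalanced dense detection.

The slide weight is a piecewise function of a sample's localization quality
(IoU ``x``) around a difficulty threshold ``mu``:

* easy-to-miss, poorly localized samples (``x <= mu - 0.1``) keep weight 1,
* boundary samples in the transition interval ``(mu - 0.1, mu)`` are
  up-weighted by the constant ``e**(1 - mu)``,
* well-localized samples (``x >= mu``) are exponentially down-weighted by
  ``e**(1 - x)``.

The weight multiplies the per-sample binary cross-entropy, shifting training
focus onto hard samples near the decision boundary.  ``mu`` is the mean IoU
of the training set, either fixed or tracked online (``auto_mu``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SlideLossParams",
    "slide_weight",
    "bce",
    "slide_cls_loss",
    "estimate_mu",
    "RunningMeanIoU",
]


@dataclass
class SlideLossParams:
    """Parameters of the slide weighting function.

    mu : difficulty threshold in [0, 1] (typically the training-set mean IoU)
    transition_width : width of the up-weighted boundary interval (0.1)
    auto_mu : refresh mu from a running mean of assigned-sample IoUs
    """

    mu: float = 0.5
    transition_width: float = 0.1
    auto_mu: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if self.transition_width < 0:
            raise ValueError("transition_width must be nonnegative")


def slide_weight(x, params: SlideLossParams | float):
    """Piecewise slide weight f(x) for IoU value(s) ``x``.

    Returns 1 for ``x <= mu - 0.1``, ``e**(1 - mu)`` on the open transition
    interval ``(mu - 0.1, mu)`` and ``e**(1 - x)`` for ``x >= mu``.  Accepts a
    scalar or an array; raises if any input leaves [0, 1].
    """
    if isinstance(params, (int, float)):
        params = SlideLossParams(mu=float(params))
    mu = params.mu
    w = params.transition_width
    xs = np.asarray(x, dtype=np.float64)
    if np.any(xs < 0.0) or np.any(xs > 1.0):
        raise ValueError("IoU values must lie in [0, 1]")
    out = np.where(
        xs <= mu - w,
        1.0,
        np.where(xs < mu, np.exp(1.0 - mu), np.exp(1.0 - xs)),
    )
    if np.isscalar(x):
        return float(out)
    return out


def bce(pred, target, eps: float = 1e-12):
    """Elementwise binary cross-entropy, prediction clipped away from {0,1}."""
    p = np.clip(np.asarray(pred, dtype=np.float64), eps, 1.0 - eps)
    t = np.asarray(target, dtype=np.float64)
    return -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))


def slide_cls_loss(pred_scores, targets, ious, params: SlideLossParams) -> float:
    """Mean slide-weighted BCE over a batch of aligned samples.

    ``pred_scores`` are class probabilities in (0, 1), ``targets`` the 0/1
    labels, ``ious`` the per-sample localization quality that drives the
    weight.  With every IoU in the weight-1 region this reduces to plain BCE.
    """
    p = np.asarray(pred_scores, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    x = np.asarray(ious, dtype=np.float64)
    if not (p.shape[0] == t.shape[0] == x.shape[0]):
        raise ValueError(
            f"length mismatch: scores {p.shape[0]}, targets {t.shape[0]}, ious {x.shape[0]}"
        )
    w = slide_weight(x, params)
    per_sample = bce(p, t)
    if per_sample.ndim > 1:  # multi-class rows share their sample's weight
        per_sample = per_sample.mean(axis=tuple(range(1, per_sample.ndim)))
    return float(np.mean(w * per_sample))


def estimate_mu(training_ious) -> float:
    """Arithmetic mean IoU of the training set: the slide threshold mu."""
    arr = np.asarray(training_ious, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot estimate mu from an empty IoU list")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("IoU values must lie in [0, 1]")
    return float(arr.mean())


@dataclass
class RunningMeanIoU:
    """Exponential moving average of assigned-sample IoUs.

    Updated per batch during training; a per-epoch snapshot refreshes mu when
    ``auto_mu`` is on.  ``momentum`` close to 1 gives a long memory.
    """

    momentum: float = 0.98
    mean: float = 0.5
    _initialized: bool = field(default=False, repr=False)

    def update(self, batch_ious) -> float:
        arr = np.asarray(batch_ious, dtype=np.float64)
        if arr.size == 0:
            return self.mean
        m = float(arr.mean())
        if not self._initialized:
            self.mean = m
            self._initialized = True
        else:
            self.mean = self.momentum * self.mean + (1.0 - self.momentum) * m
        return self.mean
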