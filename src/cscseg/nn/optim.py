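"""Adam optimizer and the binary cross-entropy loss used by every stage."""

from __future__ import annotations

import numpy as np

from .core import Param

__all__ = ["Adam", "bce_loss", "bce_loss_grad", "BCE_EPS"]

#: predictions are clamped to [BCE_EPS, 1 - BCE_EPS] inside the loss
BCE_EPS = 1e-7


class Adam:
    """Adam with bias correction; frozen parameters are never touched."""

    def __init__(self, params: list[Param], lr: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if not p.frozen]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.data -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def _clamped(pred: np.ndarray) -> np.ndarray:
    return np.clip(pred, BCE_EPS, 1.0 - BCE_EPS)


def bce_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean per-pixel binary cross-entropy, predictions clamped away from {0,1}.

    Targets may be soft (in [0,1]); shapes must match exactly.
    """
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    p = _clamped(np.asarray(pred, dtype=np.float64))
    t = np.asarray(target, dtype=np.float64)
    return float(-(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean())


def bce_loss_grad(pred: np.ndarray, target: np.ndarray,
                  grad_cap: float | None = 100.0) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the (clamped) prediction.

    ``grad_cap`` bounds the per-pixel magnitude of dL/dp.  Predictions that
    saturate the clamp would otherwise contribute gradients of order
    1/BCE_EPS and drown every other pixel in the batch — this matters for
    the additively fused output, whose straight-through clip can sit exactly
    on the clamp boundary.  A cap of 100 corresponds to evaluating the
    gradient with p clamped to roughly [1e-2, 1 - 1e-2].
    """
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    p = _clamped(np.asarray(pred, dtype=np.float64))
    t = np.asarray(target, dtype=np.float64)
    loss = float(-(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean())
    grad = (p - t) / (p * (1.0 - p))
    if grad_cap is not None:
        np.clip(grad, -grad_cap, grad_cap, out=grad)
    return loss, (grad / p.size).astype(np.float32)
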