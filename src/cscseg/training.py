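"""Two-phase training with checkpointing and validation-based selection.

Phase 1 trains the context autoencoder: the context encoder plus a
reconstruction decoder are fitted to reproduce the six cropped context
frames; the decoder is then discarded and the encoder frozen.  Phase 2
trains the U-net and the calibration decoder jointly against ground-truth
labels through the additive fusion, with the encoder and the global
backbone frozen.  Both phases use per-pixel binary cross-entropy, Adam at
learning rate 0.001, batch size 12, and keep a parameter snapshot every
five epochs; the snapshot with the lowest validation loss is selected
(earliest epoch on ties).

Training functions operate on pre-assembled arrays; sample assembly from
clips lives in :mod:`cscseg.model`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import Adam, CalibDecoder, ContextEncoder, UNet, bce_loss, bce_loss_grad

__all__ = ["TrainConfig", "Checkpoint", "select_checkpoint",
           "train_phase1", "train_phase2"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 12
    learning_rate: float = 0.001
    checkpoint_interval: int = 5
    seed: int = 0
    adam_betas: tuple[float, float] = (0.9, 0.999)

    def __post_init__(self):
        if self.epochs < 1 or self.checkpoint_interval < 1 or self.batch_size < 1:
            raise ValueError("epochs, batch_size and checkpoint_interval must be >= 1")


@dataclass
class Checkpoint:
    epoch: int
    state: dict[str, dict[str, np.ndarray]]  # network name -> state dict
    validation_loss: float

    def __post_init__(self):
        if not np.isfinite(self.validation_loss):
            raise ValueError("validation loss must be finite")


def select_checkpoint(checkpoints: list[Checkpoint]) -> Checkpoint:
    """The checkpoint with minimal validation loss; ties -> earliest epoch."""
    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    return min(checkpoints, key=lambda c: (c.validation_loss, c.epoch))


def _batches(n: int, batch_size: int, order: np.ndarray, drop_last: bool = False):
    """Yield index batches; with ``drop_last`` an incomplete trailing batch
    is skipped (unless it is the only one) — tiny batches would otherwise
    poison the batch-norm running statistics."""
    last_full = (n // batch_size) * batch_size
    stop = last_full if (drop_last and last_full > 0) else n
    for i in range(0, stop, batch_size):
        yield order[i:i + batch_size]


def _ckpt_epochs(cfg: TrainConfig) -> set[int]:
    eps = set(range(cfg.checkpoint_interval, cfg.epochs + 1, cfg.checkpoint_interval))
    eps.add(cfg.epochs)
    return eps


def train_phase1(encoder: ContextEncoder, recon: CalibDecoder,
                 ctx_train: np.ndarray, ctx_val: np.ndarray,
                 cfg: TrainConfig) -> tuple[pd.DataFrame, list[Checkpoint]]:
    """Fit the context autoencoder to reconstruct its six input frames.

    ``ctx_*``: (N, S, S, 6) float32 normalized to [-1, 1].  Reconstruction
    targets are the same frames mapped to [0, 1].  On return the encoder
    (and recon decoder) hold the best checkpoint's parameters.
    """
    if ctx_train.shape[0] == 0:
        raise ValueError("empty training set")
    if recon.glob_dim != 0:
        raise ValueError("reconstruction decoder must have glob_dim=0")
    y_train = 0.5 * (ctx_train + 1.0)
    y_val = 0.5 * (ctx_val + 1.0)
    opt = Adam(encoder.params() + recon.params(), lr=cfg.learning_rate, betas=cfg.adam_betas)
    rng = np.random.default_rng(cfg.seed)
    n = ctx_train.shape[0]
    rows, checkpoints = [], []

    def val_loss() -> float:
        losses, counts = [], []
        for idx in _batches(ctx_val.shape[0], cfg.batch_size, np.arange(ctx_val.shape[0])):
            rec = recon.forward(encoder.forward(ctx_val[idx]), None)
            losses.append(bce_loss(rec, y_val[idx]))
            counts.append(len(idx))
        return float(np.average(losses, weights=counts)) if losses else float("nan")

    ckpt_at = _ckpt_epochs(cfg)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        ep = 0.0
        seen = 0
        for idx in _batches(n, cfg.batch_size, order, drop_last=True):
            emb = encoder.forward(ctx_train[idx], train=True)
            rec = recon.forward(emb, None, train=True)
            loss, grad = bce_loss_grad(rec, y_train[idx])
            opt.zero_grad()
            encoder.backward(recon.backward(grad))
            opt.step()
            ep += loss * len(idx)
            seen += len(idx)
        vl = val_loss() if epoch in ckpt_at else np.nan
        rows.append((epoch, ep / seen, vl))
        if epoch in ckpt_at:
            checkpoints.append(Checkpoint(
                epoch=epoch,
                state={"encoder": encoder.state_dict(), "recon": recon.state_dict()},
                validation_loss=vl))
    best = select_checkpoint(checkpoints)
    encoder.load_state_dict(best.state["encoder"])
    recon.load_state_dict(best.state["recon"])
    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss"])
    return history, checkpoints


def train_phase2(unet: UNet, decoder: CalibDecoder | None,
                 x_train: np.ndarray, y_train: np.ndarray,
                 x_val: np.ndarray, y_val: np.ndarray,
                 cfg: TrainConfig,
                 ctx_train: np.ndarray | None = None, glob_train: np.ndarray | None = None,
                 ctx_val: np.ndarray | None = None, glob_val: np.ndarray | None = None,
                 ) -> tuple[pd.DataFrame, list[Checkpoint]]:
    """Jointly fit the U-net and (optionally) the calibration decoder.

    ``x_*``: (N, S, S, 1) normalized crops; ``y_*``: (N, S, S, 1) binary
    labels; ``ctx_*``: (N, h, w, C) *precomputed frozen-encoder embeddings*;
    ``glob_*``: (N, 2048) precomputed frozen-backbone embeddings (may be
    None when the decoder has no global branch).  Only the U-net and decoder
    parameters are updated; the fused prediction clip(seg + cali, 0, 1)
    passes gradients straight through the clip to both heads.
    """
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")
    use_cali = decoder is not None
    if use_cali and ctx_train is None:
        raise ValueError("calibration decoder given but no context embeddings "
                         "(run phase 1 first)")
    params = unet.params() + (decoder.params() if use_cali else [])
    opt = Adam(params, lr=cfg.learning_rate, betas=cfg.adam_betas)
    rng = np.random.default_rng(cfg.seed)
    n = x_train.shape[0]

    def forward(xb, cb, gb, train):
        seg = unet.forward(xb, train=train)
        if not use_cali:
            return seg, seg, None
        cali = decoder.forward(cb, gb, train=train)
        return np.clip(seg + cali, 0.0, 1.0), seg, cali

    def val_loss() -> float:
        losses, counts = [], []
        for idx in _batches(x_val.shape[0], cfg.batch_size, np.arange(x_val.shape[0])):
            cb = ctx_val[idx] if use_cali else None
            gb = glob_val[idx] if (use_cali and glob_val is not None) else None
            fused, _, _ = forward(x_val[idx], cb, gb, train=False)
            losses.append(bce_loss(fused, y_val[idx]))
            counts.append(len(idx))
        return float(np.average(losses, weights=counts)) if losses else float("nan")

    rows, checkpoints = [], []
    ckpt_at = _ckpt_epochs(cfg)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        ep = 0.0
        seen = 0
        for idx in _batches(n, cfg.batch_size, order, drop_last=True):
            cb = ctx_train[idx] if use_cali else None
            gb = glob_train[idx] if (use_cali and glob_train is not None) else None
            fused, seg, cali = forward(x_train[idx], cb, gb, train=True)
            loss, grad = bce_loss_grad(fused, y_train[idx])
            opt.zero_grad()
            unet.backward(grad)          # straight-through the clip
            if use_cali:
                decoder.backward(grad)   # context/global inputs are frozen
            opt.step()
            ep += loss * len(idx)
            seen += len(idx)
        vl = val_loss() if epoch in ckpt_at else np.nan
        rows.append((epoch, ep / seen, vl))
        if epoch in ckpt_at:
            state = {"unet": unet.state_dict()}
            if use_cali:
                state["decoder"] = decoder.state_dict()
            checkpoints.append(Checkpoint(epoch=epoch, state=state, validation_loss=vl))
    best = select_checkpoint(checkpoints)
    unet.load_state_dict(best.state["unet"])
    if use_cali:
        decoder.load_state_dict(best.state["decoder"])
    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss"])
    return history, checkpoints
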