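"""Training loop: binary cross-entropy on ordinal masks with Adadelta.

The model is weakly supervised: every tissue pixel of a slide inherits the
slide's ordinal age label, so the loss is ordinary per-pixel, per-channel
binary cross-entropy between the sigmoid probability mask and the ordinal
mask.  Background pixels participate with all-zero targets by default
(the ordinal mask is zero off tissue); a tissue-only loss is available.

Held-out slides are split off *by slide* and stratified by age group so no
tile of a held-out slide ever contributes a gradient; the held-out loss is
recorded every epoch to monitor convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import linknet, nn
from .linknet import LinkNet, ModelConfig
from .nn import F32

__all__ = [
    "TrainConfig",
    "LossHistory",
    "bce_loss",
    "split_holdout",
    "train",
    "convergence_summary",
]

_CLIP_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    batch_size: int = 20
    rho: float = 0.9
    adadelta_eps: float = 1e-6
    lr_scale: float = 1.0
    holdout_fraction: float = 0.2
    seed: int = 0
    loss_on_background: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in [0, 1)")


@dataclass
class LossHistory:
    """Per-epoch mean training loss and held-out loss."""

    train_loss: list[float] = field(default_factory=list)
    holdout_loss: list[float] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "holdout_loss": self.holdout_loss,
            }
        )


def bce_loss(
    probabilities: np.ndarray,
    targets: np.ndarray,
    mask: np.ndarray | None = None,
    eps: float = _CLIP_EPS,
) -> float:
    """Mean binary cross-entropy over pixels x channels (x batch).

    Probabilities are clipped to [eps, 1-eps] before the logs.  With a
    ``mask`` (broadcastable to the target shape) the mean runs over masked
    elements only.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs targets {t.shape}")
    p = np.clip(p, eps, 1.0 - eps)
    ll = -(t * np.log(p) + (1.0 - t) * np.log1p(-p))
    if mask is None:
        return float(ll.mean())
    m = np.broadcast_to(np.asarray(mask, dtype=bool), ll.shape)
    if not m.any():
        raise ValueError("loss mask selects no elements")
    return float(ll[m].mean())


def split_holdout(
    manifest: pd.DataFrame, fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Stratified slide-level train/holdout split.

    Splitting is by slide, never by tile, and stratified by age group:
    ``round(fraction * n_group)`` slides are held out from each group.
    Deterministic for a given seed.  A group with fewer than 2 slides
    cannot be split and is rejected (when ``fraction > 0``).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return sorted(manifest["slide_id"]), []
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    train_ids: list[str] = []
    holdout_ids: list[str] = []
    for age, grp in sorted(manifest.groupby("age_months"), key=lambda kv: kv[0]):
        ids = sorted(grp["slide_id"])
        if len(ids) < 2:
            raise ValueError(
                f"age group {age} months has {len(ids)} slide(s); need >= 2 to hold one out"
            )
        n_hold = int(round(fraction * len(ids)))
        n_hold = min(max(n_hold, 0), len(ids) - 1)
        perm = rng.permutation(len(ids))
        holdout_ids += [ids[i] for i in perm[:n_hold]]
        train_ids += [ids[i] for i in perm[n_hold:]]
    return sorted(train_ids), sorted(holdout_ids)


def _loss_and_grad(
    model: LinkNet, logits: np.ndarray, targets: np.ndarray, mask: np.ndarray | None
) -> tuple[float, np.ndarray]:
    """BCE loss and its gradient w.r.t. the logits, for either head."""
    t = np.asarray(targets, dtype=np.float64)
    p = model.activate(logits)
    loss = bce_loss(p, t, mask=mask)
    if mask is None:
        weight = np.float64(1.0 / t.size)
        w = weight
    else:
        m = np.broadcast_to(np.asarray(mask, dtype=bool), t.shape)
        w = m / m.sum()
    if model.config.activation_head == "sigmoid":
        dz = (p - t) * w
    else:
        pc = np.clip(p, _CLIP_EPS, 1.0 - _CLIP_EPS)
        dldp = (-(t / pc) + (1.0 - t) / (1.0 - pc)) * w
        dz = p * (dldp - (p * dldp).sum(axis=1, keepdims=True))
    return loss, dz.astype(F32)


def _epoch_loss(model: LinkNet, x: np.ndarray, y: np.ndarray, mask, batch_size: int) -> float:
    """Inference-mode mean loss over a dataset, batched."""
    total, count = 0.0, 0
    for start in range(0, len(x), batch_size):
        xb = x[start : start + batch_size]
        yb = y[start : start + batch_size]
        mb = None if mask is None else mask[start : start + batch_size, None]
        p = model.activate(model.forward(xb, training=False))
        n_elem = yb.size if mb is None else int(np.broadcast_to(mb, yb.shape).sum())
        total += bce_loss(p, yb, mask=mb) * n_elem
        count += n_elem
    return total / count


def train(
    x: np.ndarray,
    y: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
    x_holdout: np.ndarray | None = None,
    y_holdout: np.ndarray | None = None,
    tissue_masks: np.ndarray | None = None,
    holdout_tissue_masks: np.ndarray | None = None,
    checkpoint_dir: str | Path | None = None,
    checkpoint_meta: dict | None = None,
) -> tuple[LinkNet, LossHistory]:
    """Train a model on normalized tiles ``x`` (N,3,H,W) and ordinal masks
    ``y`` (N,K-1,H,W).

    Runs ``epochs x ceil(n/batch)`` Adadelta steps with seeded shuffling
    each epoch and records the mean training loss and held-out loss per
    epoch.  With ``loss_on_background=False`` the loss is restricted to
    tissue pixels (``tissue_masks`` required).  Checkpoints at the final
    and best-holdout epochs are written when ``checkpoint_dir`` is given.
    """
    x = np.ascontiguousarray(x, dtype=F32)
    y = np.ascontiguousarray(y, dtype=np.uint8)
    if len(x) < 1:
        raise ValueError("need at least one training tile")
    if x.shape[0] != y.shape[0] or x.shape[2:] != y.shape[2:]:
        raise ValueError(f"tiles {x.shape} and masks {y.shape} do not align")
    loss_mask = None
    hold_mask = None
    if not train_config.loss_on_background:
        if tissue_masks is None:
            raise ValueError("tissue_masks required when loss_on_background=False")
        loss_mask = np.asarray(tissue_masks, dtype=bool)
        if x_holdout is not None:
            if holdout_tissue_masks is None:
                raise ValueError("holdout_tissue_masks required when loss_on_background=False")
            hold_mask = np.asarray(holdout_tissue_masks, dtype=bool)

    model = linknet.init_model(model_config, seed=train_config.seed)
    if train_config.lr_scale == 0.0:
        # a null update must be a true no-op: freeze running statistics too
        model.set_bn_update(False)
    opt = nn.Adadelta(
        model.params(),
        rho=train_config.rho,
        eps=train_config.adadelta_eps,
        lr=train_config.lr_scale,
    )
    history = LossHistory()
    best_holdout = np.inf
    have_holdout = x_holdout is not None and len(x_holdout) > 0
    if have_holdout:
        x_holdout = np.ascontiguousarray(x_holdout, dtype=F32)
        y_holdout = np.ascontiguousarray(y_holdout, dtype=np.uint8)

    checkpoint_dir = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if checkpoint_dir is not None:
        checkpoint_dir.mkdir(parents=True, exist_ok=True)

    n = len(x)
    for epoch in range(1, train_config.epochs + 1):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(entropy=train_config.seed, spawn_key=(7, epoch)))
        )
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for step, start in enumerate(range(0, n, train_config.batch_size)):
            idx = order[start : start + train_config.batch_size]
            xb, yb = x[idx], y[idx]
            mb = None if loss_mask is None else loss_mask[idx][:, None]
            logits = model.forward(xb, training=True)
            loss, dz = _loss_and_grad(model, logits, yb, mb)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, step {step}")
            model.backward(dz)
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        train_loss = total / seen
        if have_holdout:
            holdout_loss = _epoch_loss(model, x_holdout, y_holdout, hold_mask, train_config.batch_size)
        else:
            holdout_loss = train_loss
        history.train_loss.append(float(train_loss))
        history.holdout_loss.append(float(holdout_loss))
        if checkpoint_dir is not None and holdout_loss < best_holdout:
            best_holdout = holdout_loss
            linknet.save_checkpoint(
                checkpoint_dir / "best.ckpt", model, meta={**(checkpoint_meta or {}), "epoch": epoch}
            )
    if checkpoint_dir is not None:
        linknet.save_checkpoint(
            checkpoint_dir / "final.ckpt",
            model,
            meta={**(checkpoint_meta or {}), "epoch": train_config.epochs},
        )
        history.as_frame().to_csv(checkpoint_dir / "loss_history.csv", index=False)
    return model, history


def convergence_summary(history: LossHistory | list[float], burn_in_epoch: int) -> float:
    """Mean held-out loss over epochs strictly after ``burn_in_epoch``.

    Mirrors the usual convergence read-out: once the loss curve has
    flattened, its post-burn-in average summarizes the converged value.
    """
    losses = history.holdout_loss if isinstance(history, LossHistory) else list(history)
    if burn_in_epoch >= len(losses):
        raise ValueError(f"burn_in_epoch {burn_in_epoch} >= number of epochs {len(losses)}")
    return float(np.mean(losses[burn_in_epoch:]))
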