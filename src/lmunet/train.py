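"""Training and evaluation loops.

All randomness (shuffling, initial weights, phantom data) descends from
explicit integer seeds, so identical invocations reproduce identical
epoch-one losses and fold assignments.  Training minimises the combined
BCE + Dice objective with AdamW.
"""

from __future__ import annotations

import numpy as np

from .losses import combined_loss
from .metrics import MetricsReport, dice_coefficient, evaluate_pair
from .nn import AdamW
from .tensor import Tensor

__all__ = ["to_model_input", "train_model", "predict_probs", "evaluate_model"]


def to_model_input(images):
    """uint8 (N, H, W, 3) images -> float32 (N, 3, H, W) in [0, 1]."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def predict_probs(model, images, batch_size=8):
    """Eval-mode sigmoid probability maps, (N, H, W) float32."""
    was_training = model.training
    model.eval()
    x = to_model_input(images)
    out = []
    for i in range(0, len(x), batch_size):
        logits = model(Tensor(x[i:i + batch_size])).data[:, 0]
        out.append(1.0 / (1.0 + np.exp(-logits)))
    if was_training:
        model.train()
    return np.concatenate(out, axis=0)


def _mean_dice(model, images, masks, batch_size=8):
    probs = predict_probs(model, images, batch_size)
    preds = (probs >= 0.5).astype(np.uint8)
    return float(np.mean([dice_coefficient(p, m) for p, m in zip(preds, masks)]))


def train_model(model, images, masks, epochs, batch_size=16, lr=1e-3,
                betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-2, seed=0,
                val_images=None, val_masks=None, log=None, fold=0):
    """Train in place; returns per-epoch records.

    Each record holds (fold, epoch, mean train loss, validation DSC — NaN
    when no validation split is given).
    """
    rng = np.random.default_rng(seed)
    opt = AdamW(model.parameters(), lr=lr, betas=betas, eps=eps,
                weight_decay=weight_decay)
    x_all = to_model_input(images)
    y_all = np.asarray(masks, dtype=np.float32)[:, None]  # (N,1,H,W)
    n = len(x_all)
    history = []
    model.train()
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            logits = model(Tensor(x_all[idx]))
            loss = combined_loss(logits, Tensor(y_all[idx]))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_dsc = (float("nan") if val_images is None
                   else _mean_dice(model, val_images, val_masks, batch_size))
        record = {"fold": fold, "epoch": epoch,
                  "train_loss": float(np.mean(losses)), "val_dsc": val_dsc}
        history.append(record)
        if log is not None:
            log(record)
    return history


def evaluate_model(model, images, masks, batch_size=8):
    """Per-case metric reports plus a mean/std summary per metric."""
    probs = predict_probs(model, images, batch_size)
    preds = (probs >= 0.5).astype(np.uint8)
    reports = [evaluate_pair(p, m) for p, m in zip(preds, masks)]
    table = [r.as_dict() for r in reports]
    keys = table[0].keys()
    summary = {k: (float(np.mean([row[k] for row in table])),
                   float(np.std([row[k] for row in table]))) for k in keys}
    return reports, summary
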