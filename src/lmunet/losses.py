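"""Training losses: binary cross-entropy, Dice, and their unweighted sum.

The combined objective is l = l_BCE + l_Dice, with the Dice term computed
on sigmoid probabilities using the squared-denominator form

    l_Dice = 1 - (2 sum p_i g_i + eps) / (sum p_i^2 + sum g_i^2 + eps).

BCE is evaluated in the numerically stable log-sum-exp form
``softplus(z) - y*z`` (equal to -[y ln sigma(z) + (1-y) ln(1-sigma(z))]).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = ["bce_loss", "dice_loss", "combined_loss"]

DICE_EPS = 1e-6


def _check_binary(truth):
    t = truth.data if isinstance(truth, Tensor) else np.asarray(truth)
    if not np.all((t == 0) | (t == 1)):
        raise ValueError("truth mask must be binary (values in {0, 1})")


def bce_loss(logits, truth) -> Tensor:
    """Mean binary cross-entropy on raw logits."""
    logits, truth = as_tensor(logits), as_tensor(truth)
    if logits.shape != truth.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs truth {truth.shape}")
    _check_binary(truth)
    return (logits.softplus() - logits * truth).mean()


def dice_loss(probs, truth, eps=DICE_EPS) -> Tensor:
    """Squared-denominator Dice loss on probabilities in [0, 1]."""
    probs, truth = as_tensor(probs), as_tensor(truth)
    if probs.shape != truth.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs truth {truth.shape}")
    inter = (probs * truth).sum()
    denom = (probs * probs).sum() + (truth * truth).sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def combined_loss(logits, truth) -> Tensor:
    """BCE + Dice, the Dice term on sigmoid(logits)."""
    logits = as_tensor(logits)
    return bce_loss(logits, truth) + dice_loss(logits.sigmoid(), truth)
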