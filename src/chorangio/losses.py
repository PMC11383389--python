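"""Training losses and confusion-sample selection (CSS).

Source and target segmentation use soft dice (background channel excluded,
smoothing eps = 1) to counter the foreground/background imbalance of choroidal
tissue.  Self-training on the unlabeled target domain is gated per pixel by
two strict-inequality gates: a confidence gate (teacher max-probability > alpha)
and a domain gate (beta1 < upsampled EDD score < beta2), whose product is the
selection mask.  The adversarial pair: the discriminator loss Le teaches the
EDD to separate the teacher's (temporally ensembled) target output space from
the student's source output space; the adaptation loss La, with the EDD frozen,
pushes the student's source predictions toward the target side (single-term
form: the teacher branch never backpropagates, so its term is dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor

__all__ = [
    "GateThresholds",
    "SelectionMask",
    "LossWeights",
    "soft_dice_loss",
    "source_loss",
    "make_pseudo_labels",
    "confidence_gate",
    "domain_gate",
    "selection_mask",
    "target_loss",
    "edd_loss",
    "adapt_loss",
    "total_loss",
]

LOG_EPS = 1e-7


@dataclass(frozen=True)
class GateThresholds:
    """CSS thresholds: confidence alpha and domain-score bounds (beta1, beta2)."""

    alpha: float = 0.85
    beta1: float = 0.1
    beta2: float = 0.9

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.beta1 < self.beta2 < 1.0:
            raise ValueError("need 0 < beta1 < beta2 < 1")

    @classmethod
    def layer_preset(cls) -> "GateThresholds":
        return cls(0.85, 0.1, 0.9)

    @classmethod
    def vessel_preset(cls) -> "GateThresholds":
        return cls(0.85, 0.15, 0.85)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the total objective Ls + lambda1*Lt + lambda2*La."""

    lambda1: float = 1.5
    lambda2: float = 0.5

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class SelectionMask:
    """Per-pixel self-training gate M = Mc * Md."""

    mc: np.ndarray
    md: np.ndarray

    @property
    def m(self) -> np.ndarray:
        return (self.mc & self.md).astype(np.uint8)

    @property
    def fraction(self) -> float:
        return float(self.m.mean())


def _promote(x) -> Tensor:
    t = as_tensor(x)
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
    return t


def _onehot(target: np.ndarray, n_classes: int) -> np.ndarray:
    target = np.asarray(target)
    if target.ndim == 2:
        target = target[None]
    out = np.zeros((target.shape[0], n_classes) + target.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        out[:, c][target == c] = 1.0
    return out


def soft_dice_loss(probs, target, mask: np.ndarray | None = None,
                   smooth: float = 1.0) -> Tensor:
    """1 - mean foreground-class soft dice, optionally over a pixel mask.

    `target` may be a hard label map or an already one-hot array matching
    `probs`.  With an all-zero mask the loss is exactly 0 (no selected pixels,
    contribution skipped).
    """
    p = _promote(probs)
    n, c = p.shape[0], p.shape[1]
    target = np.asarray(target)
    pshape = tuple(p.shape)
    if target.shape == pshape:                       # one-hot, batched
        y = np.asarray(target, dtype=np.float32)
    elif target.shape == pshape[1:] and n == 1:      # one-hot, single sample
        y = np.asarray(target, dtype=np.float32)[None]
    elif target.shape in ((n,) + pshape[2:], pshape[2:]):  # hard label map
        y = _onehot(target, c)
    else:
        raise ValueError(f"target shape {target.shape} incompatible with probs {pshape}")
    if mask is not None:
        mask = np.asarray(mask)
        if not np.isin(mask, [0, 1]).all():
            raise ValueError("pixel mask must be binary")
        if mask.sum() == 0:
            return Tensor(np.float32(0.0))
        if mask.ndim == 2:
            mask = mask[None]
        w = mask[:, None].astype(np.float32)
        p = p * w
        y = y * w
    inter = (p * y).sum(axis=(2, 3))          # (N, C)
    denom = p.sum(axis=(2, 3)) + Tensor(y.sum(axis=(2, 3)))
    dice = (inter * 2.0 + smooth) / (denom + smooth)
    # mean over foreground classes and batch, kept inside the graph
    fg_dice = dice.sum(axis=1) - _first_col(dice)
    mean_fg = fg_dice.mean() * np.float32(1.0 / (c - 1))
    return 1.0 - mean_fg


def _first_col(t: Tensor) -> Tensor:
    """Background column of a (N, C) tensor, kept in the autodiff graph."""
    sel = np.zeros(t.shape, dtype=np.float32)
    sel[:, 0] = 1.0
    return (t * sel).sum(axis=1)


def source_loss(prob_maps, vessel_gt: np.ndarray, sublayer_gt: np.ndarray) -> Tensor:
    """Supervised dice over both heads, averaged over the batch."""
    if vessel_gt is None or sublayer_gt is None:
        raise ValueError("source samples require both ground-truth masks")
    loss = None
    if prob_maps.vessel_probs is not None:
        loss = soft_dice_loss(prob_maps.vessel_probs, vessel_gt)
    if prob_maps.layer_probs is not None:
        l2 = soft_dice_loss(prob_maps.layer_probs, sublayer_gt)
        loss = l2 if loss is None else loss + l2
    if loss is None:
        raise ValueError("segmentor emitted no heads")
    return loss


def make_pseudo_labels(teacher_probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel argmax label (ties -> lowest class) and its probability."""
    p = np.asarray(teacher_probs)
    ax = 0 if p.ndim == 3 else 1
    labels = p.argmax(axis=ax).astype(np.uint8)
    maxprob = p.max(axis=ax)
    return labels, maxprob


def confidence_gate(maxprob: np.ndarray, alpha: float) -> np.ndarray:
    """Mc = 1 where the teacher's max probability strictly exceeds alpha."""
    return (np.asarray(maxprob) > alpha).astype(np.uint8)


def domain_gate(scores: np.ndarray, beta1: float, beta2: float) -> np.ndarray:
    """Md = 1 strictly inside (beta1, beta2): domain-confused pixels only."""
    if beta1 >= beta2:
        raise ValueError("beta1 must be < beta2")
    s = np.asarray(scores)
    return ((s > beta1) & (s < beta2)).astype(np.uint8)


def selection_mask(maxprob: np.ndarray, scores: np.ndarray,
                   gates: GateThresholds) -> SelectionMask:
    return SelectionMask(
        mc=confidence_gate(maxprob, gates.alpha),
        md=domain_gate(scores, gates.beta1, gates.beta2),
    )


def target_loss(student_probs, pseudo_labels, mask: SelectionMask | np.ndarray,
                ) -> tuple[Tensor, dict]:
    """Masked self-training dice against pseudo-labels for one head.

    Returns (loss, stats) where stats reports the selection fraction and an
    `empty_selection` flag when no pixel passed the gates.
    """
    m = mask.m if isinstance(mask, SelectionMask) else np.asarray(mask)
    stats = {"selection_fraction": float(np.mean(m)),
             "empty_selection": bool(m.sum() == 0)}
    loss = soft_dice_loss(student_probs, pseudo_labels, mask=m)
    return loss, stats


def edd_loss(s_target: Tensor, s_source: Tensor) -> Tensor:
    """Discriminator loss Le = E_t[-log S] + E_s[-log(1 - S)].

    Optimal when the EDD maps the (teacher-ensembled) target output space to 1
    and the source output space to 0; 2*ln 2 at the S = 0.5 midpoint.
    """
    s_t = as_tensor(s_target).clamp_min(LOG_EPS)
    one_minus = (1.0 - as_tensor(s_source)).clamp_min(LOG_EPS)
    return -(s_t.log().mean()) - one_minus.log().mean()


def adapt_loss(s_source: Tensor) -> Tensor:
    """Adversarial adaptation loss La = E_s[-log S] (EDD frozen).

    Pushes the student's source predictions toward the target side of the
    discriminator; the target term is omitted because the teacher's branch
    carries no gradient.
    """
    return -(as_tensor(s_source).clamp_min(LOG_EPS).log().mean())


def total_loss(ls, lt, la, weights: LossWeights = LossWeights()):
    """Ls + lambda1 * Lt + lambda2 * La, with finiteness diagnostics."""
    for name, v in (("Ls", ls), ("Lt", lt), ("La", la)):
        val = v.item() if isinstance(v, Tensor) else float(v)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite loss component {name} = {val}")
    return ls + weights.lambda1 * lt + weights.lambda2 * la
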