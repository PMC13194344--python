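"""Task losses and multi-task combination strategies.

The three task losses are

* ``bce_loss`` — mean binary cross-entropy over the landmark classes,
* ``kld_loss`` — KL divergence between per-position target and predicted
  vocabulary distributions, summed over unmasked sequence positions (with
  one-hot targets this is the summed negative log-likelihood of the correct
  tokens),
* ``fcs_loss`` — focal cosine-similarity loss ``(1 - cos)**gamma`` between
  frozen-encoder embeddings of the target and candidate sentences.

Combination strategies (the loss components ``l1, l2, l3`` are BCE, KLD, FCS):

* ``GL``     — geometric mean ``(l1*l2*l3)**(1/3)`` (scale-invariant),
* ``FL_img`` — image-focused ``l1*sqrt(l2*l3)``,
* ``FL_txt`` — text-focused ``l2*l3*sqrt(l1)``,
* ``AL``     — arithmetic mean ``(l1+l2+l3)/3``.

Natural logarithms throughout.  Components are epsilon-floored before roots
so gradients stay finite as a component approaches zero.  Public functions
accept plain arrays/floats and return floats; the ``*_t`` variants operate
on autodiff tensors for training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

STRATEGIES = ("GL", "FL_img", "FL_txt", "AL")


@dataclass
class LossStrategy:
    name: str = "GL"
    gamma: float = 2.0
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}; choose from {STRATEGIES}")
        if not (1.0 <= self.gamma <= 2.0):
            raise ValueError("gamma must lie in [1, 2]")


@dataclass
class LossBundle:
    l_bce: float
    l_kld: float
    l_fcs: float
    combined: float
    strategy: LossStrategy


def _floor(x, eps: float):
    if isinstance(x, Tensor):
        return x.clip_min(eps)
    return max(float(x), eps)


# --- task losses -------------------------------------------------------------

def bce_loss_t(c: np.ndarray, c_hat: Tensor, eps: float = 1e-8) -> Tensor:
    """Mean BCE over classes (and batch), on probability inputs."""
    c = np.asarray(c, dtype=float)
    if c.shape != tuple(c_hat.shape):
        raise ValueError(f"shape mismatch {c.shape} vs {c_hat.shape}")
    p = c_hat.clip_min(eps)
    q = (1.0 - c_hat).clip_min(eps)
    return -(Tensor(c) * p.log() + Tensor(1.0 - c) * q.log()).mean()


def bce_loss(c, c_hat, eps: float = 1e-8) -> float:
    """Average binary cross-entropy between a binary target vector and
    predicted per-class probabilities (natural log)."""
    return float(bce_loss_t(np.asarray(c, float),
                            Tensor(np.asarray(c_hat, float)), eps).data)


def kld_loss(P, Q, mask=None, eps: float = 1e-8) -> float:
    """KL divergence summed over unmasked positions.

    P, Q: arrays (T, V) or (B, T, V) of per-position distributions over the
    vocabulary; `mask` (same leading shape) excludes padding positions.
    0*log(0) is treated as 0; Q is epsilon-floored inside the log.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.ndim == 1:
        P, Q = P[None, :], Q[None, :]
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {Q.shape}")
    sums = P.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("target distributions must be normalised (|sum-1| <= 1e-6)")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * (np.log(P) - np.log(np.maximum(Q, eps))), 0.0)
    per_pos = terms.sum(axis=-1)
    if mask is not None:
        per_pos = per_pos * np.asarray(mask, dtype=float)
    return float(per_pos.sum())


def nll_loss_t(log_probs: Tensor, target_ids: np.ndarray,
               mask: np.ndarray | None = None) -> Tensor:
    """Summed negative log-likelihood of the target tokens — the one-hot
    special case of the KL objective, on a (B, T, V) log-probability tensor.
    Averaged over the batch so magnitudes are batch-size independent."""
    target_ids = np.asarray(target_ids)
    B, T = target_ids.shape
    bi = np.repeat(np.arange(B), T)
    ti = np.tile(np.arange(T), B)
    picked = log_probs[bi, ti, target_ids.reshape(-1)].reshape(B, T)
    if mask is not None:
        picked = picked * Tensor(np.asarray(mask, dtype=log_probs.data.dtype))
    return -picked.sum() * (1.0 / B)


def fcs_loss_t(e_target: np.ndarray, e_candidate: Tensor,
               gamma: float = 2.0, eps: float = 1e-12) -> Tensor:
    """Focal cosine-similarity loss, batch mean.  e_target: (B, d) constant;
    e_candidate: (B, d) tensor."""
    e_target = np.asarray(e_target, dtype=float)
    tn = np.linalg.norm(e_target, axis=-1)
    if np.any(tn == 0) or np.all(np.asarray(e_candidate.data) == 0):
        raise ValueError("zero-norm embedding")
    dot = (e_candidate * Tensor(e_target)).sum(axis=-1)
    cn = ((e_candidate * e_candidate).sum(axis=-1) + eps) ** 0.5
    cos = dot / (cn * Tensor(tn))
    return ((1.0 - cos) ** gamma).mean() if cos.ndim else (1.0 - cos) ** gamma


def fcs_loss(e_target, e_candidate, gamma: float = 2.0) -> float:
    """(1 - cosine(e_candidate, e_target))**gamma for a single pair or batch."""
    e_t = np.atleast_2d(np.asarray(e_target, dtype=float))
    e_c = np.atleast_2d(np.asarray(e_candidate, dtype=float))
    if np.any(np.linalg.norm(e_c, axis=-1) == 0):
        raise ValueError("zero-norm embedding")
    return float(fcs_loss_t(e_t, Tensor(e_c), gamma).data)


# --- combination strategies --------------------------------------------------

def combine_losses(l_bce, l_kld, l_fcs, strategy: LossStrategy | str = "GL"):
    """Combine the three task losses under a named strategy.

    Works on floats (returns float) and autodiff tensors (returns tensor).
    Components are floored at `strategy.epsilon` before roots.
    """
    if isinstance(strategy, str):
        strategy = LossStrategy(strategy)
    eps = strategy.epsilon
    l1, l2, l3 = (_floor(x, eps) for x in (l_bce, l_kld, l_fcs))
    if strategy.name == "GL":
        out = (l1 * l2 * l3) ** (1.0 / 3.0)
    elif strategy.name == "FL_img":
        out = l1 * (l2 * l3) ** 0.5
    elif strategy.name == "FL_txt":
        out = l2 * l3 * l1 ** 0.5
    else:  # AL
        out = (l1 + l2 + l3) * (1.0 / 3.0)
    return out if isinstance(out, Tensor) else float(out)


def make_bundle(l_bce: float, l_kld: float, l_fcs: float,
                strategy: LossStrategy | str = "GL") -> LossBundle:
    if isinstance(strategy, str):
        strategy = LossStrategy(strategy)
    return LossBundle(float(l_bce), float(l_kld), float(l_fcs),
                      combine_losses(l_bce, l_kld, l_fcs, strategy), strategy)
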