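"""Loss functions and the SGDM update rule.

The discriminator's adversarial loss splits into a real and a fake term
(``d_loss = d_real_loss + d_fake_loss``): real inputs are pushed toward
P(real) = 1 and generated inputs toward 0. The labeled real samples add a
standard cross-entropy term over the real classes. The generator either
minimizes ``log(1 − D(G(z)))`` (the saturating minimax form) or,
optionally, ``−log D(G(z))`` (the non-saturating variant commonly used to
keep early-training gradients alive).

Probabilities are epsilon-clamped before logs so degenerate batches yield
finite losses.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "supervised_loss",
    "discriminator_loss",
    "generator_loss",
    "sgdm_update",
    "EPS",
]

EPS = 1e-7


def _clamp(p: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)


def supervised_loss(class_probs, labels, eps: float = EPS) -> float:
    """Mean cross-entropy −log p(true class) over a batch.

    ``class_probs`` rows must sum to 1; a zero probability at the true
    class is clamped at ``eps`` so the loss stays finite.
    """
    p = np.asarray(class_probs, dtype=np.float64)
    y = np.asarray(labels, dtype=np.intp)
    if p.ndim != 2:
        raise ValueError("class_probs must be a (batch, classes) matrix")
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("class probability rows must sum to 1")
    if y.shape != (p.shape[0],) or np.any(y < 0) or np.any(y >= p.shape[1]):
        raise ValueError("labels must be valid class indices, one per row")
    picked = np.clip(p[np.arange(p.shape[0]), y], eps, None)
    return float(-np.mean(np.log(picked)))


def discriminator_loss(
    p_real_on_real, p_real_on_fake, eps: float = EPS
) -> tuple[float, float, float]:
    """Adversarial loss split: (d_loss, d_real_loss, d_fake_loss).

    ``d_real_loss = mean −log P(real | real batch)``,
    ``d_fake_loss = mean −log(1 − P(real | generated batch))``, and
    ``d_loss`` is their sum.
    """
    pr = _clamp(p_real_on_real, eps)
    pf = _clamp(p_real_on_fake, eps)
    d_real = float(-np.mean(np.log(pr)))
    d_fake = float(-np.mean(np.log(1.0 - pf)))
    return d_real + d_fake, d_real, d_fake


def generator_loss(p_real_on_fake, form: str = "saturating", eps: float = EPS) -> float:
    """Generator objective on a batch of P(real | generated) values.

    ``saturating``: mean log(1 − p), the quantity the minimax generator
    minimizes. ``nonsaturating``: mean −log p.
    """
    pf = _clamp(p_real_on_fake, eps)
    if form == "saturating":
        return float(np.mean(np.log(1.0 - pf)))
    if form == "nonsaturating":
        return float(-np.mean(np.log(pf)))
    raise ValueError(f"unknown generator loss form {form!r}")


def sgdm_update(weights, gradients, velocity, lr: float, momentum: float):
    """Classical-momentum SGD step: v ← m·v − lr·g; w ← w + v.

    Returns the updated ``(weights, velocity)`` as new arrays.
    """
    w = np.asarray(weights)
    g = np.asarray(gradients)
    v = np.asarray(velocity)
    if not (w.shape == g.shape == v.shape):
        raise ValueError("weights, gradients and velocity must share a shape")
    v_new = momentum * v - lr * g
    return w + v_new, v_new
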