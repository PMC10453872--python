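"""Analytic GAN-game quantities on finite discrete distributions.

These are analysis oracles, not training code: for distributions with
finite support the minimax value function can be evaluated exactly and the
optimal discriminator has the closed form

    D*(x) = p_data(x) / (p_data(x) + p_g(x)),

which equals 1/2 everywhere when the generator has matched the data
distribution — the equilibrium a converged GAN approaches, where the
value function attains −2·log 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscreteDistribution", "optimal_discriminator", "value_function"]


@dataclass(frozen=True)
class DiscreteDistribution:
    """Probabilities over a finite symbol set; must sum to 1."""

    support: tuple
    probs: tuple

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if len(self.support) != p.size:
            raise ValueError("support and probs must have equal length")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=np.float64)


def _aligned(p_data: DiscreteDistribution, p_g: DiscreteDistribution):
    if p_data.support != p_g.support:
        raise ValueError("distributions must share the same support")
    return p_data.as_array(), p_g.as_array()


def optimal_discriminator(
    p_data: DiscreteDistribution, p_g: DiscreteDistribution
) -> np.ndarray:
    """Per-symbol D*(x) = p_data/(p_data + p_g); 0.5 where both are zero."""
    pd, pg = _aligned(p_data, p_g)
    tot = pd + pg
    out = np.full(pd.shape, 0.5)
    nz = tot > 0
    out[nz] = pd[nz] / tot[nz]
    return out


def value_function(
    p_data: DiscreteDistribution, p_g: DiscreteDistribution, D
) -> float:
    """Minimax value V(G, D) = Σ p_data·log D + Σ p_g·log(1−D).

    ``D`` gives the discriminator's output at each support symbol and must
    lie strictly inside (0, 1).
    """
    pd, pg = _aligned(p_data, p_g)
    d = np.asarray(D, dtype=np.float64)
    if d.shape != pd.shape:
        raise ValueError("D must give one value per support symbol")
    if np.any(d <= 0.0) or np.any(d >= 1.0):
        raise ValueError("discriminator outputs must lie strictly in (0, 1)")
    return float(np.sum(pd * np.log(d)) + np.sum(pg * np.log(1.0 - d)))
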