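"""Environmental stochasticity and catastrophes for the endangered population.

The realized carrying capacity follows a mean-reverting (Ornstein-Uhlenbeck)
process on the log10 scale,

    log10 K[t+1] = (1 - phi) * log10 K_endangered + phi * log10 K[t] + e,
    e ~ Normal(0, sigma),

with defaults phi = 0.9 (high autocorrelation) and sigma = log10(1.3) (a
moderate year-to-year swing); the stationary standard deviation of log10 K
is sigma / sqrt(1 - phi^2) ~= 0.26.  Each generation an independent
catastrophe mortality probability is drawn from Beta(alpha=0.5, beta=8)
(mean ~5.9%, occasionally severe), applied as one Bernoulli death trial per
individual.  Ancestral and source populations experience neither process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EcologyState", "update_carrying_capacity",
           "draw_catastrophe_probability"]


@dataclass
class EcologyState:
    """Mutable state of the endangered population's environment."""

    log10_K: float
    phi: float = 0.9
    sigma: float = float(np.log10(1.3))
    catastrophe_alpha: float = 0.5
    catastrophe_beta: float = 8.0

    @classmethod
    def at_equilibrium(cls, K_endangered: int, **kwargs) -> "EcologyState":
        return cls(log10_K=float(np.log10(K_endangered)), **kwargs)


def update_carrying_capacity(state: EcologyState, K_endangered: int,
                             rng: np.random.Generator) -> int:
    """Advance the OU process one generation; returns the realized integer
    carrying capacity (rounded, floored at 1) and updates ``state``."""
    eps = rng.normal(0.0, state.sigma) if state.sigma > 0 else 0.0
    state.log10_K = ((1.0 - state.phi) * np.log10(K_endangered)
                     + state.phi * state.log10_K + eps)
    return max(1, int(np.rint(10.0 ** state.log10_K)))


def draw_catastrophe_probability(state: EcologyState,
                                 rng: np.random.Generator) -> float:
    """Fresh per-generation catastrophe mortality probability."""
    return float(rng.beta(state.catastrophe_alpha, state.catastrophe_beta))
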