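"""Competition-colonization trade-off: competitive weights and the interference lottery.

Two strategies compete on a landscape: a *fast colonizer* (high colonization
rate ``beta``) and a *superior competitor* (high interference-competitive
weight ``omega``).  The trade-off couples the two abilities through

    omega = exp(-alpha * beta)

with ``alpha >= 0`` setting the strength of the trade-off.  When both
strategies co-occupy a site they enter an interference lottery: the colonizer
loses with probability ``eta``, obtained from the ratio of the competitive
weights of the two strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["competitive_weight", "lottery_bias", "TradeoffParams"]


def competitive_weight(beta: float, alpha: float) -> float:
    """Competitive weight ``omega = exp(-alpha * beta)`` of a strategy.

    Parameters
    ----------
    beta:
        Colonization rate (per update attempt), ``beta >= 0``.
    alpha:
        Trade-off strength (dimensionless), ``alpha >= 0``.

    Returns
    -------
    float
        Weight in ``(0, 1]``; fast colonizers are weak interference
        competitors and vice versa.
    """
    if beta < 0:
        raise ValueError(f"colonization rate beta must be >= 0, got {beta}")
    if alpha < 0:
        raise ValueError(f"trade-off strength alpha must be >= 0, got {alpha}")
    return math.exp(-alpha * beta)


def lottery_bias(delta_beta: float, alpha: float) -> float:
    """Probability ``eta`` that the faster colonizer loses the interference lottery.

    The lottery between the co-occupants of a mixed site is biased by the
    ratio of their competitive weights.  With the faster strategy at rate
    ``beta_col`` and the slower at ``beta_col - delta_beta``,

        eta = omega_comp / (omega_comp + omega_col)
            = 1 / (1 + exp(-alpha * delta_beta))

    which depends on the rates only through their difference ``delta_beta``.

    Parameters
    ----------
    delta_beta:
        Colonization-rate difference in ``[-1, 1]``; positive when the focal
        (faster) strategy out-colonizes its opponent.
    alpha:
        Trade-off strength, ``alpha >= 0``.

    Returns
    -------
    float
        ``eta`` in ``(0, 1)``; ``eta = 0.5`` exactly at ``delta_beta = 0``
        (unbiased lottery, regardless of ``alpha``), and
        ``eta(-d) = 1 - eta(d)``.
    """
    if not -1.0 <= delta_beta <= 1.0:
        raise ValueError(f"delta_beta must lie in [-1, 1], got {delta_beta}")
    if alpha < 0:
        raise ValueError(f"trade-off strength alpha must be >= 0, got {alpha}")
    return 1.0 / (1.0 + math.exp(-alpha * delta_beta))


@dataclass(frozen=True)
class TradeoffParams:
    """Full parameter set of the stochastic trade-off model.

    Attributes
    ----------
    alpha:
        Trade-off strength (dimensionless, >= 0).
    beta_col:
        Colonization rate of the fast colonizer; fixed to 1 by convention.
    delta_beta:
        Colonization difference in ``[0, 1]``; the superior competitor
        colonizes at ``beta_comp = beta_col - delta_beta``.
    gamma:
        Cross-colonization factor in ``[0, 1]`` encoding priority effects:
        1 means an occupied site is as open to the other species as a vacant
        one, 0 means full inhibition (no mixed sites ever form).
    delta:
        Per-selection mortality of singly occupied sites, in ``[0, 1]``.
    eta:
        Probability the colonizer loses the interference lottery.  Computed
        from the weight ratio by default; pass explicitly to override.
    """

    alpha: float = 4.0
    beta_col: float = 1.0
    delta_beta: float = 0.2
    gamma: float = 1.0
    delta: float = 0.1
    eta: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0.0 <= self.delta_beta <= 1.0:
            raise ValueError("delta_beta must lie in [0, 1]")
        if not 0.0 <= self.beta_comp <= self.beta_col <= 1.0:
            raise ValueError(
                "colonization rates must satisfy 0 <= beta_comp <= beta_col <= 1"
            )
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.eta is not None and not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta override must lie in [0, 1]")

    @property
    def beta_comp(self) -> float:
        """Colonization rate of the superior competitor."""
        return self.beta_col - self.delta_beta

    @property
    def omega_col(self) -> float:
        """Competitive weight of the colonizer."""
        return competitive_weight(self.beta_col, self.alpha)

    @property
    def omega_comp(self) -> float:
        """Competitive weight of the competitor."""
        return competitive_weight(self.beta_comp, self.alpha)

    @property
    def eta_effective(self) -> float:
        """Lottery bias actually used: the override if set, else the weight ratio."""
        if self.eta is not None:
            return self.eta
        return lottery_bias(self.delta_beta, self.alpha)

    def replace(self, **kwargs) -> "TradeoffParams":
        from dataclasses import replace

        return replace(self, **kwargs)
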