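"""Probability arithmetic for annual-cycle decision models.

Multi-year cumulative incidences are converted to per-cycle (annual)
probabilities by inverting the compounding identity
``lambda = 1 - (1 - p)**t``; event rates per person-year convert via the
exponential survival relation ``p = 1 - exp(-rate)``.  Binomial proportions
carry Wilson-score 95% intervals, which stay well-behaved at zero counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class AnnualProbability:
    """A per-cycle probability and where it came from."""

    value: float
    source: str = "config"  # observed_count | annualized_literature | config

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"probability outside [0, 1]: {self.value}")


@dataclass(frozen=True)
class ProbabilityCI:
    point: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.point <= self.upper <= 1.0:
            raise ValueError(
                "interval must satisfy 0 <= lower <= point <= upper <= 1, "
                f"got ({self.lower}, {self.point}, {self.upper})"
            )


def annualize(cumulative_incidence: float, t: float) -> AnnualProbability:
    """Annual probability whose t-year compounding equals the cumulative incidence.

    Evaluates ``1 - (1 - lambda)**(1/t)``.  Degenerate at ``lambda = 1``
    (any positive annual probability compounds to 1 only in the limit).
    """
    lam = cumulative_incidence
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    if not 0.0 <= lam < 1.0:
        raise ValueError(
            f"cumulative incidence must be in [0, 1), got {lam}"
        )
    return AnnualProbability(
        1.0 - (1.0 - lam) ** (1.0 / t), source="annualized_literature"
    )


def estimate_probability(events: int, n: int) -> ProbabilityCI:
    """Binomial point estimate with a Wilson-score 95% interval."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= events <= n:
        raise ValueError("events must satisfy 0 <= events <= n")
    lower, upper = proportion_confint(events, n, alpha=0.05, method="wilson")
    point = events / n
    # guard against float jitter at the boundaries
    lower = min(max(float(lower), 0.0), point)
    upper = max(min(float(upper), 1.0), point)
    return ProbabilityCI(point=point, lower=lower, upper=upper)


def rate_to_annual_probability(rate: float) -> float:
    """Annual event probability from a constant rate in events/person-year."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return 1.0 - math.exp(-rate)
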