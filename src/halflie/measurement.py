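"""Physics of a single query: top-hat illumination with asymmetric photon loss.

A confocal or multiphoton microscope asking "is the emitter in this
region?" is a yes/no query whose "yes" can be lost but whose "no" cannot be
faked: the emitter fluoresces (one signal photon) if and only if it sits
inside the illuminated interval, and that photon survives collection with
probability ``1 - loss_rate``.  Detector dark counts are rare enough to be
ignored, so a detected photon (r = 1) is always truthful while a null
result (r = 0) may be a "half-lie".

Intervals are half-open, ``[lower, upper)``: a target exactly on the upper
boundary is not illuminated.  The choice is statistically irrelevant
(boundary hits are measure-zero under the uniform prior) but must be fixed
so that adjacent subdomains partition the domain and traces are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._levels import levels_for

__all__ = ["GameConfig", "QueryInterval", "MeasurementResult", "simulate_measurement"]


@dataclass(frozen=True, slots=True)
class GameConfig:
    """Full parameterization of one localization game.

    Parameters
    ----------
    precision
        Target precision epsilon as a fraction of the domain, in (0, 1].
        The game ends when the surviving interval is narrower than
        ``precision * domain_length``.
    loss_rate
        Photon loss probability alpha0 in [0, 1).  alpha0 = 1 is rejected:
        a verification-based search would never terminate and the optimal
        query boundary is undefined there.
    sectioning_order
        Number q >= 2 of equal subdomains each level splits into.
    domain_length
        Physical length L of the 1D search domain (default 1).
    """

    precision: float
    loss_rate: float
    sectioning_order: int
    domain_length: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.precision <= 1):
            raise ValueError(f"precision must be in (0, 1], got {self.precision!r}")
        if not (0 <= self.loss_rate < 1):
            raise ValueError(
                f"loss_rate must be in [0, 1); got {self.loss_rate!r} "
                "(the game is undefined at loss_rate = 1: no query can ever verify)"
            )
        if int(self.sectioning_order) != self.sectioning_order or self.sectioning_order < 2:
            raise ValueError(
                f"sectioning_order must be an integer >= 2, got {self.sectioning_order!r}"
            )
        if not (self.domain_length > 0):
            raise ValueError(f"domain_length must be positive, got {self.domain_length!r}")

    @classmethod
    def from_resolution(
        cls,
        epsilon_inverse: float,
        loss_rate: float,
        sectioning_order: int,
        domain_length: float = 1.0,
    ) -> "GameConfig":
        """Build a config from the resolution 1/epsilon (number of resolvable bins)."""
        if not (epsilon_inverse >= 1):
            raise ValueError(f"epsilon_inverse must be >= 1, got {epsilon_inverse!r}")
        return cls(
            precision=1.0 / epsilon_inverse,
            loss_rate=loss_rate,
            sectioning_order=sectioning_order,
            domain_length=domain_length,
        )

    @property
    def epsilon_inverse(self) -> float:
        return 1.0 / self.precision

    @property
    def levels(self) -> int:
        """Number of recursion levels, ``ceil(log_q(1/eps))`` (at least 1)."""
        return levels_for(self.sectioning_order, 1.0 / self.precision)


@dataclass(frozen=True, slots=True)
class QueryInterval:
    """One top-hat illumination region, the half-open interval [lower, upper)."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower < self.upper):
            raise ValueError(
                f"malformed interval: lower={self.lower!r} must be < upper={self.upper!r}"
            )
        if self.lower < 0:
            raise ValueError(f"interval lower bound must be >= 0, got {self.lower!r}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x < self.upper


@dataclass(frozen=True, slots=True)
class MeasurementResult:
    """Detector readout r in {0, 1}.  r = 1 is guaranteed truthful."""

    r: int

    def __post_init__(self) -> None:
        if self.r not in (0, 1):
            raise ValueError(f"measurement result must be 0 or 1, got {self.r!r}")

    def __bool__(self) -> bool:
        return self.r == 1


def simulate_measurement(
    target_position: float,
    query: QueryInterval,
    loss_rate: float,
    rng: np.random.Generator,
) -> MeasurementResult:
    """Simulate one illumination query against a hidden target.

    Target outside ``query``: no photon is generated and r = 0 with
    certainty, consuming no randomness.  Target inside: one photon is
    generated and survives with probability ``1 - loss_rate``, consuming
    exactly one uniform draw.  The asymmetry is the half-lie: only
    "present" can be misreported.
    """
    if not (0 <= loss_rate <= 1):
        raise ValueError(f"loss_rate must be in [0, 1], got {loss_rate!r}")
    if not query.contains(target_position):
        return MeasurementResult(0)
    lost = rng.random() < loss_rate
    return MeasurementResult(0 if lost else 1)
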