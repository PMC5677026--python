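"""Mutual information of a single boundary query under half-lies.

With a uniform prior for the target on [0, L], a query illuminating
[0, v) with loss rate alpha has joint distribution

    P(x, r=1) = (1 - alpha)/L          for x < v
    P(x, r=0) = alpha/L                for x < v
    P(x, r=0) = 1/L                    for x >= v

from which I(X:R) = H(X) - H(X|R) has the closed form (in nats, w = v/L)

    I = -[(1-alpha) w ln w + (1 - w + alpha w) ln(1 - w + alpha w)
          - alpha w ln alpha]

The boundary maximizing I is

    v0 = L a^(a/(1-a)) / (1 + (1-a) a^(a/(1-a)))       (a = alpha)

which runs from L/2 (lossless bisection) down to L/e as a -> 1.  Internally
everything is in nats; the bits used for query-budget bookkeeping divide by
ln 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

__all__ = [
    "mutual_information",
    "optimal_boundary",
    "information_map",
    "estimated_optimal_queries",
    "InfoMap",
]

_LN2 = math.log(2.0)


def mutual_information(loss_rate: float, boundary: float, domain_length: float = 1.0) -> float:
    """Information (nats) one query with turn-off boundary ``boundary`` yields.

    Scale-invariant: only the fractional boundary ``boundary/domain_length``
    matters.  Returns 0 at the degenerate boundaries 0 and L and at
    ``loss_rate = 1``.  Terms of the form p log p are evaluated as 0 when
    p = 0.
    """
    if not (0 <= loss_rate <= 1):
        raise ValueError(f"loss_rate must be in [0, 1], got {loss_rate!r}")
    if not (domain_length > 0):
        raise ValueError(f"domain_length must be positive, got {domain_length!r}")
    if not (0 <= boundary <= domain_length):
        raise ValueError(
            f"boundary must lie in [0, {domain_length}], got {boundary!r}"
        )
    a = float(loss_rate)
    w = float(boundary) / float(domain_length)
    p0 = 1.0 - w + a * w  # P(r = 0)
    val = -(xlogy((1.0 - a) * w, w) + xlogy(p0, p0) - w * xlogy(a, a))
    # clip the tiny negative rounding residue at the degenerate corners
    return max(float(val), 0.0)


def optimal_boundary(loss_rate: float, domain_length: float = 1.0) -> float:
    """Boundary v0 maximizing per-query information, in length units.

    At ``loss_rate = 0`` this is exactly L/2 (the analytic limit; the raw
    expression is a 0**0 form there).  It decreases monotonically towards
    L/e as the loss rate approaches 1, where the game itself is undefined.
    """
    if not (0 <= loss_rate < 1):
        raise ValueError(
            f"loss_rate must be in [0, 1): got {loss_rate!r}; the optimal boundary "
            "is undefined at loss_rate = 1 (its limit is domain_length/e)"
        )
    if not (domain_length > 0):
        raise ValueError(f"domain_length must be positive, got {domain_length!r}")
    a = float(loss_rate)
    if a == 0.0:
        return domain_length / 2.0
    t = a ** (a / (1.0 - a))
    return domain_length * t / (1.0 + (1.0 - a) * t)


@dataclass(frozen=True)
class InfoMap:
    """Information landscape over a (loss rate, boundary) grid.

    Attributes
    ----------
    grid
        Long-format frame with columns ``alpha``, ``v``, ``info_nats``,
        ``info_bits`` -- one row per grid cell.
    per_alpha
        One row per loss rate: the argmax boundary on the scanned grid
        (``v_opt``) and the information there (``info_max_bits``).
    """

    grid: pd.DataFrame
    per_alpha: pd.DataFrame


def information_map(
    loss_grid: Sequence[float],
    boundary_grid: Sequence[float],
    domain_length: float = 1.0,
) -> InfoMap:
    """Evaluate the query information on a full (alpha, v) grid.

    Also reports, per loss rate, the best boundary on the grid and the
    information it attains -- the ridge of the landscape, which tracks
    :func:`optimal_boundary` to within one grid step.
    """
    alphas = np.asarray(list(loss_grid), dtype=float)
    vs = np.asarray(list(boundary_grid), dtype=float)
    if alphas.size == 0 or vs.size == 0:
        raise ValueError("loss_grid and boundary_grid must be nonempty")
    if np.any((alphas < 0) | (alphas > 1)):
        raise ValueError("all loss rates must lie in [0, 1]")
    if np.any((vs < 0) | (vs > domain_length)):
        raise ValueError(f"all boundaries must lie in [0, {domain_length}]")

    w = vs / domain_length
    a = alphas[:, None]
    p0 = 1.0 - w + a * w
    info = -(
        xlogy((1.0 - a) * w, w)
        + xlogy(p0, p0)
        - w * xlogy(a, a)
    )
    info = np.maximum(info, 0.0)

    grid = pd.DataFrame(
        {
            "alpha": np.repeat(alphas, vs.size),
            "v": np.tile(vs, alphas.size),
            "info_nats": info.ravel(),
        }
    )
    grid["info_bits"] = grid["info_nats"] / _LN2

    best = info.argmax(axis=1)
    per_alpha = pd.DataFrame(
        {
            "alpha": alphas,
            "v_opt": vs[best],
            "info_max_bits": info[np.arange(alphas.size), best] / _LN2,
        }
    )
    return InfoMap(grid=grid, per_alpha=per_alpha)


def default_grids(domain_length: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Default map grids: 101 loss rates on [0, 0.99], 1001 interior boundaries."""
    alphas = np.linspace(0.0, 0.99, 101)
    vs = np.linspace(0.0, domain_length, 1003)[1:-1]
    return alphas, vs


def estimated_optimal_queries(precision: float, loss_rate: float) -> int:
    """Information-budget estimate of the query count an ideal scheme needs.

    Locating the target to precision eps requires ``log2(1/eps)`` bits;
    an optimally placed query delivers ``I(X:R)`` at the optimal boundary.
    The estimate is the ceiling of their ratio.  It is a first-pass
    yardstick, not an attainable bound: it assumes every query yields the
    single-query maximum.
    """
    if not (0 < precision <= 1):
        raise ValueError(f"precision must be in (0, 1], got {precision!r}")
    if not (0 <= loss_rate < 1):
        raise ValueError(f"loss_rate must be in [0, 1), got {loss_rate!r}")
    if precision == 1:
        return 0
    bits_needed = math.log2(1.0 / precision)
    v0 = optimal_boundary(loss_rate, 1.0)
    info_bits = mutual_information(loss_rate, v0, 1.0) / _LN2
    return math.ceil(bits_needed / info_bits)
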