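"""Closed-form expected costs of sectioning searches, baselines, and scans.

The expected total query count of q-sectioning with verification is

    m(q, eps, a0) = [ q (1/(1-a0) - 1) + (q+1)/2 ] * ceil(log_q(1/eps))

In the long run 1/(1-a0) passes must hit the correct subdomain before a
photon survives; each failed pass also pays for the other q - 1 subdomains,
and the final (successful) pass costs (q+1)/2 on average for a uniformly
placed target.  At zero loss this reduces to ((q+1)/2) * ceil(log_q(1/eps)).

Costs are rationals (the prefactor) times an integer level count.  The
optimality scans compare them with exact integer arithmetic whenever the
loss rate has a manageable decimal form -- tie classification ("optimal"
vs "uniquely optimal") would otherwise be at the mercy of float rounding.
A float loss rate is interpreted as the decimal number printed by its
shortest repr (0.99 means 99/100).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._levels import ceil_log, levels_array, levels_for

__all__ = [
    "mean_zero_lie",
    "mean_queries",
    "nearness_metric",
    "rastering_verification_mean",
    "conventional_raster_queries",
    "rivest_lower_bound",
    "OptimalityCell",
    "OptimalityMapResult",
    "optimality_map",
    "epsilon_grid_near_powers",
]

DEFAULT_Q_ZERO_LOSS = (2, 3, 4, 5, 6, 7, 8)
DEFAULT_Q_LOSSY = (2, 3, 4, 5)

# exact comparisons are abandoned past this common-denominator size
_MAX_DENOM = 1 << 30


def _loss_fraction(loss_rate) -> Fraction:
    """Loss rate as an exact rational (floats via their shortest decimal repr)."""
    if isinstance(loss_rate, float):
        return Fraction(str(loss_rate))
    return Fraction(loss_rate)


def _validate_q(q: int) -> int:
    if int(q) != q or q < 2:
        raise ValueError(f"sectioning order must be an integer >= 2, got {q!r}")
    return int(q)


def _prefactor(q: int, loss_rate) -> Fraction:
    """Exact per-level expected cost q(1/(1-a)-1) + (q+1)/2."""
    a = _loss_fraction(loss_rate)
    if not (0 <= a < 1):
        raise ValueError(f"loss_rate must be in [0, 1), got {loss_rate!r}")
    return q * (1 / (1 - a) - 1) + Fraction(q + 1, 2)


def mean_zero_lie(q: int, epsilon_inverse: float) -> float:
    """Expected query count at zero loss: ((q+1)/2) * ceil(log_q(1/eps))."""
    q = _validate_q(q)
    if not (epsilon_inverse >= 1):
        raise ValueError(f"epsilon_inverse must be >= 1, got {epsilon_inverse!r}")
    return (q + 1) / 2 * levels_for(q, epsilon_inverse)


def mean_queries(q: int, epsilon_inverse: float, loss_rate) -> float:
    """Expected query count of q-sectioning with verification at any loss rate.

    Reduces exactly to :func:`mean_zero_lie` at ``loss_rate = 0``.  The
    prefactor is evaluated as an exact rational, so e.g. the value at
    (q=3, 1/eps=1e6, a0=0.99) is exactly 3887.0 rather than a float whisker
    below it.
    """
    q = _validate_q(q)
    if not (epsilon_inverse >= 1):
        raise ValueError(f"epsilon_inverse must be >= 1, got {epsilon_inverse!r}")
    return float(_prefactor(q, loss_rate) * levels_for(q, epsilon_inverse))


def nearness_metric(q: int, epsilon_inverse: float) -> float:
    """Distance of log_q(1/eps) from the nearest integer, folded into [0, 0.5].

    0 means 1/eps is an exact power of q (detected with integer arithmetic,
    immune to float logs); 0.5 is the farthest possible.
    """
    q = _validate_q(q)
    if not (epsilon_inverse > 1):
        raise ValueError(f"epsilon_inverse must be > 1, got {epsilon_inverse!r}")
    nearest = round(epsilon_inverse)
    if abs(epsilon_inverse - nearest) <= 1e-9 * nearest:
        t = ceil_log(q, nearest)
        if q**t == nearest:
            return 0.0
    x = math.log(epsilon_inverse) / math.log(q)
    frac = x - math.floor(x)
    return 0.5 - abs(0.5 - frac)


def rastering_verification_mean(epsilon_inverse: float) -> float:
    """Expected cost of rastering over 1/eps subdomains until verification.

    This is the q = 1/eps limiting member of the sectioning family: a
    single level of (1/eps + 1)/2 expected queries at zero loss.
    Prohibitive for any appreciable resolution.
    """
    if not (epsilon_inverse > 1):
        raise ValueError(f"epsilon_inverse must be > 1, got {epsilon_inverse!r}")
    return 0.5 * (epsilon_inverse + 1)


def conventional_raster_queries(
    epsilon_inverse: float, dwell: int, adaptive: bool = False
) -> float:
    """Cost of a conventional dwell raster: gamma/eps, halved if adaptive.

    ``dwell`` is the number of queries gamma spent per pixel, at least 1.
    An adaptive scan stops after locating the target, costing 0.5*gamma/eps
    on average.
    """
    if int(dwell) != dwell or dwell < 1:
        raise ValueError(f"dwell must be an integer >= 1, got {dwell!r}")
    if not (epsilon_inverse >= 1):
        raise ValueError(f"epsilon_inverse must be >= 1, got {epsilon_inverse!r}")
    cost = dwell * epsilon_inverse
    return 0.5 * cost if adaptive else float(cost)


def rivest_lower_bound(k: int, num_errors: int) -> int:
    """Lower bound on comparison queries to find one of k items with up to
    ``num_errors`` erroneous responses of one type:

        ceil( log2 k + E log2 log2 k + E log2 E )

    with the ``E log2 E`` term taken as 0 for E <= 1.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k!r}")
    if num_errors < 0 or int(num_errors) != num_errors:
        raise ValueError(f"num_errors must be a non-negative integer, got {num_errors!r}")
    E = int(num_errors)
    log2k = math.log2(k)
    total = log2k + E * math.log2(log2k)
    if E >= 2:
        total += E * math.log2(E)
    return math.ceil(total)


@dataclass(frozen=True, slots=True)
class OptimalityCell:
    """Which sectioning orders minimize the expected cost at one (1/eps, a0)."""

    epsilon_inverse: int
    loss_rate: float
    optimal_q_set: frozenset[int]
    unique: bool


@dataclass(frozen=True)
class OptimalityMapResult:
    """Scan output: per-q win counts, and the individual cells if requested.

    Attributes
    ----------
    counts
        Frame with one row per (loss_rate, q): ``n_optimal`` cells where q
        attains the minimal mean (ties all count) and ``n_unique`` where it
        is the sole minimizer.
    n_cells
        Number of resolutions scanned per loss rate.
    cells
        ``OptimalityCell`` list (only when ``return_cells=True``; large
        scans would otherwise materialize tens of millions of objects).
    masks
        Only when ``return_masks=True``: per loss rate, a dict mapping each
        candidate q to the boolean "q is in the argmin set" array over the
        scanned resolutions -- the memory-friendly face of ``cells`` for
        joint queries on large scans.
    """

    counts: pd.DataFrame
    n_cells: int
    cells: list[OptimalityCell] | None = None
    masks: dict[float, dict[int, np.ndarray]] | None = None


def _scan_costs(eps_inv: np.ndarray, loss_rate, q_candidates: Sequence[int]):
    """Per-q cost arrays on a common scale.

    Returns integer arrays (exact comparisons) when the rational prefactors
    share a manageable denominator, float arrays otherwise.
    """
    pres = {q: 2 * _prefactor(q, loss_rate) for q in q_candidates}
    denom = 1
    for f in pres.values():
        denom = math.lcm(denom, f.denominator)
    costs = {}
    if denom <= _MAX_DENOM:
        for q in q_candidates:
            scaled = int(pres[q] * denom)  # exact by construction
            costs[q] = scaled * levels_array(q, eps_inv)
    else:
        for q in q_candidates:
            costs[q] = float(pres[q]) * levels_array(q, eps_inv).astype(float)
    return costs, denom <= _MAX_DENOM


def optimality_map(
    epsilon_inverses: Iterable[int] | np.ndarray,
    loss_rates: Sequence[float],
    q_candidates: Sequence[int] = DEFAULT_Q_ZERO_LOSS,
    return_cells: bool = False,
    return_masks: bool = False,
) -> OptimalityMapResult:
    """For every (1/eps, loss rate), find the sectioning orders of minimal mean.

    Every q attaining the minimum is counted "optimal"; "unique" requires a
    singleton argmin set.  Comparisons use exact integer arithmetic for
    decimal loss rates, so ties are classified exactly (e.g. q = 3 and
    q = 4 genuinely tie at many resolutions when the loss is zero).
    """
    eps_inv = np.asarray(list(epsilon_inverses), dtype=np.int64)
    if eps_inv.size == 0:
        raise ValueError("epsilon_inverses must be nonempty")
    if np.any(eps_inv < 2):
        raise ValueError("all epsilon_inverse values must be >= 2")
    qs = [_validate_q(q) for q in q_candidates]
    if not qs:
        raise ValueError("q_candidates must be nonempty")
    for a in loss_rates:
        if not (0 <= _loss_fraction(a) < 1):
            raise ValueError(f"loss rates must lie in [0, 1); got {a!r} "
                             "(the game is undefined at loss rate 1)")

    rows = []
    cells: list[OptimalityCell] | None = [] if return_cells else None
    masks: dict[float, dict[int, np.ndarray]] | None = {} if return_masks else None
    for a in loss_rates:
        costs, exact = _scan_costs(eps_inv, a, qs)
        best = None
        for q in qs:
            best = costs[q] if best is None else np.minimum(best, costs[q])
        if exact:
            is_opt = {q: costs[q] == best for q in qs}
        else:
            tol = 1e-9 * np.abs(best) + 1e-12
            is_opt = {q: costs[q] <= best + tol for q in qs}
        n_opt_per_cell = np.zeros(eps_inv.size, dtype=np.int16)
        for q in qs:
            n_opt_per_cell += is_opt[q]
        for q in qs:
            rows.append(
                {
                    "loss_rate": float(_loss_fraction(a)),
                    "q": q,
                    "n_optimal": int(is_opt[q].sum()),
                    "n_unique": int((is_opt[q] & (n_opt_per_cell == 1)).sum()),
                }
            )
        if masks is not None:
            masks[float(_loss_fraction(a))] = {q: is_opt[q] for q in qs}
        if cells is not None:
            unique_cell = n_opt_per_cell == 1
            opt_lists = [np.flatnonzero(is_opt[q]) for q in qs]
            qsets: list[set[int]] = [set() for _ in range(eps_inv.size)]
            for q, idx in zip(qs, opt_lists):
                for j in idx:
                    qsets[j].add(q)
            for j, e in enumerate(eps_inv):
                cells.append(
                    OptimalityCell(
                        epsilon_inverse=int(e),
                        loss_rate=float(_loss_fraction(a)),
                        optimal_q_set=frozenset(qsets[j]),
                        unique=bool(unique_cell[j]),
                    )
                )
    return OptimalityMapResult(
        counts=pd.DataFrame(rows), n_cells=int(eps_inv.size), cells=cells, masks=masks
    )


def epsilon_grid_near_powers(
    eps_max: int,
    q_candidates: Sequence[int] = DEFAULT_Q_LOSSY,
    eps_min: int = 2,
) -> np.ndarray:
    """Compressed resolution grid: {q**i - 1, q**i, q**i + 1} for all q, i.

    Because every cost function is a step function of 1/eps jumping only at
    powers of its own q, evaluating at the points straddling every power of
    every candidate q captures the full structure of the optimality map at
    a tiny fraction of the dense grid.
    """
    if eps_max < eps_min:
        raise ValueError("eps_max must be >= eps_min")
    pts: set[int] = set()
    for q in q_candidates:
        q = _validate_q(q)
        p = q
        while p - 1 <= eps_max:
            for e in (p - 1, p, p + 1):
                if eps_min <= e <= eps_max:
                    pts.add(e)
            p *= q
    return np.asarray(sorted(pts), dtype=np.int64)
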