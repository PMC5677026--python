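"""Robust ceiling-logarithm arithmetic for level counts.

The number of recursion levels a q-sectioning search needs is
``ceil(log_q(1/epsilon))``.  Evaluating that with floating-point logarithms
misfires exactly where it matters most -- at integer powers of q -- and a
silently wrong level count propagates into every expected-cost table.  All
level counts in this package therefore go through :func:`ceil_log`, which
uses exact integer power accumulation whenever the argument is (within
rounding slop) an integer, and brackets the float answer with exact integer
powers otherwise.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["ceil_log", "levels_for", "levels_array"]

#: relative slop under which a float argument is snapped to an integer
_SNAP_RTOL = 1e-9


def ceil_log(base: int, x: float) -> int:
    """Smallest non-negative integer ``t`` with ``base**t >= x``.

    Parameters
    ----------
    base
        Integer logarithm base, at least 2.
    x
        Positive argument.  Values within a relative 1e-9 of an integer are
        treated as that integer exactly, so ``ceil_log(3, 1/1e-10)`` is 21
        even though ``1/1e-10`` is not representable as exactly ``10**10``.
    """
    if base < 2 or int(base) != base:
        raise ValueError(f"base must be an integer >= 2, got {base!r}")
    base = int(base)
    if not (x > 0) or math.isinf(x):
        raise ValueError(f"argument must be a positive finite number, got {x!r}")
    if x <= 1:
        return 0

    nearest = round(x)
    if abs(x - nearest) <= _SNAP_RTOL * max(1.0, abs(x)):
        # exact integer accumulation: no float logs involved
        t, p = 0, 1
        while p < nearest:
            p *= base
            t += 1
        return t

    # float estimate, then verify against exact integer powers
    t = math.ceil(math.log(x) / math.log(base))
    while t > 0 and base ** (t - 1) >= x:
        t -= 1
    while base ** t < x:
        t += 1
    return t


def levels_for(sectioning_order: int, epsilon_inverse: float) -> int:
    """Level count of a q-sectioning search: ``max(1, ceil_log(q, 1/eps))``.

    The final split is always into q subdomains even when fewer would
    suffice, so a game always has at least one level.
    """
    return max(1, ceil_log(sectioning_order, epsilon_inverse))


def levels_array(sectioning_order: int, epsilon_inverses: np.ndarray) -> np.ndarray:
    """Vectorised :func:`levels_for` over an array of integer resolutions.

    Uses a searchsorted against the exact integer powers of q, so every
    entry matches the scalar routine bit for bit.
    """
    eps_inv = np.asarray(epsilon_inverses, dtype=np.int64)
    if eps_inv.size == 0:
        return np.zeros(0, dtype=np.int64)
    if np.any(eps_inv < 1):
        raise ValueError("all resolutions must be >= 1")
    q = int(sectioning_order)
    if q < 2:
        raise ValueError(f"sectioning order must be >= 2, got {sectioning_order!r}")
    top = int(eps_inv.max())
    powers = [1]
    while powers[-1] < top:
        powers.append(powers[-1] * q)
    out = np.searchsorted(np.asarray(powers, dtype=np.int64), eps_inv, side="left")
    return np.maximum(out, 1).astype(np.int64)
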