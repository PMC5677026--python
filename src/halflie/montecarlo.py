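"""Batch trial execution and summary statistics of query-count distributions.

The query-count distribution of a verification search is integer-valued and
heavily right-skewed at high loss (the number of passes per level is
geometric, so the data space is semi-infinite and the mean sits right of
the mode).  Summaries therefore report mean, median, mode, the standard
error of the mean, the unit-width histogram and the empirical CDF at the
observed support.

Seeding: the naive engine derives each trial's generator from
``SeedSequence((seed, trial_index))``, so any single trial can be replayed
in isolation; the fast engine draws the whole batch from
``SeedSequence((seed,))``.  Identical (config, n_trials, seed, engine)
always reproduce bit-identical summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .heuristics import run_qsectioning, sample_query_counts
from .measurement import GameConfig

__all__ = ["SummaryStats", "run_trials", "summarize"]


@dataclass(frozen=True)
class SummaryStats:
    """Central-tendency and distributional summary of integer query counts."""

    n_trials: int
    mean: float
    median: float
    mode: int
    std_error_of_mean: float
    histogram: dict[int, int]
    cdf: tuple[tuple[int, float], ...]


def summarize(counts: Sequence[int] | np.ndarray) -> SummaryStats:
    """Exact integer-aware statistics of a sample of query counts.

    The median of an even-length sample is the mean of the central pair;
    the mode breaks ties towards the smallest count.
    """
    arr = np.asarray(counts, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    values, freqs = np.unique(arr, return_counts=True)
    mode = int(values[np.argmax(freqs)])  # argmax returns the first (smallest) tie
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    cum = np.cumsum(freqs) / arr.size
    return SummaryStats(
        n_trials=int(arr.size),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        mode=mode,
        std_error_of_mean=sem,
        histogram={int(v): int(c) for v, c in zip(values, freqs)},
        cdf=tuple((int(v), float(c)) for v, c in zip(values, cum)),
    )


def run_trials(
    config: GameConfig,
    n_trials: int,
    seed: int,
    engine: Literal["naive", "fast"] = "fast",
    return_counts: bool = False,
) -> SummaryStats | tuple[SummaryStats, np.ndarray]:
    """Run many independent searches with uniformly random targets.

    ``engine="naive"`` plays every query through the measurement model
    (the reference path); ``engine="fast"`` draws the distribution-identical
    per-level (passes, subdomain) samples directly and is the default for
    large batches.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials!r}")
    if engine == "fast":
        rng = np.random.default_rng(np.random.SeedSequence((seed,)))
        counts = sample_query_counts(config, n_trials, rng)
    elif engine == "naive":
        out = np.empty(n_trials, dtype=np.int64)
        for i in range(n_trials):
            rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
            target = rng.uniform(0.0, config.domain_length)
            out[i] = run_qsectioning(config, target, rng).total_queries
        counts = out
    else:
        raise ValueError(f"engine must be 'naive' or 'fast', got {engine!r}")
    stats = summarize(counts)
    return (stats, counts) if return_counts else stats
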