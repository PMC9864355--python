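"""Seeded generator of fictive paired CO measurements.

Emulates a Bland–Altman dataset for two CO methods.  The difference
d = CO_TD − CO_DF is drawn from N(bias, sigma) first; the pair mean is
then drawn uniformly over the interval [a + |d|/2, b − |d|/2] of means
for which both CO_TD = mean + d/2 and CO_DF = mean − d/2 are
physiological.  Drawing the difference first keeps its distribution
exactly normal — so a Bland–Altman analysis of the output recovers the
configured bias and limits of agreement — while every individual CO value
still lands inside [a, b].  A difference wider than the interval itself
(|d| > b − a) admits no valid mean and is rejected; at the default
parameters this is an ~8.7-sigma event, but a grossly infeasible
configuration (LoA large relative to b − a) trips a stall guard instead
of looping forever.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ModelConfig
from .exceptions import GeneratorStalledError, InvalidParameterError

#: Minimum acceptance rate below which generation is considered stalled.
_MIN_ACCEPTANCE = 0.01
_PROBE_SIZE = 10_000


def generate_pairs(n: int,
                   config: ModelConfig = DEFAULT_CONFIG,
                   seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Generate ``n`` fictive (CO_TD, CO_DF) pairs.

    Parameters
    ----------
    n : int
        Number of accepted pairs to return (≥ 1).
    config : ModelConfig
        Bias, limits of agreement and physiological CO limits.
    seed : int, Generator or None
        Seed (or generator) for reproducible output; a fixed seed gives
        bit-identical results.

    Returns
    -------
    DataFrame
        Columns ``co_td``, ``co_df``, ``difference`` (= co_td − co_df) and
        ``mean``; all CO values inside [a, b].
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n!r}")
    rng = np.random.default_rng(seed)
    a, b = config.co_min, config.co_max
    mu, sigma = config.bias, config.sigma

    co_td = np.empty(n)
    co_df = np.empty(n)
    filled = 0
    proposed = 0
    accepted = 0
    while filled < n:
        batch = max(n - filled, _PROBE_SIZE)
        diff = rng.normal(mu, sigma, size=batch)
        half = np.abs(diff) / 2.0
        keep = half <= (b - a) / 2.0   # a valid pair mean exists
        mean = rng.uniform(a + half[keep], b - half[keep])
        td = mean + diff[keep] / 2.0
        df = mean - diff[keep] / 2.0
        proposed += batch
        accepted += int(keep.sum())
        take = min(int(keep.sum()), n - filled)
        co_td[filled:filled + take] = td[:take]
        co_df[filled:filled + take] = df[:take]
        filled += take
        if (filled < n and proposed >= _PROBE_SIZE
                and accepted / proposed < _MIN_ACCEPTANCE):
            raise GeneratorStalledError(
                f"acceptance rate {accepted / proposed:.2%} below "
                f"{_MIN_ACCEPTANCE:.0%}: loa too large relative to the "
                f"CO interval [{a}, {b}]"
            )
    return pd.DataFrame({
        "co_td": co_td,
        "co_df": co_df,
        "difference": co_td - co_df,
        "mean": (co_td + co_df) / 2.0,
    })


def difference_histogram(samples, bin_count: int = 30):
    """Bin the CO differences of generated pairs.

    Parameters
    ----------
    samples : DataFrame or array-like
        Output of :func:`generate_pairs` (its ``difference`` column is
        used) or a 1-d array of differences; at least one sample.
    bin_count : int
        Number of equally spaced bins over the observed range (≥ 1).

    Returns
    -------
    counts : ndarray of int
        Per-bin counts; sums to the number of samples.
    edges : ndarray
        ``bin_count + 1`` bin edges.
    """
    if bin_count < 1:
        raise InvalidParameterError(f"bin_count must be >= 1, got {bin_count!r}")
    if isinstance(samples, pd.DataFrame):
        diff = samples["difference"].to_numpy()
    else:
        diff = np.asarray(samples, dtype=float)
    if diff.size < 1:
        raise InvalidParameterError("need at least one sample")
    lo, hi = float(diff.min()), float(diff.max())
    if lo == hi:  # degenerate range: one occupied bin
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(diff, bins=bin_count, range=(lo, hi))
    return counts, edges
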