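"""Independent reference implementations used as test oracles.

These are deliberately written as plain single-pass walks over the two
mask rows, straight from the metric definitions, with no shared code
with the package's vectorised implementations.
"""

from __future__ import annotations

import random


def reference_gap_distance(a, b, metric: str) -> int:
    """Single-pass walk computing a pairwise gap distance.

    linear: 1 per disagreeing column. affine: 3 when the previous column
    agreed (or at column 0), else 1. cumulative: a counter that resets on
    agreement and grows by 1 per disagreeing column, summed.
    """
    assert len(a) == len(b)
    total = 0
    prev_disagree = False
    run = 0
    for x, y in zip(a, b):
        disagree = x != y
        if disagree:
            if metric == "linear":
                total += 1
            elif metric == "affine":
                total += 1 if prev_disagree else 3
            elif metric == "cumulative":
                run += 1
                total += run
            else:
                raise ValueError(metric)
        else:
            run = 0
        prev_disagree = disagree
    return total


def random_mask_pairs(n_pairs: int, max_len: int = 200, seed: int = 0):
    """Random binary mask pairs of equal length, lengths 1..max_len."""
    rng = random.Random(seed)
    pairs = []
    for _ in range(n_pairs):
        length = rng.randint(1, max_len)
        a = [rng.randint(0, 1) for _ in range(length)]
        b = [rng.randint(0, 1) for _ in range(length)]
        pairs.append((a, b))
    return pairs


def monte_carlo_bootstrap_expectations(values, n_draws: int = 200_000, seed: int = 0):
    """Brute-force expectations of the replicate mean and replicate sample sd.

    Resamples with replacement using Python's own RNG (independent of the
    implementation's numpy Generator) and averages the per-replicate mean
    and (n-1)-divisor standard deviation.
    """
    rng = random.Random(seed)
    n = len(values)
    sum_mean = 0.0
    sum_sd = 0.0
    for _ in range(n_draws):
        rep = [values[rng.randrange(n)] for _ in range(n)]
        mean = sum(rep) / n
        var = sum((x - mean) ** 2 for x in rep) / (n - 1)
        sum_mean += mean
        sum_sd += var ** 0.5
    return sum_mean / n_draws, sum_sd / n_draws
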