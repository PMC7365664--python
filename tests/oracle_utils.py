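"""Independent brute-force oracles used by the test suite.

Each oracle recomputes an operation's expected output by the most direct
means available (per-base occupancy arrays, per-base chain walks, exhaustive
enumeration) and stays independent of the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

from starrcre.intervals import GenomicInterval, RegionSet


def occupancy_union(intervals, size: int) -> np.ndarray:
    """Per-base boolean occupancy of a set of single-contig intervals."""
    occ = np.zeros(size, dtype=bool)
    for iv in intervals:
        occ[iv.start : min(iv.end, size)] = True
    return occ


def runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) runs of True values."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            in_run = False
            out.append((start, i))
    if in_run:
        out.append((start, len(mask)))
    return out


def random_region_set(rng, n: int, size: int, max_len: int = 200, contig="chr1"):
    starts = rng.integers(0, size - 1, size=n)
    lengths = rng.integers(1, max_len + 1, size=n)
    return RegionSet(
        GenomicInterval(contig, int(s), int(min(s + l, size)))
        for s, l in zip(starts, lengths)
    )


def bruteforce_bin_counts(fragments, bin_size: int, n_bins: int) -> np.ndarray:
    """Per-bin fragment-overlap counts by scanning every (fragment, bin)."""
    counts = np.zeros(n_bins, dtype=int)
    for iv in fragments:
        for b in range(n_bins):
            lo, hi = b * bin_size, (b + 1) * bin_size
            if min(iv.end, hi) - max(iv.start, lo) > 0:
                counts[b] += 1
    return counts


def bruteforce_map(truth: np.ndarray, start: int, end: int):
    """Expected liftover result from a per-base source->target truth array.

    Returns (target_start, target_end, mapped_fraction) or (None, None, frac).
    """
    vals = truth[start:end]
    mapped = vals[vals >= 0]
    frac = len(mapped) / (end - start)
    if len(mapped) == 0:
        return None, None, 0.0
    return int(mapped.min()), int(mapped.max()) + 1, frac


def hypergeom_tail(k_t: int, k_b: int, n_t: int, n_b: int) -> float:
    """One-sided tail P(X >= k_t) by direct summation of binomial products."""
    big_k = k_t + k_b
    big_n = n_t + n_b
    num = sum(
        math.comb(big_k, x) * math.comb(big_n - big_k, n_t - x)
        for x in range(k_t, min(big_k, n_t) + 1)
        if n_t - x <= big_n - big_k
    )
    return num / math.comb(big_n, n_t)


def bruteforce_r2(col_a: np.ndarray, col_b: np.ndarray) -> float | None:
    """r^2 as the squared Pearson correlation of the two allele columns."""
    if len(set(col_a.tolist())) < 2 or len(set(col_b.tolist())) < 2:
        return None
    return float(np.corrcoef(col_a, col_b)[0, 1] ** 2)
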