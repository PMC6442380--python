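"""Naive reference implementations used to cross-check the fast paths.

Each function here re-derives a result by direct enumeration or an
independent algorithm (sorted-order percentiles, per-bin scans, 2**n
sign assignments, exact hypergeometric sums, label permutations).  They
are deliberately slow and simple; production code never calls them —
they exist so tests and the validation experiments can compare two
independent routes to the same number.
"""

from __future__ import annotations

from itertools import product
from math import comb
from typing import List, Tuple

import numpy as np

from .track_io import BinnedTrack


def percentile_sorted(values: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile computed from an explicit sort."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (v.size - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))


def brute_force_regions(track: BinnedTrack, percentile: float,
                        min_length: int) -> List[Tuple[str, int, int]]:
    """Mark-merge-filter region calling by a per-bin O(n) scan."""
    threshold = percentile_sorted(track.all_values(), percentile)
    w = track.bin_width
    out: List[Tuple[str, int, int]] = []
    for chrom in track.chrom_lengths:
        vec = track.values[chrom]
        length = track.chrom_lengths[chrom]
        run_start = None
        for i in range(vec.size + 1):
            marked = i < vec.size and vec[i] >= threshold
            if marked and run_start is None:
                run_start = i
            elif not marked and run_start is not None:
                start = run_start * w
                end = min(i * w, length)
                if end - start >= min_length:
                    out.append((chrom, start, end))
                run_start = None
    return out


def wilcoxon_exact_enumeration(differences) -> float:
    """Two-sided signed-rank P from all 2**n sign assignments.

    P = min(1, 2 * min(P(W+ <= w), P(W+ >= w))) over the exact null in
    which each |d| takes either sign with probability 1/2.  Assumes no
    zero differences and no tied |d| (the caller's responsibility).
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    order = np.argsort(np.abs(d))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    w_obs = float(ranks[d > 0].sum())
    w_all = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product((False, True), repeat=n)
    ])
    p_le = np.mean(w_all <= w_obs)
    p_ge = np.mean(w_all >= w_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by exact integer hypergeometric enumeration.

    Fixes the margins of [[a, b], [c, d]] and sums the probabilities of
    all tables whose (exact, integer-arithmetic) point weight does not
    exceed the observed table's.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n_total = r1 + r2
    if n_total == 0:
        raise ValueError("all-zero table")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = comb(r1, a) * comb(r2, c)
    return min(1.0, sum(w for w in weights if w <= w_obs) / comb(n_total, c1))


def permutation_ttest(values_a, values_b, n_perm: int = 100_000,
                      rng: np.random.Generator | None = None) -> float:
    """Two-sided permutation P for a difference in means."""
    rng = rng or np.random.default_rng(0)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[:a.size].mean() - perm[a.size:].mean())
        if stat >= obs - 1e-12:
            hits += 1
    return hits / n_perm


def median_sorted(values) -> float:
    return percentile_sorted(np.asarray(values, dtype=float), 50.0)
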