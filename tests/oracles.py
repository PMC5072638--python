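"""Independent brute-force oracles used by the test suite.

These deliberately use explicit per-cell Python loops and enumeration so
that they share no code path with the vectorized implementation they
check.
"""

import itertools
import math

import numpy as np


def brute_interocular(target_values, contra_values):
    """Per-cell inter-ocular differences with explicit column mirroring.

    Returns (diffs, state) where state is 'neg', 'nonneg' or 'missing'.
    """
    nr, nc = target_values.shape
    diffs = np.full((nr, nc), np.nan)
    state = np.empty((nr, nc), dtype=object)
    for r in range(nr):
        for c in range(nc):
            t = target_values[r][c]
            m = contra_values[r][nc - 1 - c]
            if math.isnan(t) or math.isnan(m):
                state[r][c] = "missing"
                continue
            d = t - m
            diffs[r][c] = d
            state[r][c] = "neg" if d < 0 else "nonneg"
    return diffs, state


def brute_interhemispheric(values):
    """Per-cell mirrored-row differences; center row is 'centerline'."""
    nr, nc = values.shape
    assert nr % 2 == 1
    center = nr // 2
    diffs = np.full((nr, nc), np.nan)
    state = np.empty((nr, nc), dtype=object)
    for r in range(nr):
        for c in range(nc):
            if r == center:
                state[r][c] = "centerline"
                continue
            t = values[r][c]
            m = values[nr - 1 - r][c]
            if math.isnan(t) or math.isnan(m):
                state[r][c] = "missing"
                continue
            d = t - m
            diffs[r][c] = d
            state[r][c] = "neg" if d < 0 else "nonneg"
    return diffs, state


def brute_indices(diffs, state, cutoff):
    """Average negative difference and strict black count by explicit loop."""
    retained = [diffs[r][c]
                for r in range(diffs.shape[0]) for c in range(diffs.shape[1])
                if state[r][c] == "neg"]
    n_black = sum(1 for d in retained if d < -cutoff)
    avg = sum(retained) / len(retained) if retained else 0.0
    return avg, len(retained), n_black


def brute_auroc(pos, neg):
    """Pair-count AUROC: wins + half-ties over all pos×neg pairs."""
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def exact_mw_pvalue(a, b):
    """Two-sided Mann-Whitney p by full enumeration of labelings (no ties)."""
    pooled = list(a) + list(b)
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    n = len(pooled)
    us = []
    for combo in itertools.combinations(range(n), na):
        sa = [pooled[i] for i in combo]
        sb = [pooled[i] for i in range(n) if i not in combo]
        us.append(sum(1 for x in sa for y in sb if x > y))
    mean_u = sum(us) / len(us)
    # two-sided: probability of a U at least as extreme (as far from the mean)
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
    return extreme / len(us)
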