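"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, full enumeration) kept
separate from the library code paths they check.
"""

from itertools import combinations

import numpy as np


def brute_ratio_map(ch1, ch2, mask):
    """Per-voxel ch2/ch1 by explicit triple loop; NaN outside the mask."""
    nz, ny, nx = ch1.shape
    out = np.full((nz, ny, nx), np.nan)
    for i in range(nz):
        for j in range(ny):
            for k in range(nx):
                if mask[i, j, k]:
                    out[i, j, k] = ch2[i, j, k] / ch1[i, j, k]
    return out


def brute_sample_mean(ratios, mask):
    """Arithmetic mean of masked ratios by explicit accumulation."""
    total, count = 0.0, 0
    nz, ny, nx = ratios.shape
    for i in range(nz):
        for j in range(ny):
            for k in range(nx):
                if mask[i, j, k]:
                    total += ratios[i, j, k]
                    count += 1
    return total / count


def brute_depth_stats(ratios, mask, section):
    """(mean, min, max) over masked voxels of one section, by loops."""
    vals = []
    ny, nx = ratios[section].shape
    for j in range(ny):
        for k in range(nx):
            if mask[section, j, k]:
                vals.append(ratios[section, j, k])
    return (sum(vals) / len(vals), min(vals), max(vals))


def exact_rank_sum_p(a, b):
    """Exact two-sided Wilcoxon rank-sum p-value by full enumeration.

    Assumes no ties in the pooled sample.  Enumerates every assignment of
    pooled ranks to group a, builds the exact null distribution of the
    Mann-Whitney U statistic, and returns 2*min(P(U<=u), P(U>=u)) capped
    at 1.
    """
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    na = len(a)
    u_obs = sum(ranks[v] for v in a) - na * (na + 1) / 2
    us = []
    for combo in combinations(range(1, len(pooled) + 1), na):
        us.append(sum(combo) - na * (na + 1) / 2)
    us = np.array(us)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_lo, p_hi))


def welch_t_p(a, b):
    """Welch's t statistic and two-sided p from the textbook closed form."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t_stat = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t_stat), df)
    return t_stat, p
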