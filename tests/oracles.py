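"""Independent brute-force oracles used to cross-check the implementations."""

from itertools import combinations

import numpy as np


def brute_force_intersections(a, b):
    """All-pairs boolean: does a[i] overlap >= 1 bp of any interval in b?"""
    out = np.zeros(len(a), dtype=bool)
    for i, x in enumerate(a):
        for y in b:
            if x.chrom == y.chrom and x.start < y.end and y.start < x.end:
                out[i] = True
                break
    return out


def exact_wilcoxon_greater(x, y):
    """One-sided (x greater) rank-sum p by full enumeration; tie-free input.

    Enumerates every way of assigning the combined ranks to the x group and
    counts assignments whose U statistic (x-over-y pair wins) reaches the
    observed one.
    """
    x, y = list(x), list(y)
    combined = sorted(x + y)
    assert len(set(combined)) == len(combined), "oracle requires tie-free data"
    n = len(combined)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    count = total = 0
    for x_idx in combinations(range(n), len(x)):
        xs = set(x_idx)
        u = sum(1 for i in x_idx for j in range(n) if j not in xs and i > j)
        total += 1
        if u >= u_obs:
            count += 1
    return count / total


def grid_search_loglik(s, r, step=0.01):
    """Best mixture log-likelihood over a dense (theta_bg, theta_sig, pi) grid."""
    s = np.asarray(s, dtype=np.int64)
    r = np.asarray(r, dtype=np.int64)
    thetas = np.arange(step, 1.0, step)
    from scipy.special import gammaln

    n = s + r
    log_coef = gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1)
    # logpmf for every grid theta x region
    pmf = (
        log_coef[None, :]
        + s[None, :] * np.log(thetas)[:, None]
        + (n - s)[None, :] * np.log1p(-thetas)[:, None]
    )
    best = -np.inf
    for pi in np.arange(step, 1.0, step):
        a = np.log(pi) + pmf  # (T, R)
        b = np.log1p(-pi) + pmf
        ll = np.logaddexp(a[:, None, :], b[None, :, :]).sum(axis=2)
        best = max(best, float(ll.max()))
    return best


def brute_force_bin_counts(tag_positions, summit_pos, flank, bin_size):
    """Per-tag scan bin counting for one summit window."""
    n_bins = (2 * flank) // bin_size
    counts = np.zeros(n_bins)
    w_start = summit_pos - flank
    for p in tag_positions:
        offset = p - w_start
        if 0 <= offset < 2 * flank:
            counts[offset // bin_size] += 1
    return counts
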