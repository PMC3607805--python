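"""Hartigan-type dip statistic and Monte Carlo test of unimodality.

The dip of a sample is ``min_G sup_x |F_n(x) - G(x)|`` over all unimodal
distribution functions G (convex up to some mode, concave after).  The
implementation uses the following exact reduction.  Fix the mode between
order statistics k and k+1.  A unimodal G within sup-distance eps of F_n
exists iff there is a convex sequence through the bands
``[(i+1)/n - eps, i/n + eps]`` at the prefix points and a concave sequence
through the same bands at the suffix points (the band form collects the sup
over every constant piece of F_n, including the tails).  Convex feasibility
of uniform bands is a chord condition: it holds iff the empirical CDF's
lower corners never fall more than ``2*eps`` below any chord of the prefix,
i.e. ``2*eps >= max_i [(i+1)/n - gcm(x_i)]`` with gcm the greatest convex
minorant of the prefix lower corners; concave feasibility is the mirror
statement with the least concave majorant of the suffix upper corners.
Hence

    dip = min_k max( eps_convex(prefix k), eps_concave(suffix k+1) )

where both terms are half the corresponding maximal hull deviation.  The
prefix term is nondecreasing in k and the suffix term nonincreasing, so the
minimizer is located by bisection with O(n) hull evaluations.

The p-value is calibrated by Monte Carlo against uniform samples of the
same size, the least-favorable unimodal null for the dip.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def _collapse_ties(x: np.ndarray):
    """Distinct abscissae with lowest/highest original index per value."""
    n = len(x)
    distinct, first = np.unique(x, return_index=True)
    last = np.r_[first[1:] - 1, n - 1]
    return distinct, first, last


def _prefix_convex_eps(xd, lo_val, up_val, m):
    """Half the max deviation of the lower band above the gcm of the upper
    band corners, over distinct points 0..m (inclusive)."""
    # lower convex hull (monotone chain) of (xd[i], up_val[i]), i <= m
    hull = [0]
    for i in range(1, m + 1):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # keep hull convex: slope(a,b) <= slope(b,i)
            if (up_val[b] - up_val[a]) * (xd[i] - xd[b]) <= (
                up_val[i] - up_val[b]
            ) * (xd[b] - xd[a]):
                break
            hull.pop()
        hull.append(i)
    hx = xd[hull]
    hy = up_val[hull]
    gcm = np.interp(xd[: m + 1], hx, hy)
    return 0.5 * float(np.max(lo_val[: m + 1] - gcm))


def dip_statistic(x) -> float:
    """Dip statistic of a 1-d sample (0 for degenerate samples)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return 0.0
    xd, first, last = _collapse_ties(x)
    nd = len(xd)
    # band corners per distinct point: ecdf lower corner uses the smallest
    # original index, upper corner the largest
    low_corner = first / n          # F_n just left of the point
    high_corner = (last + 1) / n    # F_n at the point
    # prefix convex term: deviation of high corners above gcm of low corners
    # suffix concave term: mirror by reflecting the sample
    xr = -xd[::-1]
    low_r = (1.0 - high_corner)[::-1]
    high_r = (1.0 - low_corner)[::-1]

    def eps_convex(m):           # prefix 0..m of the original sample
        return _prefix_convex_eps(xd, high_corner, low_corner, m)

    def eps_concave(j):          # suffix j..nd-1 of the original sample
        m = nd - 1 - j
        return _prefix_convex_eps(xr, high_r, low_r, m)

    # mode between distinct points k and k+1; k = -1 => all concave,
    # k = nd-1 => all convex.  eps_convex(k) grows with k, eps_concave(k+1)
    # shrinks, so bisect for the crossover and scan its neighborhood.
    def term(k):
        a = eps_convex(k) if k >= 0 else 0.0
        b = eps_concave(k + 1) if k + 1 <= nd - 1 else 0.0
        return max(a, b)

    lo, hi = -1, nd - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        a = eps_convex(mid) if mid >= 0 else 0.0
        b = eps_concave(mid + 1) if mid + 1 <= nd - 1 else 0.0
        if a >= b:
            hi = mid
        else:
            lo = mid
    candidates = range(max(-1, lo - 2), min(nd - 1, hi + 2) + 1)
    return min(term(k) for k in candidates)


_NULL_CACHE: dict = {}


def _null_dips(n: int, n_boot: int) -> np.ndarray:
    """Monte Carlo null distribution of the dip for uniform samples of size n.

    Cached per (n, n_boot) with a fixed internal seed: the null depends only
    on the sample size, so the same table serves every test at that size.
    """
    key = (n, n_boot)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(12345)
        _NULL_CACHE[key] = np.array(
            [dip_statistic(rng.random(n)) for _ in range(n_boot)]
        )
    return _NULL_CACHE[key]


def dip_test(
    x,
    n_boot: int = 100,
    max_n: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Dip statistic and Monte Carlo p-value against the uniform null.

    Samples larger than ``max_n`` are subsampled (without replacement) for
    speed; the null replicates use the same effective size.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = np.asarray(x, dtype=float)
    if len(x) > max_n:
        x = rng.choice(x, max_n, replace=False)
    n = len(x)
    d = dip_statistic(x)
    null = _null_dips(n, n_boot)
    p = (1.0 + np.sum(null >= d)) / (n_boot + 1.0)
    return d, float(p)
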