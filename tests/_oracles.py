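"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately naive (explicit Python loops, textbook
formulas) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def running_mean_loop(x, window_samples):
    """Centered truncated-window mean by direct looping."""
    n = len(x)
    half = window_samples // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(i - half, 0)
        hi = min(i + (window_samples - 1 - half), n - 1)
        out[i] = sum(x[lo:hi + 1]) / (hi - lo + 1)
    return out


def vedba_loop(dx, dy, dz):
    """Per-sample vector norm in mg, one sample at a time."""
    return np.array([math.sqrt(a * a + b * b + c * c) * 1000.0
                     for a, b, c in zip(dx, dy, dz)])


def neighbor_counts_pairs(times, hr, tw, hw):
    """All-pairs neighbor counting."""
    n = len(times)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and abs(times[i] - times[j]) <= tw \
                    and abs(hr[i] - hr[j]) <= hw:
                counts[i] += 1
    return counts


def density_keep_mask(times, hr, tw, hw, keep_fraction):
    """Reference keep rule: top ceil(f*n) by count, ties at the cut kept."""
    counts = neighbor_counts_pairs(times, hr, tw, hw)
    k = math.ceil(keep_fraction * len(times))
    cutoff = sorted(counts, reverse=True)[k - 1]
    return counts >= cutoff


def haversine_ref(lat1, lon1, lat2, lon2, r=6371.0):
    """Textbook haversine, scalar."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = math.radians(lat2 - lat1)
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


def ols_normal_equations(X, y):
    """beta, se via explicit normal equations and matrix inversion."""
    XtX = X.T @ X
    beta = np.linalg.inv(XtX) @ X.T @ y
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (X.shape[0] - X.shape[1])
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    return beta, se


def oneway_balanced_reml(y_groups):
    """Closed-form REML for the balanced one-way random-effects layout.

    y_ij = mu + b_i + e_ij with a groups of n each:
    sigma_e^2 = MSW, sigma_b^2 = max((MSB - MSW)/n, 0), mu = grand mean.
    """
    a = len(y_groups)
    n = len(y_groups[0])
    grand = np.mean([v for g in y_groups for v in g])
    group_means = np.array([np.mean(g) for g in y_groups])
    ssw = sum(float(np.sum((np.asarray(g) - m) ** 2))
              for g, m in zip(y_groups, group_means))
    ssb = n * float(np.sum((group_means - grand) ** 2))
    msw = ssw / (a * (n - 1))
    msb = ssb / (a - 1)
    return grand, msw, max((msb - msw) / n, 0.0)
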