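"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by the most literal method
available (exhaustive scans, normal equations, textbook formulas) so they
stay independent of the library code paths they check.
"""

import numpy as np


def brute_force_peaks(x, min_prominence):
    """O(n^2) topographic peak finder.

    A peak is an interior sample strictly greater than both neighbors.  Its
    prominence: walk left (right) until a strictly higher sample or the
    edge, take the minimum along each walk, and subtract the higher of the
    two minima from the peak height.
    """
    peaks, proms = [], []
    n = len(x)
    for i in range(1, n - 1):
        if not (x[i] > x[i - 1] and x[i] > x[i + 1]):
            continue
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        right_min = x[i]
        j = i + 1
        while j < n and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        prom = x[i] - max(left_min, right_min)
        if prom >= min_prominence:
            peaks.append(i)
            proms.append(prom)
    return np.array(peaks, dtype=int), np.array(proms)


def half_prominence_width(x, peak, prominence, left_base, right_base):
    """Brute-force width at half prominence via linear crossing search."""
    level = x[peak] - 0.5 * prominence
    i = peak
    while i > left_base and x[i] > level:
        i -= 1
    if x[i] > level:
        left = float(i)
    else:
        left = i + (level - x[i]) / (x[i + 1] - x[i])
    i = peak
    while i < right_base and x[i] > level:
        i += 1
    if x[i] > level:
        right = float(i)
    else:
        right = i - (level - x[i]) / (x[i - 1] - x[i])
    return right - left


def ols_normal_equations(X, y):
    """Closed-form least squares with intercept via the normal equations."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    return beta[0], beta[1:]


def pearson_two_pass(a, b):
    """Textbook two-pass Pearson correlation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    am, bm = a.mean(), b.mean()
    num = ((a - am) * (b - bm)).sum()
    den = np.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum())
    return num / den


def bh_step_up(p, alpha):
    """Literal Benjamini-Hochberg step-up: largest k with p_(k) <= k/m*alpha."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k / m * alpha:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def r2_two_pass(y, yhat):
    """1 - SSE/SST computed naively."""
    y = np.asarray(y, dtype=float)
    sse = ((y - yhat) ** 2).sum()
    sst = ((y - y.mean()) ** 2).sum()
    return 1.0 - sse / sst
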