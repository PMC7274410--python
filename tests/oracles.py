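"""Independent brute-force reference implementations used only by tests.

Each function re-derives a quantity from first principles (fixed-step
integration, explicit sums of squares, exhaustive agglomeration) without
touching the package's own code paths.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def rk4_pairwise_batch(
    alpha, beta, g, h, reg_values, x0, times, dt=1e-3, eps_frac=1e-6
):
    """Fixed-step RK4 integration of dX/dt = a*Xr(t)^g - b*X^h.

    Vectorized over a batch of parameter draws that share one sampling
    grid; ``reg_values`` has shape (batch, len(times)) and the regulator is
    piecewise-linear between grid points. Returns (batch, len(times)).
    """
    alpha, beta, g, h, x0 = map(np.atleast_1d, (alpha, beta, g, h, x0))
    reg_values = np.atleast_2d(np.asarray(reg_values, float))
    times = np.asarray(times, float)
    eps = eps_frac * np.maximum(reg_values.max(axis=1), x0)
    reg_values = np.maximum(reg_values, eps[:, None])

    def xr_at(t):
        k = np.clip(np.searchsorted(times, t, side="right") - 1, 0,
                    len(times) - 2)
        frac = (t - times[k]) / (times[k + 1] - times[k])
        return reg_values[:, k] + frac * (
            reg_values[:, k + 1] - reg_values[:, k]
        )

    def f(t, x):
        xt = np.maximum(x, eps)
        return alpha * xr_at(t) ** g - beta * xt**h

    out = np.empty_like(reg_values)
    x = x0.astype(float).copy()
    out[:, 0] = x
    for i in range(len(times) - 1):
        t0, t1 = times[i], times[i + 1]
        n = max(int(np.ceil((t1 - t0) / dt)), 1)
        hstep = (t1 - t0) / n
        t = t0
        for _ in range(n):
            k1 = f(t, x)
            k2 = f(t + hstep / 2, x + hstep / 2 * k1)
            k3 = f(t + hstep / 2, x + hstep / 2 * k2)
            k4 = f(t + hstep, x + hstep * k3)
            x = x + hstep / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += hstep
        out[:, i + 1] = x
    return np.maximum(out, eps[:, None])


def r_squared_direct(observed, predicted):
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    ss_res = float(((obs - pred) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def anova_from_scratch(groups):
    """One-way F and p from the explicit sums-of-squares decomposition."""
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    k, n = len(arrays), len(pooled)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = stats.f.sf(f, k - 1, n - k)
    return float(f), float(p)


def pooled_t_from_scratch(a, b):
    """Classical two-sample t with pooled variance, two-sided p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (
        ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    ) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def centroid_merges_brute_force(matrix):
    """Exhaustive centroid-linkage agglomeration; returns merge heights.

    At each step the pair of clusters with the smallest Euclidean distance
    between centroids merges (ties broken by lowest index pair).
    """
    matrix = np.asarray(matrix, float)
    clusters = [[i] for i in range(len(matrix))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            ci = matrix[clusters[i]].mean(axis=0)
            for j in range(i + 1, len(clusters)):
                cj = matrix[clusters[j]].mean(axis=0)
                d = float(np.linalg.norm(ci - cj))
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [
            c for k, c in enumerate(clusters) if k not in (i, j)
        ] + [merged]
    return np.array(heights)
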