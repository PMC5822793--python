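"""Independent brute-force oracles used by the unit and acceptance tests.

Each function re-derives a quantity by the most literal possible route
(triple loops, exhaustive enumeration, explicit sums, grid search) and
is kept independent of the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def tom_brute_force(adj: np.ndarray) -> np.ndarray:
    """Triple-loop unsigned topological overlap."""
    n = adj.shape[0]
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def c_index_brute_force(score, time, event) -> float:
    """Exhaustive pair enumeration of Harrell's C."""
    score, time, event = map(np.asarray, (score, time, event))
    num = den = 0.0
    n = len(score)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if score[i] > score[j]:
                    num += 1
                elif score[i] == score[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def hypergeom_upper_tail(overlap: int, universe: int, set_size: int, module_size: int) -> float:
    """P(X >= overlap) by the explicit combinatorial sum."""
    total = math.comb(universe, module_size)
    p = 0.0
    for i in range(overlap, min(set_size, module_size) + 1):
        p += math.comb(set_size, i) * math.comb(universe - set_size, module_size - i) / total
    return p


def average_linkage_brute_force(d: np.ndarray) -> list[float]:
    """Naive O(n^3) average-linkage agglomeration; returns merge heights."""
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def cox_grid_search(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                    lo: float = -5.0, hi: float = 5.0, tol: float = 1e-6) -> float:
    """Maximize the single-covariate Breslow partial likelihood by
    successive grid refinement."""

    def loglik(beta: float) -> float:
        eta = beta * x
        ll = 0.0
        for i in range(len(x)):
            if event[i] == 1:
                risk = eta[time >= time[i]]
                ll += eta[i] - np.log(np.sum(np.exp(risk)))
        return ll

    a, b = lo, hi
    while b - a > tol:
        grid = np.linspace(a, b, 41)
        vals = [loglik(g) for g in grid]
        k = int(np.argmax(vals))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, len(grid) - 1)]
    return (a + b) / 2.0


def pearson_hand(x: np.ndarray, y: np.ndarray) -> float:
    """Sum formula with ddof-1 standard deviations."""
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    sx = np.sqrt(np.sum(xm**2) / (n - 1))
    sy = np.sqrt(np.sum(ym**2) / (n - 1))
    return float(np.sum(xm * ym) / ((n - 1) * sx * sy))


def logrank_two_sample(g: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Explicit two-group sum of (O - E)^2 / V with hypergeometric variance."""
    O = E = V = 0.0
    for tt in np.unique(time[event == 1]):
        at_risk = time >= tt
        n_t = at_risk.sum()
        n1 = (at_risk & (g == 1)).sum()
        d_t = ((time == tt) & (event == 1)).sum()
        d1 = ((time == tt) & (event == 1) & (g == 1)).sum()
        O += d1
        E += d_t * n1 / n_t
        if n_t > 1:
            V += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    return (O - E) ** 2 / V


def exp_ph_sample(rng, n: int, beta: float, censor_target: float = 0.3,
                  h0: float = 0.1):
    """Single-covariate exponential proportional-hazards draw with
    uniform censoring roughly hitting the target fraction."""
    x = rng.standard_normal(n)
    T = rng.exponential(1.0 / (h0 * np.exp(beta * x)))
    if censor_target <= 0:
        return x, T, np.ones(n, dtype=int)
    lo_c, hi_c = T.min() * 1e-6, T.max() * 1e6
    for _ in range(100):
        mid = np.sqrt(lo_c * hi_c)
        if np.mean(np.minimum(T / mid, 1.0)) > censor_target:
            lo_c = mid
        else:
            hi_c = mid
    C = rng.uniform(0, np.sqrt(lo_c * hi_c), n)
    time = np.minimum(T, C)
    ev = (T <= C).astype(int)
    return x, time, ev
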