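"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (enumeration, closed
forms, Floyd-Warshall, exact rational arithmetic) and deliberately shares
no code with the package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, isclose

import numpy as np

TIE_TOL = 1e-12


def fw_distances(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths via Floyd-Warshall on l = 1/w."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def nodal_path_length(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if vals:
            out[i] = float(np.mean(vals))
    return out


def characteristic_path_length(d: np.ndarray) -> float:
    return float(np.nanmean(nodal_path_length(d)))


def global_efficiency(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(fw_distances(sub))
    return out


def clustering(weights: np.ndarray, family: str = "onnela") -> np.ndarray:
    """Triple-enumeration weighted clustering (onnela or zhang family)."""
    n = weights.shape[0]
    wmax = weights.max()
    if wmax == 0:
        return np.zeros(n)
    w = weights / wmax
    out = np.zeros(n)
    for i in range(n):
        closed = 0.0
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) == 3:
                    if family == "onnela":
                        closed += (w[i, j] * w[j, k] * w[k, i]) ** (1.0 / 3.0)
                    else:
                        closed += w[i, j] * w[j, k] * w[k, i]
        if family == "onnela":
            deg = sum(1 for j in range(n) if weights[i, j] > 0)
            denom = deg * (deg - 1)
        else:
            s = sum(w[i, j] for j in range(n))
            denom = s**2 - sum(w[i, j] ** 2 for j in range(n))
        out[i] = closed / denom if denom > 0 else 0.0
    return out


def shortest_path_counts(weights: np.ndarray, d: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of shortest s-t paths (DP over distance order)."""
    n = weights.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = sorted(range(n), key=lambda t: d[s, t])
        for t in order:
            if t == s or not np.isfinite(d[s, t]):
                continue
            total = 0.0
            for k in range(n):
                if k != t and weights[k, t] > 0 and np.isfinite(d[s, k]):
                    if isclose(d[s, k] + 1.0 / weights[k, t], d[s, t],
                               rel_tol=0, abs_tol=TIE_TOL * max(1.0, d[s, t])):
                        total += sigma[s, k]
            sigma[s, t] = total
    return sigma


def betweenness(weights: np.ndarray) -> np.ndarray:
    """Nodal betweenness over ordered pairs via pair-dependency counting."""
    n = weights.shape[0]
    d = fw_distances(weights)
    sigma = shortest_path_counts(weights, d)
    b = np.zeros(n)
    for i in range(n):
        for s in range(n):
            for t in range(n):
                if len({i, s, t}) == 3 and np.isfinite(d[s, t]) and sigma[s, t] > 0:
                    if isclose(d[s, i] + d[i, t], d[s, t],
                               rel_tol=0, abs_tol=TIE_TOL * max(1.0, d[s, t])):
                        b[i] += sigma[s, i] * sigma[i, t] / sigma[s, t]
    return b


def set_partitions(items: list):
    """Every partition of ``items`` into nonempty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity(weights: np.ndarray, labels: np.ndarray) -> float:
    m2 = weights.sum()
    if m2 == 0:
        return 0.0
    s = weights.sum(axis=1)
    q = 0.0
    n = weights.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += weights[i, j] - s[i] * s[j] / m2
    return q / m2


def best_partition_q(weights: np.ndarray) -> float:
    """Exhaustive-search maximal modularity (n <= ~9)."""
    n = weights.shape[0]
    best = -2.0
    for part in set_partitions(list(range(n))):
        lab = np.empty(n, dtype=int)
        for k, block in enumerate(part):
            lab[block] = k
        best = max(best, modularity(weights, lab))
    return best


def fisher_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by exact-rational hypergeometric enumeration."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    observed = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(x) <= observed:
            total += pmf(x)
    return float(total)


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the step-up recursion."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return adjusted


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Rank (average ties) then Pearson."""

    def rank(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = rank(np.asarray(x, float)), rank(np.asarray(y, float))
    return float(np.corrcoef(rx, ry)[0, 1])


def inclusion_any_window(censored: np.ndarray, window: int, max_fraction: float) -> bool:
    """Does any contiguous window of >= ``window`` volumes have a censored
    fraction <= ``max_fraction``?"""
    t = len(censored)
    for length in range(window, t + 1):
        for start in range(0, t - length + 1):
            if censored[start : start + length].sum() / length <= max_fraction:
                return True
    return False


def random_graph(rng: np.random.Generator, n: int, edge_p: float = 0.6) -> np.ndarray:
    """Random symmetric weight matrix in [0,1], zero diagonal."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    present = rng.random(iu[0].size) < edge_p
    vals = rng.uniform(0.05, 1.0, iu[0].size) * present
    w[iu] = vals
    return w + w.T
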