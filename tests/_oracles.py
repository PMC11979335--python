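"""Independent brute-force oracles for graph metrics and basic statistics.

Everything here is deliberately naive — exhaustive enumeration, Floyd-
Warshall triple loops, closed-form formulas — and shares no code path with
the package implementation.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def fw_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by Floyd-Warshall."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_clustering(a: np.ndarray) -> np.ndarray:
    """Per-node clustering by explicit neighbour-pair enumeration."""
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        if len(nb) < 2:
            continue
        links = sum(1 for u, v in itertools.combinations(nb, 2) if a[u, v])
        c[i] = 2.0 * links / (len(nb) * (len(nb) - 1))
    return c


def brute_lp(a: np.ndarray) -> float:
    d = fw_distances(a)
    n = a.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and math.isfinite(d[i, j])]
    return float(np.mean(vals))


def brute_eglob(a: np.ndarray) -> float:
    d = fw_distances(a)
    n = a.shape[0]
    total = sum(
        1.0 / d[i, j] if math.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
        for i in range(n)
        for j in range(n)
        if i != j
    )
    return total / (n * (n - 1))


def brute_ne(a: np.ndarray) -> np.ndarray:
    d = fw_distances(a)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / d[i, j] if math.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
            for j in range(n)
            if j != i
        ) / (n - 1)
    return out


def brute_nle(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        if len(nb) < 2:
            continue
        out[i] = brute_eglob(a[np.ix_(nb, nb)])
    return out


def _geodesics(a: np.ndarray, d: np.ndarray, s: int, t: int) -> list[list[int]]:
    """All shortest s-t paths by depth-first extension along the distance field."""
    if not math.isfinite(d[s, t]):
        return []
    paths = []

    def extend(path: list[int]) -> None:
        u = path[-1]
        if u == t:
            paths.append(path)
            return
        for w in range(a.shape[0]):
            if a[u, w] and d[s, w] == d[s, u] + 1 and d[w, t] == d[u, t] - 1:
                extend(path + [w])

    extend([s])
    return paths


def brute_betweenness(a: np.ndarray) -> np.ndarray:
    """Normalized betweenness by exhaustive geodesic enumeration."""
    n = a.shape[0]
    d = fw_distances(a)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _geodesics(a, d, s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc / ((n - 1) * (n - 2) / 2)


def pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    """Classic pooled-variance two-sample t from raw data."""
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (n1 + n2 - 2)
    return float((np.mean(x) - np.mean(y)) / math.sqrt(sp2 * (1 / n1 + 1 / n2)))


def bh_stepup(p: list[float], q: float) -> list[bool]:
    """Benjamini-Hochberg rejections computed by the textbook step-up rule."""
    m = len(p)
    order = sorted(range(m), key=lambda k: p[k])
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            kmax = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= kmax:
            reject[idx] = True
    return reject


def exact_mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    combined = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(ix: tuple[int, ...]) -> float:
        xs = combined[list(ix)]
        ys = np.delete(combined, list(ix))
        gt = sum(1.0 for a in xs for b in ys if a > b)
        eq = sum(0.5 for a in xs for b in ys if a == b)
        return gt + eq

    obs = u_stat(tuple(range(n1)))
    mu = n1 * (len(combined) - n1) / 2.0
    count = 0
    total = 0
    for ix in itertools.combinations(range(len(combined)), n1):
        total += 1
        if abs(u_stat(ix) - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


def trapezoid_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Trapezoid quadrature written out segment by segment."""
    return float(sum((y[k] + y[k + 1]) / 2.0 * (x[k + 1] - x[k]) for k in range(len(x) - 1)))
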