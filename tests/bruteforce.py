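"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — explicit loops, exhaustive
enumeration, textbook Floyd–Warshall — and shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def strength_oracle(w: np.ndarray) -> list[float]:
    n = w.shape[0]
    return [sum(w[i][j] for j in range(n)) for i in range(n)]


def clustering_oracle(w: np.ndarray) -> float:
    """Mean Onnela clustering by ordered-pair triangle enumeration."""
    n = w.shape[0]
    if n == 0 or w.max() == 0:
        return 0.0
    what = w / w.max()
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if w[i][j] > 0]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        s = 0.0
        for j, h in itertools.permutations(nbrs, 2):
            if w[j][h] > 0:
                s += (what[i][j] * what[i][h] * what[j][h]) ** (1.0 / 3.0)
        vals.append(s / (k * (k - 1)))
    return float(np.mean(vals))


def floyd_warshall_oracle(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths with edge length 1/w."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i][j] > 0:
                d[i][j] = 1.0 / w[i][j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def global_efficiency_oracle(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall_oracle(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i][j]) and d[i][j] > 0:
                total += 1.0 / d[i][j]
    return total / (n * (n - 1))


def local_efficiency_oracle(w: np.ndarray) -> float:
    n = w.shape[0]
    if n == 0:
        return 0.0
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if w[i][j] > 0]
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        vals.append(global_efficiency_oracle(sub))
    return float(np.mean(vals))


def weighted_rich_club_oracle(w: np.ndarray) -> dict[int, float]:
    """Φw(κ) by explicit subgraph extraction; only defined κ are returned."""
    n = w.shape[0]
    deg = [sum(1 for j in range(n) if w[i][j] > 0) for i in range(n)]
    all_weights = sorted(
        (w[i][j] for i in range(n) for j in range(i + 1, n) if w[i][j] > 0),
        reverse=True,
    )
    out = {}
    for k in range(1, max(deg) + 1 if deg else 1):
        club = [i for i in range(n) if deg[i] > k]
        inside = [
            w[i][j]
            for a, i in enumerate(club)
            for j in club[a + 1:]
            if w[i][j] > 0
        ]
        if not inside:
            continue
        out[k] = sum(inside) / sum(all_weights[: len(inside)])
    return out


def two_group_f_oracle(y: np.ndarray, labels: np.ndarray) -> float:
    """One-way two-group ANOVA F from group means (no covariates)."""
    levels = sorted(set(labels))
    groups = [y[labels == lev] for lev in levels]
    grand = y.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(levels) - 1
    df2 = len(y) - len(levels)
    if ssw == 0:
        return np.inf
    return (ssb / df1) / (ssw / df2)


def exact_two_group_perm_p(y: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p of the two-group F over all distinct label
    arrangements (observed arrangement included)."""
    f_obs = two_group_f_oracle(y, labels)
    seen = set()
    hits = total = 0
    for perm in itertools.permutations(range(len(y))):
        arrangement = tuple(labels[list(perm)])
        if arrangement in seen:
            continue
        seen.add(arrangement)
        total += 1
        if two_group_f_oracle(y, np.array(arrangement)) >= f_obs - 1e-12:
            hits += 1
    return hits / total


def random_connected_weighted_graph(rng: np.random.Generator, n_max: int = 8,
                                    p: float = 0.5) -> np.ndarray:
    """Random symmetric weighted graph with at least one edge (not
    necessarily connected)."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        a = rng.random((n, n)) < p
        w = np.where(a, rng.uniform(0.1, 5.0, (n, n)), 0.0)
        w = np.triu(w, 1)
        w = w + w.T
        if (w > 0).any():
            return w
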