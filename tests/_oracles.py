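"""Brute-force reference implementations used to check the package.

These deliberately avoid the code paths (and, for graph metrics, the
library calls) they are used to verify: shortest paths by explicit BFS,
betweenness by enumerating every shortest path, PageRank by hand-rolled
power iteration, AUC by exhaustive pairwise comparison.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    """Hop distances from ``source`` over an adjacency mapping."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _all_shortest_paths(adj: dict, s, t, dist_st: int) -> list[list]:
    """Every s→t path of exactly the shortest length, by DFS enumeration."""
    paths = []

    def extend(path: list) -> None:
        u = path[-1]
        if u == t:
            if len(path) - 1 == dist_st:
                paths.append(list(path))
            return
        if len(path) - 1 >= dist_st:
            return
        for v in adj[u]:
            if v not in path:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def betweenness_by_enumeration(adj: dict) -> dict:
    """Normalised node betweenness by listing all shortest paths."""
    nodes = sorted(adj)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist = bfs_distances(adj, s)
        for t in nodes[i + 1:]:
            if t == s or t not in dist:
                continue
            paths = _all_shortest_paths(adj, s, t, dist[t])
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                score[v] += through / len(paths)
    scale = (n - 1) * (n - 2) / 2.0
    if scale > 0:
        for v in score:
            score[v] /= scale
    return score


def closeness_per_component(adj: dict) -> dict:
    """(reachable − 1) / (sum of distances), 0 for isolated nodes."""
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def eccentricity_per_component(adj: dict) -> dict:
    return {v: float(max(bfs_distances(adj, v).values())) for v in adj}


def pagerank_power_iteration(adj: dict, weights: dict | None = None,
                             damping: float = 0.85, tol: float = 1e-13,
                             max_iter: int = 100000) -> dict:
    """Weighted PageRank by plain power iteration with uniform dangling
    redistribution (isolated nodes are dangling)."""
    nodes = sorted(adj)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}

    def w(u, v):
        if weights is None:
            return 1.0
        return weights.get((u, v), weights.get((v, u), 1.0))

    strength = {u: sum(w(u, v) for v in adj[u]) for u in nodes}
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = np.full(n, (1.0 - damping) / n)
        dangling_mass = sum(x[idx[u]] for u in nodes if strength[u] == 0)
        new += damping * dangling_mass / n
        for u in nodes:
            if strength[u] == 0:
                continue
            for v in adj[u]:
                new[idx[v]] += damping * x[idx[u]] * w(u, v) / strength[u]
        if np.abs(new - x).sum() < tol:
            x = new
            break
        x = new
    return {v: float(x[idx[v]]) for v in nodes}


def auc_by_pairwise_comparison(scores, labels) -> float:
    """AUC as the Mann–Whitney probability: fraction of (positive,
    negative) pairs ranked correctly, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def translate_diff(cds: str, pos: int, alt: str) -> tuple[str, str, int]:
    """Amino-acid change by translating both full sequences and diffing.

    Returns (aa_ref, aa_alt, residue) for the single codon containing
    ``pos``; the surrounding protein is asserted unchanged.
    """
    from Bio.Seq import Seq

    mutated = cds[: pos - 1] + alt + cds[pos:]
    prot_ref = str(Seq(cds).translate())
    prot_alt = str(Seq(mutated).translate())
    residue = (pos - 1) // 3 + 1
    assert (prot_ref[: residue - 1] == prot_alt[: residue - 1]
            and prot_ref[residue:] == prot_alt[residue:])
    return prot_ref[residue - 1], prot_alt[residue - 1], residue
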