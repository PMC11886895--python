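"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive — all-pairs set intersections,
exhaustive path/draw enumeration, literal formula transcriptions — and
shares no code with the package.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def naive_cerna_pairs(circ_map, gene_map, min_shared):
    """All-pairs set-intersection enumeration of competitive pairs."""
    out = {}
    for c, cm in circ_map.items():
        for g, gm in gene_map.items():
            shared = cm & gm
            if len(shared) >= min_shared:
                out[(c, g)] = frozenset(shared)
    return out


def naive_map_variant(pos, features, window_bp, k):
    """Distance-sort union rule: window hits ∪ per-side nearest-k, per type.

    ``features`` are (id, ftype, start, end) tuples on the variant's
    chromosome. Returns {(id, ftype): (relation, distance)}.
    """
    out = {}
    for ftype in {f[1] for f in features}:
        feats = [f for f in features if f[1] == ftype]
        dists = {}
        for fid, _, s, e in feats:
            if s <= pos < e:
                d = 0
            elif pos < s:
                d = s - pos
            else:
                d = pos - (e - 1)
            dists[fid] = d
        left = sorted(
            [f for f in feats if f[3] <= pos],
            key=lambda f: (dists[f[0]], f[2], f[0]),
        )[:k]
        right = sorted(
            [f for f in feats if f[2] > pos],
            key=lambda f: (dists[f[0]], f[2], f[0]),
        )[:k]
        for fid, _, s, e in feats:
            inside = s <= pos < e
            in_window = dists[fid] <= window_bp
            ranked = any(fid == f[0] for f in left + right)
            if inside:
                out[(fid, ftype)] = ("inside", 0)
            elif in_window:
                out[(fid, ftype)] = ("within_window", dists[fid])
            elif ranked:
                out[(fid, ftype)] = ("closest_rank_k", dists[fid])
    return out


def welch_formulas(x, y):
    """Literal transcription of the Welch t and Welch–Satterthwaite df."""
    from scipy.stats import t as tdist

    nx_, ny = len(x), len(y)
    mx = sum(x) / nx_
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx_ - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx_ + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx_) ** 2 / (nx_ - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def bh_stepup(p_values):
    """Independently coded BH step-up (explicit loop, no vectorization)."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def enumerate_shortest_path_betweenness(edges, nodes):
    """Exhaustive betweenness: enumerate every shortest path by BFS backtrack.

    Returns the unnormalized, undirected (halved) betweenness per node.
    """
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def shortest_paths(s, t):
        # BFS levels from s, then backtrack all geodesics to t
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        if t not in dist:
            return []
        paths = []

        def back(path):
            u = path[-1]
            if u == s:
                paths.append(path[::-1])
                return
            for v in adj[u]:
                if dist.get(v, -1) == dist[u] - 1:
                    back(path + [v])

        back([t])
        return paths

    bet = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = shortest_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                bet[v] += 1.0 / len(paths)
    return bet


def exact_mannwhitney_greater(x, y):
    """Exact one-sided (x > y) Mann–Whitney p by enumerating group splits."""
    def u_stat(a, b):
        return sum(
            1.0 if ai > bj else 0.5 if ai == bj else 0.0 for ai in a for bj in b
        )

    pooled = list(x) + list(y)
    n1 = len(x)
    observed = u_stat(x, y)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        if u_stat(a, b) >= observed - 1e-12:
            count += 1
        total += 1
    return observed, count / total


def hypergeom_tail_by_enumeration(N, K, n, k):
    """P[overlap ≥ k] by enumerating every size-n draw from an N-universe."""
    universe = list(range(N))
    special = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        if len(special & set(draw)) >= k:
            hits += 1
        total += 1
    return hits / total
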