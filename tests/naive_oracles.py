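"""Independent, deliberately naive reference implementations.

Everything here is coded directly from the printed definitions with plain
Python loops, sharing no code path with the package, so the tests can treat
these as independent oracles.
"""

from __future__ import annotations

import math


def naive_lambda(g: list[float]) -> float:
    """Dense scan + bisection for the nonzero root of ∏(1+λg_i) = 1+λ."""
    def f(lam: float) -> float:
        prod = 1.0
        for gi in g:
            prod *= 1.0 + lam * gi
        return prod - (1.0 + lam)

    total = sum(g)
    if abs(total - 1.0) <= 1e-12:
        return 0.0
    if total > 1.0:
        lo, hi = -1.0 + 1e-9, -1e-12
    else:
        lo, hi = 1e-12, 1.0
        while f(hi) <= 0.0:
            hi *= 2.0
            if hi > 1e9:
                raise ArithmeticError("no bracket")
    # coarse scan to tighten the bracket, then plain bisection
    steps = 2000
    prev_l, prev_v = lo, f(lo)
    for k in range(1, steps + 1):
        lam = lo + (hi - lo) * k / steps
        v = f(lam)
        if prev_v * v <= 0.0:
            lo, hi = prev_l, lam
            break
        prev_l, prev_v = lam, v
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def naive_chain(g_ordered: list[float], lam: float) -> list[float]:
    chain = [g_ordered[0]]
    for gi in g_ordered[1:]:
        chain.append(chain[-1] + gi + lam * gi * chain[-1])
    return chain


def naive_choquet(h_sorted: list[float], chain: list[float]) -> float:
    n = len(h_sorted)
    h = list(h_sorted) + [0.0]
    return sum((h[i] - h[i + 1]) * chain[i] for i in range(n))


def _clip(v: float) -> float:
    return min(max(v, 0.0), 1.0)


def naive_generalized(op, h_sorted, chain, M, h0=1.0, d3_ratio_of_sum=True) -> float:
    """Term-by-term transcription of the ten generalized-integral formulas.

    ``M`` is a plain callable on [0,1]^2.
    """
    n = len(h_sorted)
    h = list(h_sorted) + [0.0]
    total = 0.0
    for i in range(n):
        hi, hnext = h[i], h[i + 1]
        hprev = h0 if i == 0 else h[i - 1]
        G = chain[i]
        if op in ("CM", "CFM"):
            total += M(_clip(hi - hnext), G)
        elif op == "CCM":
            total += M(hi, G) - M(hnext, G)
        elif op == "CMC":
            total += M(hi, G) - M(hnext, G) + M(_clip(hi - hnext), G)
        elif op == "CMMin":
            total += M(_clip(min(hi, G) - min(hnext, G)), G)
        elif op == "CMMin2":
            total += M(min(hi, G), min(hnext, G))
        elif op == "CMinM":
            total += min(M(hi, G), M(hnext, G))
        elif op == "CD1":
            total += M(_clip(hprev - hnext), G)
        elif op == "CD2":
            total += M(_clip(hprev + hnext - hi), G)
        elif op == "CD3":
            if hi == 0.0:
                continue
            arg = (hprev + hnext) / hi if d3_ratio_of_sum else hprev + hnext / hi
            total += M(_clip(arg), G)
        else:
            raise ValueError(op)
    if op == "CFM":
        total = min(total, 1.0)
    return total


def naive_owa(x: list[float], normalized: bool = True) -> float:
    n = len(x)
    y = sorted(x, reverse=True)
    w = [1.0 - j / n for j in range(n)]
    if normalized:
        s = sum(w)
        w = [wj / s for wj in w]
    return sum(wj * yj for wj, yj in zip(w, y))


# --- tree oracles ----------------------------------------------------------


def tree_from_pruefer(seq: list[int], m: int) -> list[tuple[int, int]]:
    """Decode a Prüfer sequence of length m-2 into the edge list of a tree."""
    degree = [1] * m
    for v in seq:
        degree[v] += 1
    edges = []
    seq = list(seq)
    for v in seq:
        for leaf in range(m):
            if degree[leaf] == 1:
                edges.append((min(leaf, v), max(leaf, v)))
                degree[leaf] -= 1
                degree[v] -= 1
                break
    last = [v for v in range(m) if degree[v] == 1]
    edges.append((min(last), max(last)))
    return edges


def brute_tree_metrics(edges: list[tuple[int, int]], m: int) -> dict:
    """All five global tree metrics by explicit path enumeration.

    The unique path between each node pair is found by DFS; betweenness of a
    node is the fraction of pairs whose path crosses it as an intermediate,
    normalized by (m-1)(m-2)/2.
    """
    adj = {v: [] for v in range(m)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)

    def path(s, t):
        stack = [(s, [s])]
        while stack:
            v, p = stack.pop()
            if v == t:
                return p
            for w in adj[v]:
                if w not in p:
                    stack.append((w, p + [w]))
        raise AssertionError("disconnected")

    through = [0] * m
    diameter = 0
    for s in range(m):
        for t in range(s + 1, m):
            p = path(s, t)
            diameter = max(diameter, len(p) - 1)
            for v in p[1:-1]:
                through[v] += 1
    pairs = (m - 1) * (m - 2) / 2.0
    bc = [c / pairs if pairs > 0 else 0.0 for c in through]
    degrees = [len(adj[v]) for v in range(m)]
    leaves = sum(1 for d in degrees if d == 1)
    bc_max = max(bc)
    return {
        "max_degree": max(degrees),
        "max_bc": bc_max,
        "leaf_fraction": leaves / m,
        "diameter": diameter,
        "hierarchy": leaves / (2.0 * (m - 1) * bc_max) if bc_max > 0 else 0.0,
    }


def all_spanning_trees_best(weights: dict[tuple[int, int], float], m: int):
    """Enumerate every spanning tree via Prüfer sequences; return the max-weight one."""
    import itertools

    best = None
    if m == 2:
        candidates = [[(0, 1)]]
    else:
        candidates = [
            tree_from_pruefer(list(seq), m)
            for seq in itertools.product(range(m), repeat=m - 2)
        ]
    for edges in candidates:
        w = sum(weights[e] for e in edges)
        if best is None or w > best[0]:
            best = (w, sorted(edges))
    return best
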