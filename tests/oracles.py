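"""Independent brute-force reference implementations for the metric tests.

Everything here enumerates dyads, triples and geodesics directly from the
arc set — no networkx, no shared code with the package — so agreement with
the package is a genuine cross-check, not a tautology. Nodes are integers
0..n-1 and a graph is a plain ``set`` of ordered pairs.
"""

from __future__ import annotations

from itertools import product

INF = float("inf")


def bf_dyad_census(n: int, arcs: set[tuple[int, int]]) -> tuple[int, int, int]:
    m = a = 0
    for i in range(n):
        for j in range(i + 1, n):
            ij, ji = (i, j) in arcs, (j, i) in arcs
            if ij and ji:
                m += 1
            elif ij or ji:
                a += 1
    return m, a, n * (n - 1) // 2 - m - a


def bf_density(n: int, arcs) -> float:
    return len(arcs) / (n * (n - 1))


def bf_degrees(n: int, arcs) -> list[tuple[int, int, int]]:
    rows = []
    for v in range(n):
        din = sum(1 for e, a in arcs if a == v)
        dout = sum(1 for e, a in arcs if e == v)
        rows.append((din, dout, din + dout))
    return rows


def bf_isolates(n: int, arcs) -> list[int]:
    deg = bf_degrees(n, arcs)
    return [v for v in range(n) if deg[v][2] == 0]


def bf_reciprocity(n: int, arcs) -> tuple[float | None, float | None]:
    m, a, _ = bf_dyad_census(n, arcs)
    arc_based = 2 * m / (2 * m + a) if (2 * m + a) else None
    dyad_based = m / (m + a) if (m + a) else None
    return arc_based, dyad_based


def bf_components(n: int, arcs) -> tuple[int, list[tuple[int, ...]]]:
    """Weak components among non-isolates, by depth-first search."""
    iso = set(bf_isolates(n, arcs))
    nodes = [v for v in range(n) if v not in iso]
    nbr = {v: set() for v in nodes}
    for e, a in arcs:
        nbr[e].add(a)
        nbr[a].add(e)
    seen: set[int] = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], []
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(nbr[v] - seen)
        comps.append(tuple(sorted(comp)))
    comps.sort(key=lambda c: (-len(c), c[0]))
    return max(0, len(comps) - 1), comps


def bf_distances(n: int, arcs) -> list[list[float]]:
    """All-pairs directed geodesics by Floyd–Warshall."""
    d = [[0 if i == j else (1 if (i, j) in arcs else INF) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def bf_transitivity(n: int, arcs) -> float | None:
    paths = closed = 0
    for i, j, k in product(range(n), repeat=3):
        if i == j or j == k or i == k:
            continue
        if (i, j) in arcs and (j, k) in arcs:
            paths += 1
            if (i, k) in arcs:
                closed += 1
    return closed / paths if paths else None


def bf_compactness(n: int, arcs) -> float:
    d = bf_distances(n, arcs)
    total = sum(
        1.0 / d[i][j]
        for i in range(n)
        for j in range(n)
        if i != j and d[i][j] < INF
    )
    return total / (n * (n - 1))


def _geodesic_counts(n: int, arcs) -> list:
    """sigma[d][i][j]: number of walks of length d — walks of geodesic
    length are exactly the geodesics."""
    a = [[1 if (i, j) in arcs else 0 for j in range(n)] for i in range(n)]
    powers = [[[1 if i == j else 0 for j in range(n)] for i in range(n)]]
    cur = [row[:] for row in powers[0]]
    for _ in range(n):
        nxt = [
            [sum(cur[i][k] * a[k][j] for k in range(n)) for j in range(n)]
            for i in range(n)
        ]
        powers.append(nxt)
        cur = nxt
    return powers


def bf_betweenness(n: int, arcs) -> list[float]:
    """Directed betweenness via matrix-power geodesic counting,
    normalized by (n-1)(n-2)."""
    dist = bf_distances(n, arcs)
    powers = _geodesic_counts(n, arcs)
    btw = [0.0] * n
    for v in range(n):
        for s in range(n):
            for t in range(n):
                if len({s, t, v}) < 3 or dist[s][t] == INF:
                    continue
                d_st = int(dist[s][t])
                sigma = powers[d_st][s][t]
                if dist[s][v] == INF or dist[v][t] == INF:
                    continue
                if dist[s][v] + dist[v][t] != dist[s][t]:
                    continue
                through = powers[int(dist[s][v])][s][v] * powers[int(dist[v][t])][v][t]
                btw[v] += through / sigma
    norm = (n - 1) * (n - 2)
    return [b / norm for b in btw]


def bf_closeness(n: int, arcs) -> list[float]:
    """Wasserman–Faust outward closeness, 0 when nothing is reachable."""
    dist = bf_distances(n, arcs)
    scores = []
    for i in range(n):
        reach = [dist[i][j] for j in range(n) if j != i and dist[i][j] < INF]
        r = len(reach)
        scores.append((r / (n - 1)) * (r / sum(reach)) if r else 0.0)
    return scores


def bf_centralization(n: int, arcs, kind: str) -> float:
    if n < 3:
        return 0.0
    deg = bf_degrees(n, arcs)
    if kind == "degree":
        scores = [t for _i, _o, t in deg]
        denom = 2 * (n - 1) * (n - 2)
    elif kind == "indegree":
        scores = [i for i, _o, _t in deg]
        denom = (n - 1) ** 2
    elif kind == "outdegree":
        scores = [o for _i, o, _t in deg]
        denom = (n - 1) ** 2
    elif kind == "closeness":
        scores = bf_closeness(n, arcs)
        denom = (n - 1) * (n - 2) / (2 * n - 3)
    elif kind == "betweenness":
        scores = bf_betweenness(n, arcs)
        denom = n - 1
    else:
        raise ValueError(kind)
    c_max = max(scores)
    return min(1.0, max(0.0, sum(c_max - c for c in scores) / denom))
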