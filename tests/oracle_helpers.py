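"""Independent brute-force oracles for the graph metrics.

Deliberately naive: explicit breadth-first distances, explicit enumeration of
every geodesic, explicit triple checks. These share no code with the package
implementations they are used to verify.
"""

from collections import deque
from itertools import combinations

INF = float("inf")


def _bfs_distances(nodes, succ, source):
    dist = {v: INF for v in nodes}
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in succ[u]:
            if dist[v] == INF:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _succ_map(nodes, edges):
    succ = {v: [] for v in nodes}
    for u, v in edges:
        succ[u].append(v)
    return succ


def enumerate_geodesics(nodes, edges, s, t):
    """All shortest directed paths s -> t, as explicit node tuples."""
    succ = _succ_map(nodes, edges)
    dist_from_s = _bfs_distances(nodes, succ, s)
    if dist_from_s[t] == INF:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in succ[u]:
            if dist_from_s[v] == dist_from_s[u] + 1 and dist_from_s[v] <= dist_from_s[t]:
                # still on some shortest route toward t?
                rest = _bfs_distances(nodes, succ, v)
                if dist_from_s[v] + rest[t] == dist_from_s[t]:
                    extend(path + [v])

    extend([s])
    return paths


def brute_betweenness(nodes, edges):
    """Fractional geodesic betweenness by total enumeration of shortest paths."""
    nodes = list(nodes)
    score = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = enumerate_geodesics(nodes, edges, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                score[v] += through / len(paths)
    return score


def brute_triangles(nodes, edges, ego):
    """Unordered classmate pairs closing an any-direction triangle with ego."""
    tied = {frozenset(e) for e in edges}
    count = 0
    for a, b in combinations([v for v in nodes if v != ego], 2):
        if (
            frozenset((ego, a)) in tied
            and frozenset((ego, b)) in tied
            and frozenset((a, b)) in tied
        ):
            count += 1
    return count


def brute_directed_triads(nodes, edges, ego):
    """Ordered distinct triples (i, j, k) containing ego with i->j, j->k, i->k."""
    eset = set(edges)
    count = 0
    for i in nodes:
        for j in nodes:
            for k in nodes:
                if len({i, j, k}) < 3 or ego not in (i, j, k):
                    continue
                if (i, j) in eset and (j, k) in eset and (i, k) in eset:
                    count += 1
    return count
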