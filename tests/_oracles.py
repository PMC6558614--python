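"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms used in the implementation:
centralities come from hand-written BFS distances and the pair-counting
betweenness formula (not Brandes accumulation), and hypergeometric tails
come from exhaustive enumeration of draws.
"""

from itertools import combinations
from math import comb


def bfs_layers(adj, source, nodes):
    """Hand-rolled BFS; returns dist dict (unreachable nodes absent)."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_centralities(graph):
    """degree, normalized betweenness, Wasserman-Faust closeness for every
    node of an undirected networkx-style graph, via all-pairs shortest-path
    counting."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    adj = {u: sorted(graph.neighbors(u)) for u in nodes}

    dist = {}
    sigma = {}
    for s in nodes:
        d = bfs_layers(adj, s, nodes)
        dist[s] = d
        # count shortest paths by dynamic programming over distance layers
        cnt = {s: 1}
        for v in sorted(d, key=d.get):
            if v == s:
                continue
            cnt[v] = sum(cnt[u] for u in adj[v] if u in d and d[u] == d[v] - 1)
        sigma[s] = cnt

    degree = {u: len(adj[u]) for u in nodes}
    betweenness = {}
    scale = (n - 1) * (n - 2) / 2
    for v in nodes:
        acc = 0.0
        for s, t in combinations(nodes, 2):
            if v in (s, t) or t not in dist[s]:
                continue
            if v in dist[s] and v in dist[t] and dist[s][v] + dist[t][v] == dist[s][t]:
                acc += sigma[s][v] * sigma[t][v] / sigma[s][t]
        betweenness[v] = acc / scale if scale > 0 else 0.0

    closeness = {}
    for u in nodes:
        reach = len(dist[u])  # includes u itself
        total = sum(dist[u].values())
        if reach > 1 and total > 0:
            closeness[u] = ((reach - 1) / total) * ((reach - 1) / (n - 1))
        else:
            closeness[u] = 0.0
    return degree, betweenness, closeness


def brute_hypergeom_tail(k, K, n, N):
    """P(X >= k) by enumerating every n-subset of an N-gene universe with
    K marked genes.  Feasible for N <= 12."""
    marked = set(range(K))
    total = comb(N, n)
    hits = sum(
        1 for draw in combinations(range(N), n) if len(marked & set(draw)) >= k
    )
    return hits / total


def brute_hypergeom_all_tails(K, n, N):
    """P(X >= k) for every k in 0..min(n, K), by enumerating all C(N, n)
    draws from an N-gene universe with the first K genes marked."""
    kmax = min(n, K)
    counts = [0] * (kmax + 1)
    for draw in combinations(range(N), n):
        j = sum(1 for g in draw if g < K)
        counts[j] += 1
    total = comb(N, n)
    tails = []
    suffix = [0] * (kmax + 2)
    for j in range(kmax, -1, -1):
        suffix[j] = suffix[j + 1] + counts[j]
    for k in range(kmax + 1):
        tails.append(suffix[k] / total)
    return tails


def brute_bh(pvals):
    """Benjamini-Hochberg step-up by the textbook definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q
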