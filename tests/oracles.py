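"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: betweenness by explicit
all-shortest-paths enumeration, rank-product nulls by exhaustive
permutation, hypergeometric tails by enumeration of draws.
"""

import itertools
import math
from collections import deque

import numpy as np


def brute_betweenness(graph):
    """Pair-fraction betweenness by explicit shortest-path enumeration.

    For every unordered pair s != t, enumerate ALL shortest s-t paths with
    a BFS-layered DFS and credit each internal node 1/(number of shortest
    paths). Endpoints excluded; unreachable pairs contribute nothing.
    """
    nodes = list(graph.nodes)
    btw = dict.fromkeys(nodes, 0.0)
    for i, s in enumerate(nodes):
        # BFS distances from s
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for t in nodes[i + 1:]:
            if t not in dist:
                continue
            # enumerate all shortest paths s -> t by walking down the DAG
            paths = []
            stack = [(t, [t])]
            while stack:
                u, path = stack.pop()
                if u == s:
                    paths.append(path)
                    continue
                for v in graph.neighbors(u):
                    if dist.get(v, -2) == dist[u] - 1:
                        stack.append((v, path + [v]))
            for path in paths:
                for node in path[1:-1]:
                    btw[node] += 1.0 / len(paths)
    return btw


def exhaustive_rp_pvalues(ranks):
    """Exact pooled-null rank-product p-values for a tiny rank matrix.

    Enumerates every combination of within-sample label permutations,
    pools all null rank products, and returns the exact null CDF value
    P(null rp <= observed rp) per gene.
    """
    ranks = np.asarray(ranks, float)
    n, k = ranks.shape
    obs = np.exp(np.log(ranks).mean(axis=1))
    null = []
    for perms in itertools.product(itertools.permutations(range(n)), repeat=k):
        permuted = np.column_stack([ranks[list(perms[j]), j] for j in range(k)])
        null.extend(np.exp(np.log(permuted).mean(axis=1)))
    null = np.sort(null)
    return np.searchsorted(null, obs, side="right") / len(null)


def hypergeom_upper_tail(universe_size, set_size, query_size, overlap):
    """P(X >= overlap) by direct summation of hypergeometric masses."""
    total = math.comb(universe_size, query_size)
    prob = 0.0
    for k in range(overlap, min(set_size, query_size) + 1):
        if query_size - k > universe_size - set_size:
            continue
        prob += math.comb(set_size, k) * math.comb(universe_size - set_size, query_size - k) / total
    return prob


def hypergeom_by_enumeration(universe_size, set_size, query_size, overlap):
    """P(X >= overlap) by enumerating every possible draw (population <= 15)."""
    population = list(range(universe_size))
    successes = set(population[:set_size])
    hits = 0
    total = 0
    for draw in itertools.combinations(population, query_size):
        total += 1
        if len(successes.intersection(draw)) >= overlap:
            hits += 1
    return hits / total
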