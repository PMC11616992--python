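"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (scalar math, exhaustive enumeration)
and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def pair_geometry_scalar(p_i, v_i, p_j, v_j):
    """Scalar recomputation of the four pair descriptors from raw vectors."""
    sep = [p_j[k] - p_i[k] for k in range(3)]
    d = math.sqrt(sum(s * s for s in sep))
    e = [s / d for s in sep]

    def ang(v, axis):
        dot = sum(v[k] * axis[k] for k in range(3))
        dot = max(-1.0, min(1.0, dot))
        return math.degrees(math.acos(dot))

    alpha_i = ang(v_i, e)
    alpha_j = ang(v_j, [-c for c in e])
    # torsion: signed angle between the transverse components about e
    def perp(v):
        dot = sum(v[k] * e[k] for k in range(3))
        return [v[k] - dot * e[k] for k in range(3)]

    pi_, pj_ = perp(v_i), perp(v_j)
    cross_e_pi = [
        e[1] * pi_[2] - e[2] * pi_[1],
        e[2] * pi_[0] - e[0] * pi_[2],
        e[0] * pi_[1] - e[1] * pi_[0],
    ]
    x = sum(pi_[k] * pj_[k] for k in range(3))
    y = sum(cross_e_pi[k] * pj_[k] for k in range(3))
    tau = math.degrees(math.atan2(y, x))
    if tau <= -180.0 + 1e-12:
        tau = 180.0
    return d, alpha_i, alpha_j, tau


def all_shortest_paths(adj: dict, lengths: dict, s, t, tol=1e-9):
    """All minimum-cost simple paths s→t by exhaustive DFS (tiny graphs)."""
    best_cost = math.inf
    best: list[list] = []
    stack = [(s, [s], 0.0)]
    while stack:
        node, path, cost = stack.pop()
        if cost > best_cost + tol:
            continue
        if node == t:
            if cost < best_cost - tol:
                best_cost, best = cost, [path]
            elif abs(cost - best_cost) <= tol:
                best.append(path)
            continue
        for nbr in adj[node]:
            if nbr not in path:
                stack.append((nbr, path + [nbr], cost + lengths[(node, nbr)]))
    return best_cost, best


def brute_force_betweenness(graph, length_of=lambda w: 1.0 / w):
    """Unnormalized betweenness with fractional tie credit, by enumeration.

    ``graph`` is a networkx Graph with 'weight' edge attributes.
    """
    nodes = sorted(graph.nodes())
    adj = {v: sorted(graph.neighbors(v)) for v in nodes}
    lengths = {}
    for u, v, data in graph.edges(data=True):
        l = length_of(data.get("weight", 1.0))
        lengths[(u, v)] = l
        lengths[(v, u)] = l
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        cost, paths = all_shortest_paths(adj, lengths, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return np.array([bc[v] for v in nodes])


def brute_force_degree(graph):
    """Weighted degree as explicit row sums of the weight matrix."""
    nodes = sorted(graph.nodes())
    n = len(nodes)
    w = np.zeros((n, n))
    index = {v: i for i, v in enumerate(nodes)}
    for u, v, data in graph.edges(data=True):
        w[index[u], index[v]] = data.get("weight", 1.0)
        w[index[v], index[u]] = data.get("weight", 1.0)
    return w.sum(axis=1)
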