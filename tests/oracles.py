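"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: centralities come from
explicit enumeration of all shortest paths (via ``nx.all_shortest_paths``),
and hypergeometric tails from exact integer binomial-coefficient sums.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx


def brute_force_metrics(g: nx.Graph) -> dict[str, dict]:
    """Betweenness/stress/closeness/eccentricity/radiality by enumeration."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}

    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            sigma = len(paths)
            interior: dict = {}
            for path in paths:
                for v in path[1:-1]:
                    interior[v] = interior.get(v, 0) + 1
            for v, count in interior.items():
                betweenness[v] += count / sigma
                stress[v] += count

    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    betweenness = {v: b * scale for v, b in betweenness.items()}

    ecc = {v: 0 for v in nodes}
    closeness = {v: 0.0 for v in nodes}
    mean_dist = {}
    for v in nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        others = {u: d for u, d in dist.items() if u != v}
        if others:
            ecc[v] = max(others.values())
            mean_dist[v] = sum(others.values()) / len(others)
            closeness[v] = 1.0 / mean_dist[v]

    radiality = {v: 1.0 for v in nodes}
    for comp in nx.connected_components(g):
        diam = max(ecc[v] for v in comp)
        if diam > 0:
            for v in comp:
                radiality[v] = (diam + 1 - mean_dist[v]) / diam

    return {
        "betweenness": betweenness,
        "stress": stress,
        "eccentricity": ecc,
        "closeness": closeness,
        "radiality": radiality,
    }


def exact_tails(k: int, K: int, n: int, N: int) -> tuple[Fraction, Fraction]:
    """Exact (P(X >= k), P(X <= k)) as rationals, X ~ Hypergeom(N, K, n)."""
    denom = comb(N, n)
    lo, hi = max(0, n + K - N), min(K, n)
    upper = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1))
    lower = sum(comb(K, i) * comb(N - K, n - i) for i in range(lo, k + 1))
    return Fraction(upper, denom), Fraction(lower, denom)


def exact_two_sided(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact doubled-smaller-tail two-sided p, capped at 1."""
    p_e, p_d = exact_tails(k, K, n, N)
    return min(Fraction(1), 2 * min(p_e, p_d))
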