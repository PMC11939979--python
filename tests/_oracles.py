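"""Independent brute-force oracles used to check the implementation.

These deliberately take the slow, literal route: shortest paths are
enumerated explicitly, permutation nulls are enumerated exhaustively,
and hypergeometric tails are summed from binomial coefficients.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def brute_force_centralities(graph: nx.Graph) -> dict[str, dict]:
    """Distance-based centralities by explicit shortest-path enumeration."""
    betweenness = {v: 0.0 for v in graph}
    stress = {v: 0.0 for v in graph}
    closeness: dict = {}
    eccentricity: dict = {}
    radiality: dict = {}
    centroid: dict = {}
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        dist = {v: nx.single_source_shortest_path_length(sub, v) for v in comp}
        diam = max(dist[u][v] for u in comp for v in comp)
        for s, t in itertools.combinations(comp, 2):
            paths = list(nx.all_shortest_paths(sub, s, t))
            for v in comp:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                stress[v] += through
                betweenness[v] += through / len(paths)
        for v in comp:
            total = sum(dist[v][w] for w in comp)
            closeness[v] = 1.0 / total
            eccentricity[v] = 1.0 / max(dist[v][w] for w in comp if w != v)
            radiality[v] = sum(diam + 1 - dist[v][w] for w in comp if w != v) / (len(comp) - 1)
            best = None
            for w in comp:
                if w == v:
                    continue
                gamma_vw = sum(1 for u in comp if dist[u][v] < dist[u][w])
                gamma_wv = sum(1 for u in comp if dist[u][w] < dist[u][v])
                f = gamma_vw - gamma_wv
                best = f if best is None else min(best, f)
            centroid[v] = best
    return {
        "betweenness": betweenness,
        "stress": stress,
        "closeness": closeness,
        "eccentricity": eccentricity,
        "radiality": radiality,
        "centroid": centroid,
    }


def exhaustive_presence_p(presence: list[int], n_a: int) -> float:
    """Exact two-sided permutation p for a 0/1 vector split into groups.

    Enumerates every assignment of ``n_a`` of the subjects to group A and
    doubles the smaller tail of the resulting null distribution of the
    group-A presence count.
    """
    n = len(presence)
    observed = sum(presence[:n_a])
    counts: dict[int, int] = {}
    for combo in itertools.combinations(range(n), n_a):
        a = sum(presence[i] for i in combo)
        counts[a] = counts.get(a, 0) + 1
    total = math.comb(n, n_a)
    lower = sum(c for a, c in counts.items() if a <= observed) / total
    upper = sum(c for a, c in counts.items() if a >= observed) / total
    return min(1.0, 2.0 * min(lower, upper))


def exact_hypergeom_upper(overlap: int, universe: int, term: int, selection: int) -> float:
    """P(X >= overlap) summed from binomial coefficients."""
    denom = math.comb(universe, selection)
    hi = min(term, selection)
    return sum(
        math.comb(term, j) * math.comb(universe - term, selection - j) / denom
        for j in range(overlap, hi + 1)
    )


def bh_stepup(p_values: np.ndarray) -> np.ndarray:
    """Literal Benjamini–Hochberg step-up adjustment."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
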