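"""PPI network construction, centrality suite, hubs/bottlenecks, null models.

Networks are built from a scored undirected interaction table (per-edge
"databases" and "experiments" channel scores in [0, 1]) restricted either
to selected differentially abundant proteins or to the proteins a group
reliably detects.  The centrality suite follows the conventions of the
Centiscape Cytoscape plugin:

* betweenness and stress are unnormalized shortest-path pair counts
  (each unordered pair counted once);
* closeness is the reciprocal of the total distance to all reachable
  nodes, eccentricity the reciprocal of the maximum distance;
* radiality of v is ``sum_w (diam + 1 - d(v, w)) / (n - 1)`` within the
  component;
* centroid value of v is ``min_w (gamma_v(w) - gamma_w(v))`` where
  ``gamma_v(w)`` counts nodes strictly closer to v than to w;
* bridging is betweenness times the bridging coefficient
  ``(1/deg(v)) / sum_{i in N(v)} 1/deg(i)``.

Hubs are nodes whose betweenness and centroid both exceed the network
averages; bottlenecks exceed the averages of betweenness and bridging.
Observed topology is validated against degree-preserving random models
built by double-edge-swap rewiring.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

from .io import GroupDesign, PSMMatrix

NODE_CENTRALITIES = [
    "degree",
    "betweenness",
    "centroid",
    "stress",
    "eigenvector",
    "bridging",
    "eccentricity",
    "closeness",
    "radiality",
]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _filtered_edges(
    interactions: pd.DataFrame,
    nodes: set[str],
    db_min: float,
    exp_min: float,
) -> dict[tuple[str, str], tuple[float, float]]:
    edges: dict[tuple[str, str], tuple[float, float]] = {}
    for p1, p2, db, ex in interactions[
        ["protein1", "protein2", "databases_score", "experiments_score"]
    ].itertuples(index=False):
        if p1 == p2 or p1 not in nodes or p2 not in nodes:
            continue
        key = (p1, p2) if p1 <= p2 else (p2, p1)
        old = edges.get(key, (0.0, 0.0))
        edges[key] = (max(old[0], float(db)), max(old[1], float(ex)))
    return {
        k: v for k, v in edges.items() if v[0] >= db_min or v[1] >= exp_min
    }


def build_dap_network(
    daps: Iterable[str],
    interactions: pd.DataFrame,
    db_min: float = 0.3,
    exp_min: float = 0.15,
) -> nx.Graph:
    """Undirected simple graph over the selected proteins.

    An edge is retained iff its "databases" score is >= ``db_min`` OR its
    "experiments" score is >= ``exp_min`` (inclusive thresholds);
    duplicate pairs are merged keeping the maximum per-channel score and
    self-loops are dropped.  Selected proteins without any retained
    interaction remain as isolated nodes.
    """
    if not (0 <= db_min <= 1 and 0 <= exp_min <= 1):
        raise ValueError("score thresholds must lie in [0, 1]")
    nodes = set(daps)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(nodes))
    for (u, v), (db, ex) in _filtered_edges(interactions, nodes, db_min, exp_min).items():
        graph.add_edge(u, v, databases_score=db, experiments_score=ex)
    return graph


def group_membership_threshold(n_subjects: int) -> int:
    """Minimum number of detections for a protein to enter a group network."""
    return -(-n_subjects // 2)  # ceil(n/2): 3-of-5, 2-of-4, 4-of-7


def build_group_network(
    matrix: PSMMatrix,
    design: GroupDesign,
    group: str,
    interactions: pd.DataFrame,
    db_min: float = 0.3,
    exp_min: float = 0.15,
    restrict_to: Iterable[str] | None = None,
) -> nx.Graph:
    """Network over the proteins a group detects in at least half its subjects.

    A protein enters the node set when its PSM is nonzero in at least
    ``ceil(n/2)`` of the group's ``n`` subjects.  ``restrict_to``
    optionally intersects that set with an external selection (e.g. the
    DAP list).  Edges are filtered as in :func:`build_dap_network`.
    """
    subjects = design.subjects_in(group)
    threshold = group_membership_threshold(len(subjects))
    detected = (matrix.values[subjects] > 0).sum(axis=1)
    members = set(matrix.values.index[detected >= threshold])
    if restrict_to is not None:
        members &= set(restrict_to)
    return build_dap_network(members, interactions, db_min=db_min, exp_min=exp_min)


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def _bfs_dist_sigma(adj: list[list[int]], source: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from one source (unit weights)."""
    n = len(adj)
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=float)
    dist[source] = 0
    sigma[source] = 1.0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if dist[w] < 0:
                dist[w] = dist[u] + 1
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


@dataclass
class CentralityTable:
    """Node, edge and network-level topological indices.

    ``nodes`` has one row per node with the nine node centralities
    (distance-based values are NaN for isolated nodes); ``edges`` carries
    the edge betweenness; ``network`` holds diameter, average distance
    and average degree of the largest connected component.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    network: dict[str, float]


def compute_centralities(graph: nx.Graph) -> CentralityTable:
    """Compute the full centrality suite of an undirected simple graph.

    Distance-based indices are computed within each connected component
    of two or more nodes; eigenvector centrality is the principal
    adjacency eigenvector per component (unit norm, nonnegative).
    Betweenness, stress and edge betweenness count each unordered
    source–target pair once.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = pd.DataFrame(
        np.nan, index=pd.Index(sorted(graph.nodes()), name="node"), columns=NODE_CENTRALITIES
    )
    nodes["degree"] = [graph.degree(v) for v in nodes.index]

    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=len, reverse=True)
    for comp in components:
        if len(comp) < 2:
            continue
        _component_centralities(graph, comp, nodes)

    # bridging = betweenness x bridging coefficient
    bridging = []
    for v in nodes.index:
        deg_v = graph.degree(v)
        if deg_v == 0:
            bridging.append(np.nan)
            continue
        denom = sum(1.0 / graph.degree(w) for w in graph.neighbors(v))
        coeff = (1.0 / deg_v) / denom
        bridging.append(nodes.loc[v, "betweenness"] * coeff)
    nodes["bridging"] = bridging

    eb = nx.edge_betweenness_centrality(graph, normalized=False)
    edges = pd.DataFrame(
        [(u, v, val) for (u, v), val in sorted(eb.items())],
        columns=["protein1", "protein2", "edge_betweenness"],
    )

    largest = components[0] if components else []
    network: dict[str, float] = {}
    if len(largest) >= 2:
        sub = graph.subgraph(largest)
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        dists = [
            lengths[u][v] for i, u in enumerate(largest) for v in largest[i + 1 :]
        ]
        network["diameter"] = float(max(dists))
        network["average_distance"] = float(np.mean(dists))
        network["average_degree"] = float(np.mean([sub.degree(v) for v in largest]))
    else:
        network = {"diameter": np.nan, "average_distance": np.nan, "average_degree": 0.0}
    return CentralityTable(nodes=nodes, edges=edges, network=network)


def _component_centralities(graph: nx.Graph, comp: list, nodes: pd.DataFrame) -> None:
    index = {v: i for i, v in enumerate(comp)}
    adj = [[index[w] for w in graph.neighbors(v) if w in index] for v in comp]
    n = len(comp)
    dist = np.zeros((n, n), dtype=np.int64)
    sigma = np.zeros((n, n), dtype=float)
    for i in range(n):
        dist[i], sigma[i] = _bfs_dist_sigma(adj, i)

    diam = int(dist.max())
    off = ~np.eye(n, dtype=bool)

    betweenness = np.zeros(n)
    stress = np.zeros(n)
    sigma_safe = np.where(sigma == 0, 1.0, sigma)
    for v in range(n):
        through = (dist[:, v][:, None] + dist[v, :][None, :]) == dist
        paths = sigma[:, v][:, None] * sigma[v, :][None, :]
        valid = through & off
        valid[v, :] = False
        valid[:, v] = False
        contrib = np.where(valid, paths, 0.0)
        stress[v] = contrib.sum() / 2.0
        betweenness[v] = np.where(valid, contrib / sigma_safe, 0.0).sum() / 2.0

    closeness = 1.0 / dist.sum(axis=1)
    eccentricity = 1.0 / dist.max(axis=1)
    radiality = ((diam + 1.0) * (n - 1) - dist.sum(axis=1)) / (n - 1)

    # gamma[v, w] = number of nodes strictly closer to v than to w
    gamma = np.zeros((n, n), dtype=np.int64)
    for v in range(n):
        gamma[v] = (dist[:, v][:, None] < dist).sum(axis=0)
    diff = gamma - gamma.T
    np.fill_diagonal(diff, np.iinfo(np.int64).max)
    centroid = diff.min(axis=1).astype(float)

    adjacency = np.zeros((n, n))
    for i, neigh in enumerate(adj):
        adjacency[i, neigh] = 1.0
    eigvals, eigvecs = np.linalg.eigh(adjacency)
    principal = eigvecs[:, -1]
    if principal.sum() < 0:
        principal = -principal
    principal = np.abs(principal)
    principal /= np.linalg.norm(principal)

    for v, name in enumerate(comp):
        nodes.loc[name, "betweenness"] = betweenness[v]
        nodes.loc[name, "stress"] = stress[v]
        nodes.loc[name, "closeness"] = closeness[v]
        nodes.loc[name, "eccentricity"] = eccentricity[v]
        nodes.loc[name, "radiality"] = radiality[v]
        nodes.loc[name, "centroid"] = centroid[v]
        nodes.loc[name, "eigenvector"] = principal[v]


# ---------------------------------------------------------------------------
# hubs and bottlenecks
# ---------------------------------------------------------------------------

@dataclass
class HubSelection:
    """Above-average centrality flags with the network means used."""

    flags: pd.DataFrame  # is_hub, is_bottleneck per node
    means: dict[str, float]


def select_hubs_bottlenecks(centralities: CentralityTable) -> HubSelection:
    """Flag hubs (betweenness & centroid) and bottlenecks (betweenness & bridging).

    Means are taken over all non-singleton nodes of the network and the
    comparison is strict, so a perfectly regular network (e.g. a
    complete graph) yields no hubs or bottlenecks.
    """
    nodes = centralities.nodes
    informative = nodes[nodes["betweenness"].notna()]
    means = {
        "betweenness": float(informative["betweenness"].mean()),
        "centroid": float(informative["centroid"].mean()),
        "bridging": float(informative["bridging"].mean()),
    }
    above_b = nodes["betweenness"] > means["betweenness"]
    flags = pd.DataFrame(
        {
            "is_hub": (above_b & (nodes["centroid"] > means["centroid"])).fillna(False),
            "is_bottleneck": (above_b & (nodes["bridging"] > means["bridging"])).fillna(False),
        },
        index=nodes.index,
    )
    return HubSelection(flags=flags, means=means)


# ---------------------------------------------------------------------------
# degree-preserving random models
# ---------------------------------------------------------------------------

def rewire_replicas(
    graph: nx.Graph,
    n: int,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> Iterator[tuple[nx.Graph, bool]]:
    """Yield ``n`` degree-preserving rewired replicas of ``graph``.

    Each replica applies ``swaps_per_edge * |E|`` successful double-edge
    swaps, which keep every node degree fixed and the graph simple.  On
    graphs where no valid swap exists (the attempt budget is exhausted)
    the replica equals the input and is flagged (second tuple element
    True).  Deterministic given ``seed``.
    """
    m = graph.number_of_edges()
    if m < 2:
        raise ValueError("randomization needs a network with at least 2 edges")
    seeds = np.random.SeedSequence(seed).generate_state(n)
    for replica_seed in seeds:
        replica = nx.Graph(graph)
        flagged = False
        try:
            nx.double_edge_swap(
                replica,
                nswap=swaps_per_edge * m,
                max_tries=max(100 * m, 100 * swaps_per_edge * m // 10),
                seed=int(replica_seed),
            )
        except nx.NetworkXException:
            replica = nx.Graph(graph)
            flagged = True
        yield replica, flagged


@dataclass
class RandomEnsembleSummary:
    """Real-vs-random comparison of mean betweenness."""

    n_replicates: int
    replicate_means: list[float]
    real_mean: float
    quantile: float
    seed: int
    n_flagged: int = 0


def randomize_ensemble(
    graph: nx.Graph,
    n: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> tuple[list[float], int]:
    """Mean node betweenness of ``n`` degree-preserving random models.

    Returns the per-replica means (unnormalized betweenness averaged
    over all nodes) and the number of replicas flagged as un-rewirable.
    """
    means: list[float] = []
    n_flagged = 0
    for replica, flagged in rewire_replicas(graph, n, seed=seed, swaps_per_edge=swaps_per_edge):
        bc = nx.betweenness_centrality(replica, normalized=False)
        means.append(float(np.mean(list(bc.values()))))
        n_flagged += flagged
    return means, n_flagged


def compare_real_vs_random(
    real: CentralityTable,
    replicate_means: list[float],
    seed: int = 0,
    n_flagged: int = 0,
    plot_path: str | Path | None = None,
) -> RandomEnsembleSummary:
    """Locate the real network's mean betweenness within the null ensemble.

    The empirical quantile is the fraction of replicas whose mean
    betweenness is <= the real value.  When ``plot_path`` is given a
    violin plot of the null distribution with the real value marked is
    written there.
    """
    if not replicate_means:
        raise ValueError("empty ensemble")
    real_mean = float(real.nodes["betweenness"].fillna(0.0).mean())
    quantile = float(np.mean([m <= real_mean for m in replicate_means]))
    summary = RandomEnsembleSummary(
        n_replicates=len(replicate_means),
        replicate_means=list(replicate_means),
        real_mean=real_mean,
        quantile=quantile,
        seed=seed,
        n_flagged=n_flagged,
    )
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.violinplot([replicate_means], showmedians=True)
        ax.axhline(real_mean, color="crimson", label="real network")
        ax.set_ylabel("mean betweenness")
        ax.set_xticks([])
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return summary


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, path: str | Path) -> None:
    """Edge-list TSV with the retained per-channel scores."""
    rows = [
        (u, v, d.get("databases_score", np.nan), d.get("experiments_score", np.nan))
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["protein1", "protein2", "databases_score", "experiments_score"]
    ).to_csv(path, sep="\t", index=False)
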