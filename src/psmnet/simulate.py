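"""Synthetic cohorts, interactomes, and annotation sets.

The generator emulates the data a urine spectral-count proteomics study
produces at the protein level: a protein-by-subject PSM count matrix over
several clinical groups, a scored undirected interactome, and functional
annotation sets.  Ground truth (planted group-exclusive proteins, planted
fold changes, planted enriched terms, top-degree interactome nodes) is
recorded so downstream selection stages can be tested for recovery.

Count model
-----------
Each protein draws a log-normal baseline mean.  A cell where the protein
is present holds ``1 + NB(mean - 1, dispersion)`` counts, i.e. a shifted
negative binomial whose expectation equals the target mean; absence
(zero) arises only from detection dropout or planted exclusivity.  This
makes presence/absence structure — what the identification-frequency
filters operate on — an explicit, independently controlled layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import GroupDesign, PSMMatrix


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror a small three-arm urine proteomics cohort: five
    healthy donors (HD), four low-risk (LRPCa) and seven high-risk
    (HRPCa) patients, ~2490 identified proteins.
    """

    group_sizes: tuple[int, ...] = (5, 4, 7)
    group_labels: tuple[str, ...] = ("HD", "LRPCa", "HRPCa")
    n_proteins: int = 2490
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    dispersion: float = 10.0
    detection_prob: float = 0.8
    n_exclusive_per_group: int = 20
    n_foldchange_daps: int = 30
    fold_change: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != len(self.group_labels):
            raise ValueError("group_sizes and group_labels length mismatch")
        if len(self.group_sizes) < 2:
            raise ValueError("need at least 2 groups")
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("every group needs at least 2 subjects")
        if not (0.0 <= self.detection_prob <= 1.0):
            raise ValueError("detection_prob must be in [0, 1]")
        if self.fold_change <= 1.0:
            raise ValueError("fold_change must be > 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.n_exclusive_per_group < 0 or self.n_foldchange_daps < 0:
            raise ValueError("planting counts must be non-negative")
        planted = (
            self.n_exclusive_per_group * len(self.group_sizes)
            + self.n_foldchange_daps
        )
        if planted > self.n_proteins:
            raise ValueError(
                f"{planted} planted proteins exceed n_proteins={self.n_proteins}"
            )


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    exclusive_proteins: dict[str, set[str]] = field(default_factory=dict)
    foldchange_proteins: dict[str, tuple[str, str]] = field(default_factory=dict)
    enriched_terms: set[str] = field(default_factory=set)
    hub_like_nodes: set[str] = field(default_factory=set)

    def all_exclusive(self) -> set[str]:
        out: set[str] = set()
        for s in self.exclusive_proteins.values():
            out |= s
        return out


def _shifted_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Counts >= 1 with expectation ``mean`` (requires mean > 1)."""
    m = np.maximum(np.asarray(mean, dtype=float) - 1.0, 1e-9)
    p = dispersion / (dispersion + m)
    return 1 + rng.negative_binomial(dispersion, p)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[PSMMatrix, GroupDesign, SyntheticTruth]:
    """Draw a protein-by-subject PSM count matrix with planted signal.

    Returns the raw count matrix, the subject-to-group design, and the
    ground truth.  Exclusive proteins have exactly zero counts outside
    their group; fold-change proteins have their mean multiplied (``up``)
    or divided (``down``) by ``config.fold_change`` in one affected
    group; dropout then zeroes each cell independently with probability
    ``1 - detection_prob``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    labels = config.group_labels
    protein_ids = [f"P{i:05d}" for i in range(config.n_proteins)]
    subject_ids: list[str] = []
    subject_groups: list[str] = []
    for label, n in zip(labels, config.group_sizes):
        for k in range(1, n + 1):
            subject_ids.append(f"{label}_{k}")
            subject_groups.append(label)
    group_arr = np.asarray(subject_groups)

    # per-protein baseline means, >= 1.5 so the shifted-NB model is valid
    baseline = np.maximum(
        np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_proteins)),
        1.5,
    )

    order = rng.permutation(config.n_proteins)
    cursor = 0
    truth = SyntheticTruth()
    for label in labels:
        picked = order[cursor : cursor + config.n_exclusive_per_group]
        truth.exclusive_proteins[label] = {protein_ids[i] for i in picked}
        cursor += config.n_exclusive_per_group
    fc_idx = order[cursor : cursor + config.n_foldchange_daps]
    directions = rng.choice(["up", "down"], size=config.n_foldchange_daps)
    affected = rng.choice(len(labels), size=config.n_foldchange_daps)
    for i, d, a in zip(fc_idx, directions, affected):
        truth.foldchange_proteins[protein_ids[i]] = (labels[a], str(d))
        if d == "down":
            # keep the reduced mean above the shifted-NB floor
            baseline[i] = max(baseline[i], 1.5 * config.fold_change)

    mean_matrix = np.tile(baseline[:, None], (1, len(subject_ids)))
    for i, d, a in zip(fc_idx, directions, affected):
        cols = group_arr == labels[a]
        if d == "up":
            mean_matrix[i, cols] *= config.fold_change
        else:
            mean_matrix[i, cols] /= config.fold_change

    counts = _shifted_nb(rng, mean_matrix, config.dispersion)

    for label in labels:
        for pid in truth.exclusive_proteins[label]:
            i = protein_ids.index(pid)
            counts[i, group_arr != label] = 0

    if config.detection_prob < 1.0:
        dropout = rng.random(counts.shape) >= config.detection_prob
        counts = np.where(dropout, 0, counts)

    frame = pd.DataFrame(counts, index=protein_ids, columns=subject_ids)
    design = GroupDesign(dict(zip(subject_ids, subject_groups)), groups=labels)
    return PSMMatrix(frame, normalized=False), design, truth


def generate_interactome(
    protein_ids: list[str],
    n_nodes: int = 400,
    attach_edges: int = 3,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
    n_hub_like: int = 10,
) -> pd.DataFrame:
    """Scale-free scored interactome over a sample of the cohort's proteins.

    Preferential attachment (Barabási–Albert, ``attach_edges`` edges per
    new node) yields the heavy-tailed degree distribution real
    interactomes show.  Each edge carries independent uniform [0, 1]
    "databases" and "experiments" channel scores.  When ``truth`` is
    given, the ``n_hub_like`` highest-degree node IDs are recorded in
    ``truth.hub_like_nodes``.
    """
    if attach_edges < 1 or n_nodes <= attach_edges:
        raise ValueError("need n_nodes > attach_edges >= 1")
    if n_nodes > len(protein_ids):
        raise ValueError(
            f"n_nodes={n_nodes} exceeds the {len(protein_ids)} available protein IDs"
        )
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(protein_ids, size=n_nodes, replace=False))
    graph = nx.barabasi_albert_graph(n_nodes, attach_edges, seed=int(rng.integers(2**31)))
    rows = []
    for u, v in sorted(graph.edges()):
        rows.append(
            (chosen[u], chosen[v], float(rng.random()), float(rng.random()))
        )
    table = pd.DataFrame(
        rows, columns=["protein1", "protein2", "databases_score", "experiments_score"]
    )
    if truth is not None:
        degree = sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))
        truth.hub_like_nodes = {chosen[i] for i, _ in degree[:n_hub_like]}
    return table


def generate_annotations(
    universe: list[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 40),
    planted_terms: int = 3,
    seed: int = 0,
    dap_proteins: set[str] | None = None,
    truth: SyntheticTruth | None = None,
) -> "AnnotationSets":
    """Random annotation sets with planted enriched terms.

    Background terms are uniform random draws from the universe; planted
    terms are drawn from ``dap_proteins`` (falling back to the universe
    when that pool is too small), so a selection of those proteins is
    recoverably enriched for them.  Planted term IDs are recorded in
    ``truth.enriched_terms`` when given.
    """
    from .enrichment import AnnotationSets  # local import to avoid a cycle

    if not universe:
        raise ValueError("empty protein universe")
    lo, hi = term_size_range
    if lo < 1 or hi < lo or hi > len(universe):
        raise ValueError("term sizes must satisfy 1 <= lo <= hi <= |universe|")
    if planted_terms > n_terms:
        raise ValueError("planted_terms cannot exceed n_terms")
    rng = np.random.default_rng(seed)
    pool = sorted(dap_proteins) if dap_proteins else []
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        if t < planted_terms and len(pool) >= size:
            members = rng.choice(pool, size=size, replace=False)
            desc = "planted enriched term (synthetic)"
        else:
            members = rng.choice(universe, size=size, replace=False)
            desc = "random background term (synthetic)"
        tid = f"T{t:04d}"
        terms[tid] = (desc, frozenset(str(m) for m in members))
        if t < planted_terms and truth is not None:
            truth.enriched_terms.add(tid)
    return AnnotationSets(terms=terms, universe=frozenset(universe))
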