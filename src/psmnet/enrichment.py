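"""Functional-module assignment and differential enrichment.

Annotation sets map functional terms (GO terms, pathways, ...) to protein
sets over an explicit universe.  Module assignment of a protein selection
uses the upper-tail hypergeometric test with Benjamini–Hochberg FDR
control; differential enrichment across subject groups applies the same
one-way F-ratio rule as the protein-level selection to a term-by-subject
enrichment-score matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from ._stats import apply_f_rule, one_way_f
from .io import GroupDesign, PSMMatrix


@dataclass(frozen=True)
class AnnotationSets:
    """Term -> (description, member proteins) over an explicit universe."""

    terms: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty protein universe")
        for tid, (_, members) in self.terms.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"term {tid!r} has members outside the universe: {sorted(stray)[:5]}"
                )

    @classmethod
    def from_gmt(cls, path: str | Path, universe: set[str] | None = None) -> "AnnotationSets":
        """Read GMT (term, description, tab-separated members per line).

        When no universe is given, the union of all members is used.
        """
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                terms[fields[0]] = (fields[1], frozenset(fields[2:]))
        if universe is None:
            universe = set().union(*(m for _, m in terms.values())) if terms else set()
        return cls(terms=terms, universe=frozenset(universe))

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for tid, (desc, members) in self.terms.items():
                handle.write("\t".join([tid, desc, *sorted(members)]) + "\n")


def hypergeometric_enrichment(
    selection: set[str],
    annotations: AnnotationSets,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment of a protein selection.

    For each term the p-value is ``P(X >= overlap)`` drawing
    ``|selection|`` proteins without replacement from the universe with
    the term members as successes.  Benjamini–Hochberg adjustment is
    applied across all tested terms; a term is called enriched iff its
    adjusted p is <= ``fdr_threshold``.  Results are sorted by raw p.
    """
    stray = selection - annotations.universe
    if stray:
        raise ValueError(f"selection proteins outside the universe: {sorted(stray)[:10]}")
    m_universe = len(annotations.universe)
    n_selection = len(selection)
    rows = []
    for tid, (desc, members) in annotations.terms.items():
        overlap = len(selection & members)
        p = float(_sps.hypergeom.sf(overlap - 1, m_universe, len(members), n_selection))
        rows.append((tid, desc, overlap, len(members), p))
    frame = pd.DataFrame(
        rows, columns=["term_id", "description", "overlap", "term_size", "p_value"]
    ).set_index("term_id")
    frame["selection_size"] = n_selection
    frame["universe_size"] = m_universe
    if len(frame):
        _, p_adj, _, _ = multipletests(frame["p_value"].to_numpy(), method="fdr_bh")
        frame["p_adjusted"] = np.minimum(1.0, p_adj)
        frame["enriched"] = frame["p_adjusted"] <= fdr_threshold
        frame = frame.sort_values("p_value", kind="stable")
    else:
        frame["p_adjusted"] = pd.Series(dtype=float)
        frame["enriched"] = pd.Series(dtype=bool)
    return frame


def enrichment_score_matrix(
    matrix: PSMMatrix,
    annotations: AnnotationSets,
) -> pd.DataFrame:
    """Term-by-subject enrichment scores (−log10 raw hypergeometric p).

    Each subject's detected-protein set (nonzero PSM, intersected with
    the universe) is tested against every term; the score scale is
    −log10 of the raw p-value.
    """
    cols = {}
    for subject in matrix.subject_ids:
        detected = set(matrix.values.index[matrix.values[subject] > 0])
        detected &= set(annotations.universe)
        res = hypergeometric_enrichment(detected, annotations, fdr_threshold=1.0)
        cols[subject] = -np.log10(np.maximum(res["p_value"], 1e-300))
    frame = pd.DataFrame(cols)
    frame.index.name = "term_id"
    return frame.sort_index()


def differential_enrichment(
    term_matrix: pd.DataFrame,
    design: GroupDesign,
    f_threshold: float = 3.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-way F-ratio selection of differentially enriched terms.

    Rows are terms, columns subjects; a term is selected iff its F ratio
    across groups is >= ``f_threshold`` and its p-value <= ``p_threshold``.
    """
    labels = design.labels_for(list(term_matrix.columns))
    f, p = one_way_f(term_matrix.to_numpy(dtype=float), labels)
    return pd.DataFrame(
        {
            "F_ratio": f,
            "p_value": p,
            "selected": apply_f_rule(f, p, f_threshold, p_threshold),
        },
        index=term_matrix.index,
    )
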