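"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are tab-separated with a header row:

* PSM matrix — first column ``protein_id``, remaining columns one per
  subject, non-negative counts (raw) or reals (normalized).
* group design — two columns ``subject`` and ``group``.
* interaction table — four columns ``protein1``, ``protein2``,
  ``databases_score``, ``experiments_score`` (undirected, scores in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class PSMMatrix:
    """Protein-by-subject spectral-count matrix.

    ``values`` is indexed by protein ID with one column per subject.
    ``normalized`` records whether total-signal normalization has been
    applied; raw matrices hold integer counts.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein IDs")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate subject IDs")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("PSM matrix has negative entries")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class GroupDesign:
    """Subject-to-group assignment with an ordered list of group labels."""

    assignment: Mapping[str, str]
    groups: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        seen = list(dict.fromkeys(self.assignment.values()))
        groups = tuple(self.groups) if self.groups else tuple(seen)
        object.__setattr__(self, "groups", groups)
        missing = set(seen) - set(groups)
        if missing:
            raise ValueError(f"groups {sorted(missing)} missing from group order")
        if len(groups) < 2:
            raise ValueError("a design needs at least 2 groups")
        for g in groups:
            if not self.subjects_in(g):
                raise ValueError(f"group {g!r} is empty")

    def subjects_in(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return [s for s, g in self.assignment.items() if g == group]

    def sizes(self) -> dict[str, int]:
        return {g: len(self.subjects_in(g)) for g in self.groups}

    def labels_for(self, subjects: list[str]) -> np.ndarray:
        try:
            return np.asarray([self.assignment[s] for s in subjects])
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"subject {exc.args[0]!r} not in design") from exc


def read_psm_matrix(path: str | Path, normalized: bool = False) -> PSMMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return PSMMatrix(frame, normalized=normalized)


def write_psm_matrix(matrix: PSMMatrix, path: str | Path) -> None:
    matrix.values.rename_axis("protein_id").to_csv(path, sep="\t")


def read_design(path: str | Path) -> GroupDesign:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["subject", "group"]:
        raise ValueError("design table must have columns 'subject' and 'group'")
    return GroupDesign(dict(zip(frame["subject"], frame["group"])))


def write_design(design: GroupDesign, path: str | Path) -> None:
    rows = [(s, g) for s, g in design.assignment.items()]
    pd.DataFrame(rows, columns=["subject", "group"]).to_csv(path, sep="\t", index=False)


INTERACTION_COLUMNS = ["protein1", "protein2", "databases_score", "experiments_score"]


def read_interactions(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"protein1": str, "protein2": str})
    missing = [c for c in INTERACTION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"interaction table missing columns {missing}")
    return frame[INTERACTION_COLUMNS]


def write_interactions(table: pd.DataFrame, path: str | Path) -> None:
    table[INTERACTION_COLUMNS].to_csv(path, sep="\t", index=False)
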