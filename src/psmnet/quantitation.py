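"""Label-free spectral-count comparison of subject groups.

Implements the differential-abundance layer of the pipeline: total-signal
normalization, per-group mean profiles and their Spearman correlation,
Venn-style overlap partitioning of detected proteins, identification
frequency (IF) based selection, one-way F-ratio selection (the univariate
F-to-enter criterion of stepwise discriminant analysis), the DAve
differential-abundance index, exact presence tests, and clustering/PCA
quality control of the selected proteins.

Definitions
-----------
IF
    Percentage of a group's subjects in which a protein is detected
    (nonzero PSM), printed as an integer percent.
DAve
    ``((mean_A - mean_B) / (mean_A + mean_B)) / 0.5``, bounded in
    [-2, 2]; a protein seen in only one of the two compared conditions
    is assigned the boundary value ±2 by convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.cluster import hierarchy as _sch
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from ._stats import apply_f_rule, one_way_f, round_half_away
from .io import GroupDesign, PSMMatrix


# ---------------------------------------------------------------------------
# normalization and group summaries
# ---------------------------------------------------------------------------

def normalize_total_signal(matrix: PSMMatrix) -> PSMMatrix:
    """Scale each subject column so all column totals equal the mean total.

    Zero entries remain exactly zero.  Raises if any subject has an
    all-zero column (its scale factor would be undefined).
    """
    values = matrix.values
    totals = values.sum(axis=0)
    zero_subjects = list(totals.index[totals == 0])
    if zero_subjects:
        raise ValueError(f"subjects with all-zero counts: {zero_subjects}")
    target = float(totals.mean())
    scaled = values * (target / totals)
    return PSMMatrix(scaled, normalized=True)


def group_mean_profiles(matrix: PSMMatrix, design: GroupDesign) -> pd.DataFrame:
    """Arithmetic mean PSM per protein within each group (proteins x groups)."""
    cols = {g: matrix.values[design.subjects_in(g)].mean(axis=1) for g in design.groups}
    return pd.DataFrame(cols)


def spearman_group_correlation(profiles: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation between group mean profiles.

    Symmetric with unit diagonal; a pair involving a constant profile has
    undefined correlation and is reported as NaN rather than 0.
    """
    groups = list(profiles.columns)
    if len(groups) < 2:
        raise ValueError("need at least 2 group profiles")
    out = pd.DataFrame(np.eye(len(groups)), index=groups, columns=groups)
    for a, b in itertools.combinations(groups, 2):
        x, y = profiles[a].to_numpy(), profiles[b].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho = np.nan
        else:
            rho = _sps.spearmanr(x, y).statistic
        out.loc[a, b] = out.loc[b, a] = rho
    return out


def presence_sets(matrix: PSMMatrix, design: GroupDesign) -> dict[str, set[str]]:
    """Proteins detected (nonzero in at least one subject) per group."""
    return {
        g: set(matrix.values.index[(matrix.values[design.subjects_in(g)] > 0).any(axis=1)])
        for g in design.groups
    }


def overlap_partition(sets: dict[str, set[str]]) -> dict[frozenset[str], int]:
    """Counts of every exclusive Venn region over 1-3 (or more) groups.

    The returned map has one entry per non-empty subset of group labels;
    its value counts elements belonging to exactly those groups.  Region
    counts sum to the union size.
    """
    groups = list(sets)
    if not groups:
        raise ValueError("no sets given")
    out: dict[frozenset[str], int] = {
        frozenset(c): 0
        for r in range(1, len(groups) + 1)
        for c in itertools.combinations(groups, r)
    }
    universe = set().union(*sets.values())
    for element in universe:
        member_of = frozenset(g for g in groups if element in sets[g])
        out[member_of] += 1
    return out


# ---------------------------------------------------------------------------
# DAP selection
# ---------------------------------------------------------------------------

def identification_frequency(matrix: PSMMatrix, design: GroupDesign) -> pd.DataFrame:
    """Integer-percent IF per protein and group (halves round away from zero)."""
    cols = {}
    for g in design.groups:
        sub = matrix.values[design.subjects_in(g)]
        frac = (sub > 0).sum(axis=1) / sub.shape[1]
        cols[g] = round_half_away(100.0 * frac.to_numpy())
    return pd.DataFrame(cols, index=matrix.values.index)


def select_daps_by_if(if_table: pd.DataFrame) -> set[str]:
    """IF rule: strictly > 50% in some group and strictly < 50% in another."""
    high = (if_table > 50).any(axis=1)
    low = (if_table < 50).any(axis=1)
    return set(if_table.index[high & low])


def anova_f_selection(
    matrix: PSMMatrix,
    design: GroupDesign,
    f_threshold: float = 3.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-protein one-way F ratio across groups with the joint selection rule.

    Selected iff ``F >= f_threshold`` and ``p <= p_threshold``.  Proteins
    with zero total variance get F = 0 and are never selected.
    """
    subjects = matrix.subject_ids
    labels = design.labels_for(subjects)
    f, p = one_way_f(matrix.values.to_numpy(), labels)
    return pd.DataFrame(
        {
            "F_ratio": f,
            "p_value": p,
            "selected": apply_f_rule(f, p, f_threshold, p_threshold),
        },
        index=matrix.values.index,
    )


def dave_index(mean_a: float, mean_b: float) -> float:
    """DAve differential-abundance index for one protein, two conditions.

    ``((A - B) / (A + B)) / 0.5`` in [-2, 2]; ±2 when the protein is
    exclusive to one condition; NaN (undefined) when both means are zero.
    Positive values mean higher abundance in A.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    if mean_a == 0 and mean_b == 0:
        return math.nan
    if mean_b == 0:
        return 2.0
    if mean_a == 0:
        return -2.0
    return ((mean_a - mean_b) / (mean_a + mean_b)) / 0.5


def pairwise_dave_filter(dave: float, threshold: float = 0.4) -> bool:
    """Two-sided magnitude threshold: retained iff ``|DAve| >= threshold``."""
    if math.isnan(dave):
        return False
    return abs(dave) >= threshold


def pairwise_dave_table(group_means: pd.DataFrame) -> pd.DataFrame:
    """DAve per protein for every ordered pair of groups (columns ``A_vs_B``)."""
    out = {}
    for a, b in itertools.combinations(group_means.columns, 2):
        out[f"{a}_vs_{b}"] = [
            dave_index(x, y)
            for x, y in zip(group_means[a].to_numpy(), group_means[b].to_numpy())
        ]
    return pd.DataFrame(out, index=group_means.index)


def combine_daps(
    if_set: set[str],
    lda_set: set[str],
    dave_table: pd.DataFrame,
    if_table: pd.DataFrame | None = None,
    group_means: pd.DataFrame | None = None,
    f_stats: pd.DataFrame | None = None,
    dave_threshold: float = 0.4,
) -> pd.DataFrame:
    """Union of IF- and F-selected proteins with provenance and DAve calls.

    One row per selected protein; ``source`` is ``IF``, ``LDA`` or
    ``both``.  For every group pair the DAve value is annotated along
    with a boolean ``pass_dave`` call at ``dave_threshold`` (the
    direction filter applied to F/LDA-derived candidates).
    """
    union = sorted(if_set | lda_set)
    out = pd.DataFrame(index=pd.Index(union, name="protein_id"))
    out["source"] = [
        "both" if p in if_set and p in lda_set else ("IF" if p in if_set else "LDA")
        for p in union
    ]
    if group_means is not None:
        for g in group_means.columns:
            out[f"mean_{g}"] = group_means.loc[union, g]
    if if_table is not None:
        for g in if_table.columns:
            out[f"IF_{g}"] = if_table.loc[union, g]
    for pair in dave_table.columns:
        vals = dave_table.loc[union, pair]
        out[f"DAve_{pair}"] = vals
        out[f"pass_dave_{pair}"] = [pairwise_dave_filter(v, dave_threshold) for v in vals]
    if f_stats is not None:
        out["F_ratio"] = f_stats.loc[union, "F_ratio"]
        out["p_value"] = f_stats.loc[union, "p_value"]
    return out


def select_daps(
    matrix: PSMMatrix,
    design: GroupDesign,
    f_threshold: float = 3.5,
    p_threshold: float = 0.05,
    dave_threshold: float = 0.4,
) -> pd.DataFrame:
    """Full DAP selection pipeline on a raw or normalized matrix."""
    normalized = matrix if matrix.normalized else normalize_total_signal(matrix)
    if_table = identification_frequency(matrix, design)
    if_set = select_daps_by_if(if_table)
    f_stats = anova_f_selection(normalized, design, f_threshold, p_threshold)
    lda_set = set(f_stats.index[f_stats["selected"]])
    means = group_mean_profiles(normalized, design)
    daves = pairwise_dave_table(means)
    return combine_daps(
        if_set, lda_set, daves,
        if_table=if_table, group_means=means, f_stats=f_stats,
        dave_threshold=dave_threshold,
    )


# ---------------------------------------------------------------------------
# presence-based biomarker test
# ---------------------------------------------------------------------------

def _exact_presence_p(n_a: int, n_b: int, a_present: int, k_present: int) -> float:
    """Exact two-sided permutation p for a binary presence split.

    Under exchangeability the number of present subjects landing in group
    A follows a hypergeometric permutation null; the two-sided p doubles
    the smaller tail (capped at 1), matching an exact rank-sum on 0/1
    indicators.
    """
    n = n_a + n_b
    denom = math.comb(n, n_a)
    pmf = [
        math.comb(k_present, a) * math.comb(n - k_present, n_a - a) / denom
        for a in range(n_a + 1)
    ]
    lower = sum(pmf[: a_present + 1])
    upper = sum(pmf[a_present:])
    return min(1.0, 2.0 * min(lower, upper))


def presence_ranksum_test(
    matrix: PSMMatrix,
    design: GroupDesign,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Exact two-sided rank-sum test on per-subject presence indicators.

    For each protein the subjects of the two groups are reduced to 1
    (detected, PSM > 0) or 0, and the exact permutation null over group
    assignments gives the two-sided p-value.  Detected counts and
    rounded percentages are reported per group, with Benjamini–Hochberg
    adjusted p-values alongside the raw ones.
    """
    subs_a = design.subjects_in(group_a)
    subs_b = design.subjects_in(group_b)
    if len(subs_a) < 2 or len(subs_b) < 2:
        raise ValueError("both groups need at least 2 subjects")
    present_a = (matrix.values[subs_a] > 0).sum(axis=1).to_numpy()
    present_b = (matrix.values[subs_b] > 0).sum(axis=1).to_numpy()
    n_a, n_b = len(subs_a), len(subs_b)
    p_values = np.array(
        [
            _exact_presence_p(n_a, n_b, int(a), int(a + b))
            for a, b in zip(present_a, present_b)
        ]
    )
    _, p_adj, _, _ = multipletests(p_values, method="fdr_bh")
    return pd.DataFrame(
        {
            f"count_{group_a}": present_a,
            f"percent_{group_a}": round_half_away(100.0 * present_a / n_a),
            f"count_{group_b}": present_b,
            f"percent_{group_b}": round_half_away(100.0 * present_b / n_b),
            "p_value": p_values,
            "p_adjusted": p_adj,
        },
        index=matrix.values.index,
    )


# ---------------------------------------------------------------------------
# clustering / PCA quality control
# ---------------------------------------------------------------------------

@dataclass
class ClusterQC:
    """Hierarchical clustering and PCA of subjects over selected proteins."""

    subjects: list[str]
    linkage: np.ndarray
    pca_coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster labels from the dendrogram's top splits."""
        flat = _sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.subjects, (int(c) for c in flat)))


def cluster_qc(matrix: PSMMatrix, design: GroupDesign) -> ClusterQC:
    """Ward/Euclidean clustering and PCA of subjects over a DAP-restricted matrix.

    Subjects are the observations, selected proteins the features.  The
    per-component variance shares sum to one over all retained
    components.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("need at least 2 proteins for clustering QC")
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least 3 subjects for clustering QC")
    data = matrix.values.to_numpy().T  # subjects x proteins
    linkage = _sch.linkage(data, method="ward", metric="euclidean")
    n_comp = min(data.shape[0], data.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(data)
    coord_frame = pd.DataFrame(
        coords,
        index=matrix.subject_ids,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return ClusterQC(
        subjects=matrix.subject_ids,
        linkage=linkage,
        pca_coordinates=coord_frame,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
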