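"""Shared statistical kernels used by more than one analysis stage."""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps


def one_way_f(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise one-way fixed-effects F ratio across groups.

    Parameters
    ----------
    values
        2-D array, one row per feature, one column per subject.
    labels
        1-D array of group labels, one per column of ``values``.

    Returns
    -------
    (F, p)
        Between/within variance ratio with ``df1 = g - 1`` and
        ``df2 = N - g``, and the upper-tail p-value from the F
        distribution.  Rows with zero total variance get ``F = 0`` and
        ``p = 1``; rows with zero within-group variance but nonzero
        between-group variance get ``F = inf`` and ``p = 0``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    g = groups.size
    n_total = values.shape[1]
    if g < 2:
        raise ValueError("one_way_f requires at least 2 groups")
    for grp in groups:
        if np.sum(labels == grp) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 subjects")

    grand = values.mean(axis=1, keepdims=True)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for grp in groups:
        cols = values[:, labels == grp]
        m = cols.mean(axis=1, keepdims=True)
        ssb += cols.shape[1] * (m - grand).ravel() ** 2
        ssw += ((cols - m) ** 2).sum(axis=1)

    df1 = g - 1
    df2 = n_total - g
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    # degenerate rows: no variance at all -> F = 0; perfect separation -> inf
    f = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), f)
    p = np.where(np.isinf(f), 0.0, _sps.f.sf(np.where(np.isinf(f), 0.0, f), df1, df2))
    p = np.where(f == 0, 1.0, p)
    return f, p


def apply_f_rule(
    f: np.ndarray,
    p: np.ndarray,
    f_threshold: float = 3.5,
    p_threshold: float = 0.05,
) -> np.ndarray:
    """Joint selection rule: F >= f_threshold AND p <= p_threshold."""
    return (np.asarray(f) >= f_threshold) & (np.asarray(p) <= p_threshold)


def round_half_away(x: np.ndarray | float) -> np.ndarray | int:
    """Round to the nearest integer, halves away from zero (printed-percent style)."""
    arr = np.asarray(x, dtype=float)
    out = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
    return out.astype(int) if arr.ndim else int(out)
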