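"""Cluster occupancy and transition dynamics from per-herd label series.

Successive bulk-tank records of a herd (1-3 days apart) form a categorical
time series of cluster labels.  The transition matrix counts consecutive
within-herd pairs (cluster at time t, cluster at time t+1) pooled over
herds, and row-normalizes the counts into probabilities.  Rows with no
observed departures are flagged rather than invented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TransitionMatrix",
    "transition_matrix",
    "cluster_proportions",
    "stationary_distribution",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """Pooled k x k transition counts with row-normalized probabilities."""

    counts: pd.DataFrame
    probabilities: pd.DataFrame
    population: str = ""

    @property
    def empty_rows(self) -> list[int]:
        """States never observed as a departure point (probability rows NaN)."""
        return [int(s) for s in self.counts.index[self.counts.sum(axis=1) == 0]]

    def to_percent(self) -> pd.DataFrame:
        return self.probabilities * 100.0


def transition_matrix(
    label_series: pd.DataFrame,
    n_states: int | None = None,
    max_gap_days: float | None = None,
    population: str = "",
) -> TransitionMatrix:
    """Estimate the transition matrix from a labeled record table.

    ``label_series`` needs columns ``herd_id, date, label`` with labels in
    1..k and dates sorted within each herd (unsorted input is rejected,
    never silently reordered).  Pairs are consecutive records of the same
    herd; pairs more than ``max_gap_days`` apart are excluded when that
    option is set.  Counts are pooled across herds.
    """
    df = label_series
    labels = df["label"].to_numpy()
    if n_states is None:
        n_states = int(labels.max())
    if labels.min() < 1 or labels.max() > n_states:
        raise ValueError(f"labels must lie in 1..{n_states}")
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    dates = pd.to_datetime(df["date"])
    for _, grp in df.groupby("herd_id", sort=False):
        d = pd.to_datetime(grp["date"]).to_numpy()
        if len(d) > 1 and (np.diff(d) <= np.timedelta64(0, "s")).any():
            raise ValueError("per-herd series must be strictly date-sorted")
        lab = grp["label"].to_numpy()
        src, dst = lab[:-1] - 1, lab[1:] - 1
        if max_gap_days is not None and len(d) > 1:
            gaps = np.diff(d) / np.timedelta64(1, "D")
            keep = gaps <= max_gap_days
            src, dst = src[keep], dst[keep]
        np.add.at(counts, (src, dst), 1)
    idx = pd.RangeIndex(1, n_states + 1, name="from")
    cols = pd.RangeIndex(1, n_states + 1, name="to")
    counts_df = pd.DataFrame(counts, index=idx, columns=cols)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row_sums > 0, counts / row_sums, np.nan)
    probs_df = pd.DataFrame(probs, index=idx, columns=cols)
    _ = dates  # date parsing validated above
    return TransitionMatrix(counts_df, probs_df, population)


def cluster_proportions(
    labels: pd.Series | np.ndarray, by: pd.Series | None = None
) -> pd.DataFrame:
    """Fraction of records per cluster, optionally split by population tag."""
    lab = pd.Series(np.asarray(labels), name="label")
    if by is None:
        frac = lab.value_counts(normalize=True).sort_index()
        return frac.rename("proportion").to_frame().T.set_axis(["all"])
    tag = pd.Series(np.asarray(by), name="population")
    out = (
        pd.crosstab(tag, lab, normalize="index")
        .sort_index(axis=1)
    )
    out.columns.name = "label"
    return out


def stationary_distribution(probabilities, tol: float = 1e-10) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix.

    The left eigenvector for eigenvalue 1, normalized to sum to 1.  The
    chain must be irreducible over states with observed departures;
    reducible chains (e.g. the identity matrix) are rejected.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.isnan(p).any():
        raise ValueError("probability matrix has empty (NaN) rows")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows must sum to 1")
    n_comp, _ = connected_components(p > 0, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError(f"chain is reducible ({n_comp} strongly connected components)")
    w, v = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = pi / pi.sum()
    if (pi < -tol).any():
        raise ValueError("no non-negative stationary vector found (periodic chain?)")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()
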