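"""Cluster summaries, probability time series and the traffic-light layer.

The monitoring product of the pipeline: per-cluster trait means/SDs with
best/worst-two rankings under a configurable "is high good?" orientation,
per-herd cluster-membership probability series, correlations between the
probabilities and traits, and a green/orange/red flag per record derived
from a configurable cluster-to-flag map.  For the Walloon cluster
numbering the default map flags cluster 3 red (abnormal profile),
clusters 2, 5 and 6 orange (transient/intermediate stress), and clusters
1, 4 and 7 green.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import DEFAULT_FLAG_MAP, DEFAULT_TRAIT_ORIENTATION

__all__ = [
    "ClusterSummary",
    "summarize_clusters",
    "flag_records",
    "probability_series",
    "probability_trait_correlations",
    "alert_episodes",
]

_FLAGS = ("green", "orange", "red")


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster trait statistics with favourability rankings."""

    means: pd.DataFrame  # cluster x trait
    sds: pd.DataFrame
    ranks: pd.DataFrame  # 1 = most favourable under the orientation
    best_two: dict[str, list[int]]
    worst_two: dict[str, list[int]]
    empty_clusters: tuple[int, ...] = ()


def summarize_clusters(
    records: pd.DataFrame,
    labels,
    trait_orientation: dict[str, bool] | None = None,
) -> ClusterSummary:
    """Per-cluster means/SDs and best-/worst-two cluster sets per trait.

    ``trait_orientation`` maps trait name to "high is favourable"; traits
    absent from the map are ranked with high-is-good.  Orientation is an
    interpretive convention, shipped as an editable default.  Single-record
    clusters get a missing SD; empty clusters are reported, not invented.
    """
    orientation = dict(DEFAULT_TRAIT_ORIENTATION)
    if trait_orientation:
        orientation.update(trait_orientation)
    lab = pd.Series(np.asarray(labels), index=records.index, name="cluster")
    numeric = records.select_dtypes(include=[np.number])
    grouped = numeric.groupby(lab)
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    means.index.name = sds.index.name = "cluster"

    ranks = pd.DataFrame(index=means.index, columns=means.columns, dtype=float)
    best_two: dict[str, list[int]] = {}
    worst_two: dict[str, list[int]] = {}
    for trait in means.columns:
        high_good = orientation.get(trait, True)
        r = means[trait].rank(ascending=not high_good, method="first")
        ranks[trait] = r
        order = r.sort_values().index
        best_two[trait] = [int(c) for c in order[:2]]
        worst_two[trait] = [int(c) for c in order[-2:]]
    return ClusterSummary(
        means=means,
        sds=sds,
        ranks=ranks,
        best_two=best_two,
        worst_two=worst_two,
        empty_clusters=(),
    )


def flag_records(
    labels_or_probabilities,
    flag_map: dict[int, str] | None = None,
    probability_threshold: float | None = None,
) -> pd.Series:
    """Traffic-light flag per record.

    Default mode maps the hard cluster label through ``flag_map``.
    Threshold mode (probabilities given as a DataFrame with columns
    ``p<cluster>`` plus a threshold) escalates to the most severe flag
    among clusters whose membership probability exceeds the threshold,
    even when that cluster is not the argmax — an early-warning reading
    of the probability signal.
    """
    fmap = dict(DEFAULT_FLAG_MAP if flag_map is None else flag_map)
    for c, f in fmap.items():
        if f not in _FLAGS:
            raise ValueError(f"unknown flag {f!r} for cluster {c}")
    severity = {f: i for i, f in enumerate(_FLAGS)}

    if isinstance(labels_or_probabilities, pd.DataFrame):
        probs = labels_or_probabilities
        clusters = [int(c[1:]) for c in probs.columns]
        unmapped = [c for c in clusters if c not in fmap]
        if unmapped:
            raise ValueError(f"clusters missing from flag_map: {unmapped}")
        hard = np.asarray(clusters)[probs.to_numpy().argmax(axis=1)]
        flags = pd.Series([fmap[c] for c in hard], index=probs.index, name="flag")
        if probability_threshold is not None:
            arr = probs.to_numpy()
            for j, c in enumerate(clusters):
                esc = arr[:, j] > probability_threshold
                cand = fmap[c]
                worse = flags.map(severity) < severity[cand]
                flags[esc & worse.to_numpy()] = cand
        return flags

    labels = pd.Series(np.asarray(labels_or_probabilities))
    unmapped = sorted(set(labels.unique()) - set(fmap))
    if unmapped:
        raise ValueError(f"clusters missing from flag_map: {unmapped}")
    return labels.map(fmap).rename("flag")


def probability_series(
    predictions: pd.DataFrame,
    herd_id: str,
    flag_map: dict[int, str] | None = None,
    probability_threshold: float | None = None,
) -> pd.DataFrame:
    """One herd's chronological membership-probability series with flags.

    ``predictions`` carries ``herd_id, date`` and probability columns
    ``p1..pk``.  Returns the herd's rows sorted by date with ``label``
    (argmax cluster) and ``flag`` columns appended.  Duplicate herd-date
    keys are rejected.
    """
    sub = predictions.loc[predictions["herd_id"] == herd_id].copy()
    sub["date"] = pd.to_datetime(sub["date"])
    if sub["date"].duplicated().any():
        raise ValueError(f"duplicate dates for herd {herd_id}")
    sub = sub.sort_values("date", kind="stable")
    pcols = [c for c in sub.columns if c.startswith("p") and c[1:].isdigit()]
    probs = sub[pcols].astype(float)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("probability rows must sum to 1")
    clusters = np.array([int(c[1:]) for c in pcols])
    sub["label"] = clusters[probs.to_numpy().argmax(axis=1)]
    sub["flag"] = flag_records(
        probs, flag_map=flag_map, probability_threshold=probability_threshold
    ).to_numpy()
    return sub


def probability_trait_correlations(
    probabilities: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each cluster-probability column with each trait.

    Rows: probability columns; columns: traits.  Zero-variance columns
    yield missing entries (flagged as NaN) rather than errors.
    """
    if len(probabilities) != len(traits):
        raise ValueError("probabilities and traits must align row-wise")
    if len(probabilities) < 3:
        raise ValueError("need at least 3 records to correlate")
    out = pd.DataFrame(index=probabilities.columns, columns=traits.columns, dtype=float)
    p = probabilities.to_numpy(dtype=float)
    t = traits.to_numpy(dtype=float)
    for i, pc in enumerate(probabilities.columns):
        for j, tc in enumerate(traits.columns):
            x, y = p[:, i], t[:, j]
            if x.std() == 0 or y.std() == 0:
                out.loc[pc, tc] = np.nan
            else:
                out.loc[pc, tc] = float(np.corrcoef(x, y)[0, 1])
    return out


def alert_episodes(flags: pd.Series, min_run: int = 2) -> pd.Series:
    """Boolean alert per record: part of >= ``min_run`` consecutive non-green flags.

    A single isolated orange record is noise at a 1-3 day sampling rhythm;
    a sustained run is the configurable default trigger.
    """
    bad = (flags != "green").to_numpy()
    runs = np.zeros(len(bad), dtype=int)
    count = 0
    for i, b in enumerate(bad):
        count = count + 1 if b else 0
        runs[i] = count
    alert = np.zeros(len(bad), dtype=bool)
    i = len(bad) - 1
    while i >= 0:
        if runs[i] >= min_run:
            alert[i - runs[i] + 1 : i + 1] = True
        i -= 1
    return pd.Series(alert, index=flags.index, name="alert")
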