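"""GH-stratified subsampling for the clustering stage.

Hierarchical clustering cannot hold the full population in memory, so the
clustering subset keeps *all* extreme records (GH at or above the top
boundary) and draws a fixed-size uniform sample without replacement from
each lower stratum.  This equilibrates common and rare profiles, which is
what lets rare herd states form their own clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StrataPlan", "stratified_subsample"]


@dataclass(frozen=True)
class StrataPlan:
    """Stratum boundaries and draw sizes.

    With the default boundaries ``(0, 1, 2, 3)`` the bounded strata are
    [0, 1), [1, 2), [2, 3) and the kept tail is GH >= 3.
    """

    boundaries: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    per_stratum_n: int = 5000
    keep_tail: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) < 2 or not (np.diff(b) > 0).all():
            raise ValueError("boundaries must be strictly increasing, length >= 2")
        if self.per_stratum_n < 0:
            raise ValueError("per_stratum_n must be >= 0")


def stratified_subsample(
    gh: pd.Series, plan: StrataPlan
) -> tuple[pd.Index, dict]:
    """Select the clustering subset from per-record GH scores.

    Returns ``(keys, report)`` where keys index into ``gh`` and the report
    maps each stratum to its size and drawn count.  Strata are half-open
    [a, b); the tail (gh >= top boundary) is kept in full when
    ``plan.keep_tail``.  Draws are uniform without replacement and
    deterministic under ``plan.seed``; a stratum smaller than
    ``per_stratum_n`` is taken whole and noted as a shortfall.
    """
    if gh.isna().any():
        raise ValueError("gh must be present for all records")
    rng = np.random.default_rng(plan.seed)
    b = list(plan.boundaries)
    selected: list[pd.Index] = []
    report: dict[str, dict] = {}

    for lo, hi in zip(b[:-1], b[1:]):
        idx = gh.index[(gh >= lo) & (gh < hi)]
        take = min(plan.per_stratum_n, len(idx))
        drawn = (
            pd.Index(rng.choice(idx.to_numpy(), size=take, replace=False))
            if take
            else pd.Index([], dtype=gh.index.dtype)
        )
        selected.append(drawn)
        report[f"[{lo:g}, {hi:g})"] = {
            "size": int(len(idx)),
            "drawn": int(take),
            "shortfall": bool(len(idx) < plan.per_stratum_n),
        }

    tail = gh.index[gh >= b[-1]]
    if plan.keep_tail:
        selected.append(tail)
        report[f"[{b[-1]:g}, inf)"] = {
            "size": int(len(tail)), "drawn": int(len(tail)), "shortfall": False,
        }
    parts = [p for p in selected if len(p)]
    if not parts:
        return pd.Index([], dtype=gh.index.dtype), report
    keys = parts[0].append(parts[1:]) if len(parts) > 1 else parts[0]
    return keys, report
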