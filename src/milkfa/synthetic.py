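"""Synthetic bulk-tank milk generator.

Herds evolve as a first-order Markov chain over K latent states (feeding /
stress regimes).  Conditional on its state, each bulk-tank record is a draw
from a state-specific multivariate Gaussian over the 31 fatty-acid traits
(g/100 g fat), fat and protein (g/dL milk) and six auxiliary phenotypes.
Sampling dates are irregular, 1-3 days apart, as in routine milk-payment
collection.  The default generating truth is the Walloon reference
parameter set in :mod:`milkfa.reference`.

Records are emitted on the milk basis (FA in g/dL milk, obtained from the
fat-basis draw and the record's fat content), so the downstream cleaning
and unit-conversion steps operate on data shaped like the real source.
Artifacts (missing values, out-of-range fat/protein, negative FA values)
can be injected to exercise the cleaning rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .reference import AUX_TRAITS, COMPOSITION_TRAITS, FA_TRAITS

__all__ = [
    "StateModel",
    "SimConfig",
    "make_state_models",
    "default_state_models",
    "simulate_herd_series",
    "simulate_population",
    "simulate_spectra",
    "inject_artifacts",
]

_STUDIED = list(FA_TRAITS) + list(COMPOSITION_TRAITS) + list(AUX_TRAITS)


@dataclass(frozen=True)
class StateModel:
    """One latent herd state: a Gaussian over the modeled traits."""

    state_id: int
    mean: pd.Series
    covariance: np.ndarray

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (len(self.mean), len(self.mean)):
            raise ValueError("covariance shape does not match mean length")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigmin = np.linalg.eigvalsh(cov).min()
        if eigmin <= 0:
            raise ValueError(
                f"covariance must be positive-definite (min eigenvalue {eigmin:g})"
            )
        fa_means = self.mean.reindex(FA_TRAITS).dropna()
        if (fa_means < 0).any():
            raise ValueError("fatty-acid state means must be non-negative")

    @property
    def traits(self) -> list[str]:
        return list(self.mean.index)


@dataclass
class SimConfig:
    """Simulation settings for one synthetic population."""

    n_herds: int = 50
    horizon_days: int = 120
    #: probability of a 1-, 2- or 3-day gap between successive tank records
    sampling_interval: dict[int, float] = field(
        default_factory=lambda: {1: 1 / 3, 2: 1 / 3, 3: 1 / 3}
    )
    transition: np.ndarray = field(default_factory=reference.transition_matrix)
    initial_distribution: np.ndarray | None = None
    seed: int = 0
    start_date: str = "2021-01-01"
    artifact_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")
        if self.n_herds < 1:
            raise ValueError("n_herds must be >= 1")
        tm = np.asarray(self.transition, dtype=float)
        if tm.ndim != 2 or tm.shape[0] != tm.shape[1]:
            raise ValueError("transition matrix must be square")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1 within 1e-9")
        if (tm < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        self.transition = tm
        gaps = self.sampling_interval
        if not gaps or any(g not in (1, 2, 3) for g in gaps):
            raise ValueError("sampling_interval support must be within {1, 2, 3}")
        total = sum(gaps.values())
        if total <= 0:
            raise ValueError("sampling_interval probabilities must sum > 0")
        self.sampling_interval = {g: p / total for g, p in gaps.items()}
        for name, rate in self.artifact_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"artifact rate {name!r} must be in [0, 1]")


def make_state_models(
    mean_table: pd.DataFrame,
    sd_table: pd.Series,
    within_state_sd_fraction: float = 0.5,
    correlation: np.ndarray | None = None,
) -> list[StateModel]:
    """Build one :class:`StateModel` per row of ``mean_table``.

    The within-state covariance is ``D @ C @ D`` where ``D`` is the diagonal
    of ``within_state_sd_fraction * sd`` and ``C`` the supplied trait
    correlation (identity if absent).  The fraction scales the population
    dispersion down to a within-state dispersion, so that between-state
    spread dominates and states remain statistically distinguishable.
    """
    if not 0.0 < within_state_sd_fraction <= 1.0:
        raise ValueError("within_state_sd_fraction must be in (0, 1]")
    traits = list(mean_table.columns)
    missing = set(traits) - set(sd_table.index)
    if missing:
        raise ValueError(f"sd_table is missing traits: {sorted(missing)}")
    sds = sd_table.reindex(traits).to_numpy(dtype=float)
    if (sds <= 0).any():
        bad = [t for t, s in zip(traits, sds) if s <= 0]
        raise ValueError(f"traits with non-positive SD give a degenerate covariance: {bad}")
    d = within_state_sd_fraction * sds
    if correlation is None:
        corr = np.eye(len(traits))
    else:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (len(traits), len(traits)):
            raise ValueError("correlation shape does not match trait count")
        corr = _nearest_pd_correlation(corr)
    cov = corr * np.outer(d, d)
    return [
        StateModel(state_id=int(idx), mean=row.astype(float), covariance=cov.copy())
        for idx, row in mean_table.iterrows()
    ]


def _nearest_pd_correlation(corr: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues to make a symmetric correlation matrix PD."""
    corr = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(corr)
    if w.min() > 0:
        return corr
    if w.min() < -0.1:
        raise ValueError("correlation matrix is far from positive-definite")
    w = np.clip(w, min_eig, None)
    fixed = (v * w) @ v.T
    # restore unit diagonal
    s = np.sqrt(np.diag(fixed))
    return fixed / np.outer(s, s)


def default_state_models(
    within_state_sd_fraction: float = 0.5,
    correlation: np.ndarray | None = None,
) -> list[StateModel]:
    """The seven Walloon reference states with default dispersion."""
    return make_state_models(
        reference.cluster_means(),
        reference.trait_sds(),
        within_state_sd_fraction=within_state_sd_fraction,
        correlation=correlation,
    )


def _simulate_chain(
    transition: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    initial_distribution: np.ndarray | None,
) -> np.ndarray:
    k = transition.shape[0]
    if initial_distribution is None:
        initial_distribution = np.full(k, 1.0 / k)
    # inverse-CDF sampling on precomputed row CDFs: one uniform per step
    cdf = np.cumsum(transition, axis=1)
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = np.searchsorted(np.cumsum(initial_distribution), rng.random())
    u = rng.random(n_steps)
    for i in range(1, n_steps):
        states[i] = np.searchsorted(cdf[states[i - 1]], u[i])
    return states


def simulate_herd_series(
    states: list[StateModel],
    config: SimConfig,
    herd_id: str,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one herd's bulk-tank series.

    Returns ``(records, truth)``: records on the milk basis with strictly
    increasing dates, and the aligned latent-state labels for truth-based
    testing.  FA draws are truncated at zero (real negatives are artifacts,
    injected separately).
    """
    if not states:
        raise ValueError("need at least one state model")
    k = len(states)
    if config.transition.shape[0] != k:
        raise ValueError("transition dimension does not match number of states")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    gap_vals = np.array(sorted(config.sampling_interval))
    gap_p = np.array([config.sampling_interval[g] for g in gap_vals])
    # day offsets until the horizon is exhausted
    offsets = [0]
    while True:
        nxt = offsets[-1] + int(rng.choice(gap_vals, p=gap_p))
        if nxt >= config.horizon_days:
            break
        offsets.append(nxt)
    n = len(offsets)
    labels = _simulate_chain(config.transition, n, rng, config.initial_distribution)

    traits = states[0].traits
    draws = np.empty((n, len(traits)))
    for s_idx in range(k):
        mask = labels == s_idx
        if not mask.any():
            continue
        sm = states[s_idx]
        draws[mask] = rng.multivariate_normal(
            sm.mean.to_numpy(dtype=float), sm.covariance, size=int(mask.sum()),
            method="cholesky",
        )
    df = pd.DataFrame(draws, columns=traits)
    fa_cols = [t for t in FA_TRAITS if t in df.columns]
    df[fa_cols] = df[fa_cols].clip(lower=0.0)
    df["fat"] = df["fat"].clip(lower=0.1)  # fat must stay positive for the basis change
    # emit on the milk basis: FA[g/dL milk] = FA[g/100 g fat] * fat[g/dL] / 100
    df[fa_cols] = df[fa_cols].mul(df["fat"] / 100.0, axis=0)

    dates = pd.to_datetime(config.start_date) + pd.to_timedelta(offsets, unit="D")
    df.insert(0, "herd_id", herd_id)
    df.insert(1, "date", dates)
    df["unit_basis"] = "milk_basis"
    truth = pd.DataFrame(
        {"herd_id": herd_id, "date": dates, "state_id": labels + 1}
    )
    return df, truth


def simulate_population(
    states: list[StateModel], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``config.n_herds`` herds; reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    rec_parts, truth_parts = [], []
    width = max(4, len(str(config.n_herds)))
    for h in range(config.n_herds):
        herd_id = f"H{h + 1:0{width}d}"
        rec, truth = simulate_herd_series(states, config, herd_id, rng=rng)
        rec_parts.append(rec)
        truth_parts.append(truth)
    records = pd.concat(rec_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    return records, truth


def simulate_spectra(
    records: pd.DataFrame,
    n_points: int = 212,
    noise_sd: float = 0.1,
    seed: int = 0,
    loading_seed: int = 97,
) -> pd.DataFrame:
    """Emulated first-derivative spectra: a fixed linear image of the FA traits.

    Each spectrum is ``W @ traits + noise`` with a loading matrix ``W`` drawn
    once from ``loading_seed`` (the same map for every record and every call
    with the same ``loading_seed``, so train/test spectra live in one space).
    These are a statistical stand-in, not physically realistic MIR spectra.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fa_cols = [t for t in FA_TRAITS if t in records.columns]
    if n_points < len(fa_cols):
        raise ValueError("n_points must be >= number of FA traits")
    x = records[fa_cols].to_numpy(dtype=float)
    w = np.random.default_rng(loading_seed).standard_normal((n_points, len(fa_cols)))
    w /= np.sqrt(len(fa_cols))
    spectra = x @ w.T
    if noise_sd > 0:
        spectra = spectra + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=spectra.shape
        )
    cols = [f"sp{i + 1:03d}" for i in range(n_points)]
    return pd.DataFrame(spectra, columns=cols, index=records.index)


def inject_artifacts(
    records: pd.DataFrame,
    artifact_rates: dict[str, float],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Perturb a copy of ``records`` with data-entry artifacts.

    ``artifact_rates`` maps artifact names to per-row probabilities:

    - ``out_of_range``: fat outside [1.5, 9] or protein outside [1, 7]
    - ``negative_fa``: one FA trait flipped negative
    - ``missing``: one studied trait set to NaN

    Each artifact type is drawn independently per row.  Returns the
    perturbed table and a log with one row per perturbation
    (``row``, ``artifact``, ``column``, ``old_value``, ``new_value``).
    """
    for name, rate in artifact_rates.items():
        if name not in ("out_of_range", "negative_fa", "missing"):
            raise ValueError(f"unknown artifact type {name!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError("artifact rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = records.copy()
    fa_cols = [t for t in FA_TRAITS if t in out.columns]
    studied = [t for t in _STUDIED if t in out.columns]
    log_rows: list[dict] = []

    def _hit_rows(rate: float) -> np.ndarray:
        return out.index[rng.random(len(out)) < rate]

    rate = artifact_rates.get("out_of_range", 0.0)
    if rate > 0:
        for idx in _hit_rows(rate):
            col = rng.choice(["fat", "fat", "protein", "protein"])
            low = rng.random() < 0.5
            if col == "fat":
                new = rng.uniform(0.1, 1.4) if low else rng.uniform(9.1, 12.0)
            else:
                new = rng.uniform(0.1, 0.9) if low else rng.uniform(7.1, 10.0)
            log_rows.append(
                {"row": idx, "artifact": "out_of_range", "column": col,
                 "old_value": out.at[idx, col], "new_value": new}
            )
            out.at[idx, col] = new

    rate = artifact_rates.get("negative_fa", 0.0)
    if rate > 0 and fa_cols:
        for idx in _hit_rows(rate):
            col = str(rng.choice(fa_cols))
            old = out.at[idx, col]
            new = -abs(old) if old != 0 else -0.01
            log_rows.append(
                {"row": idx, "artifact": "negative_fa", "column": col,
                 "old_value": old, "new_value": new}
            )
            out.at[idx, col] = new

    rate = artifact_rates.get("missing", 0.0)
    if rate > 0 and studied:
        for idx in _hit_rows(rate):
            col = str(rng.choice(studied))
            log_rows.append(
                {"row": idx, "artifact": "missing", "column": col,
                 "old_value": out.at[idx, col], "new_value": np.nan}
            )
            out.at[idx, col] = np.nan

    log = pd.DataFrame(
        log_rows, columns=["row", "artifact", "column", "old_value", "new_value"]
    )
    return out, log
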