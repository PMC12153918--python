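"""Record cleaning, unit conversion, reference PCA and GH novelty scoring.

The cleaning rules follow routine dairy milk-recording recommendations
applied at the bulk-tank level: fat in [1.5, 9] g/dL, protein in [1, 7]
g/dL, no negative fatty acids, no missing studied trait.  Cleaning happens
on the milk basis; FA concentrations are then re-expressed in g/100 g fat,
the basis on which all downstream multivariate analysis runs.

The reference projection is a PCA of the standardized 31 FA traits fitted
on one reference population.  Any population can then be projected onto it
without refitting, and each record receives a GH score — the squared
Mahalanobis distance of its retained PC scores from the reference score
mean, divided by the number of retained components:

    GH = (x - mu)' S^-1 (x - mu) / nPC

On the Gaussian reference population nPC * GH is approximately
chi-squared(nPC), so GH has mean about 1 and GH > 3 marks an extreme
record.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .reference import AUX_TRAITS, COMPOSITION_TRAITS, FA_TRAITS

__all__ = [
    "FAT_BOUNDS",
    "PROTEIN_BOUNDS",
    "clean_records",
    "convert_to_fat_basis",
    "ReferenceProjection",
    "project",
    "compute_gh",
]

FAT_BOUNDS = (1.5, 9.0)
PROTEIN_BOUNDS = (1.0, 7.0)

_STUDIED = list(FA_TRAITS) + list(COMPOSITION_TRAITS) + list(AUX_TRAITS)


def _basis(records: pd.DataFrame) -> str:
    if "unit_basis" in records.columns:
        vals = records["unit_basis"].unique()
        if len(vals) > 1:
            raise ValueError(f"mixed unit_basis values: {vals}")
        return str(vals[0])
    return "milk_basis"


def clean_records(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter out-of-bound, negative-FA and incomplete rows.

    Operates on milk-basis records (the bounds are stated in g/dL of milk).
    Returns ``(kept, log)``; the log holds one reason per rejected row,
    the first failing rule in the fixed order fat-bound, protein-bound,
    negative-FA, missing.  Bound rules only fire on observed values;
    rows with missing fat/protein fall through to the missing rule.
    """
    if _basis(records) != "milk_basis":
        raise ValueError("clean_records expects milk-basis records")
    fa_cols = [t for t in FA_TRAITS if t in records.columns]
    studied = [t for t in _STUDIED if t in records.columns]

    fat = records["fat"]
    protein = records["protein"]
    fat_bad = fat.notna() & ~fat.between(*FAT_BOUNDS)
    protein_bad = protein.notna() & ~protein.between(*PROTEIN_BOUNDS)
    neg_fa = (records[fa_cols] < 0).any(axis=1)
    missing = records[studied].isna().any(axis=1)

    reason = pd.Series(pd.NA, index=records.index, dtype="string")
    # first-failing-rule precedence, applied in reverse so earlier rules win
    reason[missing] = "missing"
    reason[neg_fa] = "negative_fa"
    reason[protein_bad] = "protein_bound"
    reason[fat_bad] = "fat_bound"

    rejected = reason.notna()
    kept = records.loc[~rejected].copy()
    log = pd.DataFrame({"reason": reason[rejected]})
    return kept, log


def convert_to_fat_basis(records: pd.DataFrame) -> pd.DataFrame:
    """Re-express FA concentrations as g/100 g fat.

    ``FA' = 100 * FA / fat``.  Fat, protein and auxiliaries are unchanged.
    Rejects already-converted tables and rows with non-positive fat (clean
    first; cleaning guarantees fat >= 1.5).
    """
    if _basis(records) == "fat_basis":
        raise ValueError("records are already on the fat basis")
    bad = records.index[~(records["fat"] > 0)]
    if len(bad):
        raise ValueError(f"non-positive fat for rows {list(bad[:10])}")
    out = records.copy()
    fa_cols = [t for t in FA_TRAITS if t in out.columns]
    out[fa_cols] = out[fa_cols].mul(100.0 / out["fat"], axis=0)
    out["unit_basis"] = "fat_basis"
    return out


class ReferenceProjection(BaseEstimator, TransformerMixin):
    """Standardized PCA of the FA traits with frozen Mahalanobis geometry.

    Fitting centers and scales each trait to unit variance (the PCA is of
    the correlation structure), decomposes, and retains the smallest number
    of components whose cumulative explained variance reaches
    ``variance_threshold``.  The retained-score mean and covariance of the
    fitting population are stored; projected external populations reuse
    them unchanged, which is what makes GH comparable across populations.

    Parameters
    ----------
    variance_threshold : float, default 0.95
        Cumulative explained-variance fraction that fixes the number of
        retained components.
    trait_order : sequence of str, optional
        Trait columns to use (default: the 31 FA traits).

    Attributes
    ----------
    center_, scale_ : ndarray of shape (n_traits,)
    loadings_ : ndarray of shape (n_traits, n_components), orthonormal columns
    n_pc_ : int
    explained_fraction_ : float, cumulative fraction at ``n_pc_``
    explained_ratio_ : ndarray, per-component fractions (all components)
    score_mean_, score_cov_, score_cov_inv_ : retained-score geometry
    """

    def __init__(self, variance_threshold: float = 0.95, trait_order=None):
        self.variance_threshold = variance_threshold
        self.trait_order = trait_order

    def _traits(self) -> list[str]:
        return list(self.trait_order) if self.trait_order is not None else list(FA_TRAITS)

    def _matrix(self, X) -> np.ndarray:
        traits = self._traits()
        if isinstance(X, pd.DataFrame):
            missing = [t for t in traits if t not in X.columns]
            if missing:
                raise ValueError(f"missing trait columns: {missing}")
            return X[traits].to_numpy(dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.shape[1] != len(traits):
            raise ValueError(
                f"expected {len(traits)} trait columns, got {arr.shape[1]}"
            )
        return arr

    def fit(self, X, y=None) -> "ReferenceProjection":
        if not 0.0 < self.variance_threshold < 1.0:
            raise ValueError("variance_threshold must be in (0, 1)")
        mat = self._matrix(X)
        if mat.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit the projection")
        if not np.isfinite(mat).all():
            raise ValueError("non-finite values in fitting data; clean first")
        self.center_ = mat.mean(axis=0)
        self.scale_ = mat.std(axis=0, ddof=1)
        zero = np.where(self.scale_ == 0)[0]
        if len(zero):
            names = [self._traits()[i] for i in zero]
            raise ValueError(f"constant traits (zero SD): {names}")
        z = (mat - self.center_) / self.scale_
        pca = PCA(svd_solver="full").fit(z)
        ratio = pca.explained_variance_ratio_
        cum = np.cumsum(ratio)
        n_pc = int(np.searchsorted(cum, self.variance_threshold) + 1)
        self.explained_ratio_ = ratio
        self.n_pc_ = n_pc
        self.explained_fraction_ = float(cum[n_pc - 1])
        self.loadings_ = pca.components_[:n_pc].T
        scores = z @ self.loadings_
        self.score_mean_ = scores.mean(axis=0)
        self.score_cov_ = np.cov(scores, rowvar=False, ddof=1)
        self.score_cov_inv_ = np.linalg.inv(self.score_cov_)
        return self

    def transform(self, X) -> np.ndarray:
        """Project records onto the retained components (no refitting)."""
        check_is_fitted(self, "loadings_")
        mat = self._matrix(X)
        return (mat - self.center_) / self.scale_ @ self.loadings_

    def gh(self, X) -> np.ndarray:
        """GH score per record, computed from trait columns."""
        return self.gh_from_scores(self.transform(X))

    def gh_from_scores(self, scores: np.ndarray) -> np.ndarray:
        """GH score from already-projected retained scores."""
        check_is_fitted(self, "score_cov_inv_")
        scores = np.asarray(scores, dtype=float)
        if scores.shape[1] != self.n_pc_:
            raise ValueError(f"expected {self.n_pc_} score columns")
        d = scores - self.score_mean_
        return np.einsum("ij,jk,ik->i", d, self.score_cov_inv_, d) / self.n_pc_

    # -- serialization: exact float round-trip via JSON ---------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "loadings_")
        return {
            "variance_threshold": self.variance_threshold,
            "trait_order": self._traits(),
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "loadings": self.loadings_.tolist(),
            "n_pc": self.n_pc_,
            "explained_fraction": self.explained_fraction_,
            "explained_ratio": self.explained_ratio_.tolist(),
            "score_mean": self.score_mean_.tolist(),
            "score_cov": self.score_cov_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceProjection":
        proj = cls(
            variance_threshold=d["variance_threshold"],
            trait_order=d["trait_order"],
        )
        proj.center_ = np.asarray(d["center"], dtype=float)
        proj.scale_ = np.asarray(d["scale"], dtype=float)
        proj.loadings_ = np.asarray(d["loadings"], dtype=float)
        proj.n_pc_ = int(d["n_pc"])
        proj.explained_fraction_ = float(d["explained_fraction"])
        proj.explained_ratio_ = np.asarray(d["explained_ratio"], dtype=float)
        proj.score_mean_ = np.asarray(d["score_mean"], dtype=float)
        proj.score_cov_ = np.asarray(d["score_cov"], dtype=float)
        proj.score_cov_inv_ = np.linalg.inv(proj.score_cov_)
        return proj

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceProjection":
        return cls.from_dict(json.loads(Path(path).read_text()))


def project(records: pd.DataFrame, projection: ReferenceProjection) -> pd.DataFrame:
    """Score table (PC1..PCn) for fat-basis records, indexed like the input."""
    if _basis(records) != "fat_basis":
        raise ValueError("project expects fat-basis records")
    scores = projection.transform(records)
    cols = [f"PC{i + 1}" for i in range(projection.n_pc_)]
    return pd.DataFrame(scores, columns=cols, index=records.index)


def compute_gh(scores: pd.DataFrame, projection: ReferenceProjection) -> pd.Series:
    """GH per record from a score table produced by :func:`project`."""
    gh = projection.gh_from_scores(np.asarray(scores, dtype=float))
    return pd.Series(gh, index=scores.index, name="gh")
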