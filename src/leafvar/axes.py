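"""Functional trait axes: Horn's parallel analysis, PCA scores and
variance partitioning across organizational levels.

The main axes of leaf trait variation are the principal components of the
scaled (complete, post-imputation) trait table.  Horn's parallel analysis
decides how many axes carry signal: observed correlation-matrix eigenvalues
are bias-corrected with the mean eigenvalues of same-shape standard-normal
datasets, and an axis is retained while its adjusted eigenvalue exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import TRAITS


def _corr_eigvals(X: np.ndarray) -> np.ndarray:
    """Eigenvalues of the correlation matrix, descending, zero-padded.

    Uses an SVD of the standardized data when there are more columns than
    rows, which is much cheaper for wide wavelength blocks.
    """
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column; correlation undefined")
    Z = (X - X.mean(axis=0)) / sd
    if p <= n:
        vals = np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False))[::-1]
    else:
        s = np.linalg.svd(Z, compute_uv=False)
        vals = np.zeros(p)
        vals[: len(s)] = s**2 / (n - 1)
    return np.clip(vals, 0.0, None)


def horn_pa(
    data: np.ndarray | pd.DataFrame,
    n_iter: int = 100,
    seed: int | None = 0,
    eigenvalue_threshold: float = 1.0,
    quantile: float | None = None,
) -> tuple[np.ndarray, int]:
    """Horn's parallel analysis for principal component retention.

    Returns ``(adjusted_eigenvalues, n_retained)`` where
    ``adjusted_k = observed_k - (reference random_k - 1)`` over ``n_iter``
    same-shape standard-normal datasets, and components are retained from
    the first axis while adjusted eigenvalues exceed the threshold.

    The reference is the mean random eigenvalue by default; with
    ``quantile`` set (e.g. 0.95) the per-component empirical quantile is
    used instead, which is strict enough that pure noise retains nothing.
    Under the mean rule the first adjusted eigenvalue of pure noise hovers
    at exactly 1, so retention there is a coin flip by construction.
    """
    X = np.asarray(data, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-d array with at least 2 columns")
    n, p = X.shape
    observed = _corr_eigvals(X)
    rng = np.random.default_rng(seed)
    rand = np.empty((n_iter, p))
    for i in range(n_iter):
        rand[i] = _corr_eigvals(rng.standard_normal((n, p)))
    reference = (
        rand.mean(axis=0) if quantile is None else np.quantile(rand, quantile, axis=0)
    )
    adjusted = observed - (reference - 1.0)
    n_retained = 0
    for v in adjusted:
        if v > eigenvalue_threshold:
            n_retained += 1
        else:
            break
    return adjusted, n_retained


@dataclass
class ScoreTable:
    """PCA scores with loadings and retention diagnostics."""

    scores: pd.DataFrame  # leaf/tree keys + PC1, PC2, ...
    loadings: pd.DataFrame  # traits x components
    explained_variance_ratio: np.ndarray
    adjusted_eigenvalues: np.ndarray | None = None
    n_retained: int | None = None


class HornPCA(TransformerMixin, BaseEstimator):
    """Centered/scaled PCA with Horn's parallel analysis retention.

    Axis signs are fixed so that the trait with the largest absolute
    loading on each axis loads positively, making scores reproducible
    across library versions.  Fitted attributes: ``loadings_`` (columns are
    orthonormal axes), ``explained_variance_ratio_``,
    ``adjusted_eigenvalues_``, ``n_retained_``.
    """

    def __init__(self, n_iter: int = 100, seed: int = 0, run_pa: bool = True):
        self.n_iter = n_iter
        self.seed = seed
        self.run_pa = run_pa

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        n, p = X.shape
        if n < p:
            raise ValueError("fewer rows than traits")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant trait column")
        self.scale_ = sd
        Z = (X - self.mean_) / self.scale_
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        load = vt.T  # (p, n_axes) orthonormal columns
        signs = np.sign(load[np.argmax(np.abs(load), axis=0), np.arange(load.shape[1])])
        signs[signs == 0] = 1.0
        self.loadings_ = load * signs
        eig = s**2 / (n - 1)
        self.explained_variance_ = eig
        self.explained_variance_ratio_ = eig / eig.sum()
        if self.run_pa:
            self.adjusted_eigenvalues_, self.n_retained_ = horn_pa(
                X, n_iter=self.n_iter, seed=self.seed
            )
        else:
            self.adjusted_eigenvalues_, self.n_retained_ = None, None
        self.n_features_in_ = p
        return self

    def transform(self, X):
        Z = (np.asarray(X, float) - self.mean_) / self.scale_
        return Z @ self.loadings_

    def inverse_transform(self, scores):
        return np.asarray(scores, float) @ self.loadings_.T * self.scale_ + self.mean_


def fit_pca(
    leaf_traits: pd.DataFrame,
    trait_cols=TRAITS,
    n_iter: int = 100,
    seed: int = 0,
    n_axes: int = 2,
    run_pa: bool = True,
) -> ScoreTable:
    """Fit the trait PCA and return leaf scores for the leading axes.

    ``leaf_traits`` must be complete (post-imputation); all non-trait
    columns are carried through to the score table as keys.
    """
    X = leaf_traits[list(trait_cols)].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("trait table must be complete before PCA")
    est = HornPCA(n_iter=n_iter, seed=seed, run_pa=run_pa).fit(X)
    scores = est.transform(X)
    keys = [c for c in leaf_traits.columns if c not in trait_cols]
    out = leaf_traits[keys].copy()
    for a in range(min(n_axes, scores.shape[1])):
        out[f"PC{a + 1}"] = scores[:, a]
    loadings = pd.DataFrame(
        est.loadings_,
        index=list(trait_cols),
        columns=[f"PC{i + 1}" for i in range(est.loadings_.shape[1])],
    )
    return ScoreTable(
        scores=out,
        loadings=loadings,
        explained_variance_ratio=est.explained_variance_ratio_,
        adjusted_eigenvalues=est.adjusted_eigenvalues_,
        n_retained=est.n_retained_,
    )


def variance_partition(
    values: np.ndarray | pd.Series,
    hierarchy: pd.DataFrame,
    levels=("species_id", "population_id", "tree_id"),
) -> pd.Series:
    """Nested sums-of-squares variance decomposition of a leaf-level value.

    ``hierarchy`` holds one nesting column per level, outermost first; the
    residual (within the innermost level) is reported as ``leaf``.  The
    returned fractions are non-negative and sum to 1.
    """
    x = np.asarray(values, float)
    if len(x) != len(hierarchy):
        raise ValueError("values and hierarchy must align")
    total = float(((x - x.mean()) ** 2).sum())
    if total == 0:
        raise ValueError("zero total variance")
    df = hierarchy.copy()
    df["_x"] = x
    fractions = {}
    upper_mean = pd.Series(x.mean(), index=df.index)
    for i, level in enumerate(levels):
        group_cols = list(levels[: i + 1])
        gm = df.groupby(group_cols)["_x"].transform("mean")
        ss = float(((gm - upper_mean) ** 2).sum())
        name = level.replace("_id", "")
        fractions[name] = ss / total
        upper_mean = gm
    fractions["leaf"] = float(((df["_x"] - upper_mean) ** 2).sum()) / total
    return pd.Series(fractions)
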