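"""Connectome-based predictive modeling (CPM) baseline and a ridge baseline.

CPM screens edges by the p-value of their Pearson correlation with the
training outcome (default threshold 0.001), splits surviving edges by
correlation sign, sums each subject's connectivity over the positive and
negative edge sets ("network strengths"), and fits a linear model of the
outcome on the strengths.  Features are the upper triangle of the
symmetric connectivity matrix including the diagonal, flattened row-wise
into a vector of length (V^2 + V) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge, RidgeCV

from .datatypes import ConnectomeSet

__all__ = [
    "EdgeFeatureVector",
    "CpmModel",
    "vectorize_edges",
    "matrix_from_edge_vector",
    "stack_edge_features",
    "cpm_train",
    "cpm_predict",
    "ridge_baseline",
]


@dataclass
class EdgeFeatureVector:
    """Row-wise upper-triangle (with diagonal) flattening of one matrix."""

    values: np.ndarray
    n_nodes: int

    def index_of(self, x: int, y: int) -> int:
        """Flat position of unordered pair (x, y), 0-based, x <= y."""
        x, y = min(x, y), max(x, y)
        v = self.n_nodes
        if not 0 <= x <= y < v:
            raise IndexError("node index out of range")
        # row-major upper triangle: rows 0..x-1 contribute V-i entries each
        return x * v - x * (x - 1) // 2 + (y - x)


def _triu_with_diag(v: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(v, k=0)


def vectorize_edges(mat: np.ndarray, atol: float = 1e-8
                    ) -> EdgeFeatureVector:
    """Flatten a symmetric V x V matrix to its (V^2+V)/2 upper-triangle
    entries (diagonal included), row-wise."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(mat, mat.T, atol=atol, rtol=0.0):
        raise ValueError("input matrix is asymmetric beyond tolerance")
    iu = _triu_with_diag(mat.shape[0])
    return EdgeFeatureVector(mat[iu].copy(), mat.shape[0])


def matrix_from_edge_vector(vec: EdgeFeatureVector) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`."""
    v = vec.n_nodes
    mat = np.zeros((v, v))
    iu = _triu_with_diag(v)
    mat[iu] = vec.values
    mat = mat + mat.T - np.diag(np.diag(mat))
    return mat


def stack_edge_features(C: ConnectomeSet) -> np.ndarray:
    """N x E feature matrix from a connectome stack."""
    iu = _triu_with_diag(C.n_nodes)
    return C.values[:, iu[0], iu[1]].copy()


@dataclass
class CpmModel:
    """Edge sets and the final linear fit of a trained CPM."""

    positive_edges: np.ndarray
    negative_edges: np.ndarray
    coef: np.ndarray                  # aligned with `terms`
    intercept: float
    terms: tuple = ()                 # subset of ("pos", "neg")
    p_threshold: float = 0.001
    empty: bool = False               # no edge survived screening

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in (0, 1]")
        if set(self.positive_edges) & set(self.negative_edges):
            raise ValueError("positive and negative edge sets overlap")


def _edge_correlations(features: np.ndarray, y: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each feature column with y, and two-sided p-values
    from the t transform t = r sqrt((n-2)/(1-r^2))."""
    n = y.size
    yc = y - y.mean()
    fc = features - features.mean(axis=0)
    denom = np.sqrt(np.sum(fc ** 2, axis=0) * np.sum(yc ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, fc.T @ yc / np.where(denom > 0, denom, 1.0),
                     0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def _strengths(features: np.ndarray, model: CpmModel) -> np.ndarray:
    cols = []
    if "pos" in model.terms:
        cols.append(features[:, model.positive_edges].sum(axis=1))
    if "neg" in model.terms:
        cols.append(features[:, model.negative_edges].sum(axis=1))
    return np.column_stack(cols) if cols else np.zeros((features.shape[0], 0))


def cpm_train(features: np.ndarray, y: np.ndarray,
              p_threshold: float = 0.001, mode: str = "two") -> CpmModel:
    """Screen edges on the training set and fit the strength model.

    ``mode="two"`` fits y on (positive strength, negative strength);
    ``mode="difference"`` on the single summary pos - neg.  Constant
    feature columns (e.g., the diagonal self-edges of a correlation-based
    connectome) are dropped with a warning before screening.  If no edge
    survives the threshold the model predicts the training mean and is
    flagged ``empty``.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if features.shape[0] != n:
        raise ValueError("feature rows must match y length")
    if n < 10:
        raise ValueError("need at least 10 training subjects")
    const = np.ptp(features, axis=0) == 0
    if np.any(const):
        warnings.warn(f"dropping {int(const.sum())} constant feature "
                      "column(s) before edge screening", stacklevel=2)
    usable = ~const
    r, p = _edge_correlations(features[:, usable], y)
    idx = np.nonzero(usable)[0]
    if p_threshold >= 1.0:
        survive = np.ones(r.size, dtype=bool)
    else:
        survive = p < p_threshold
    pos = idx[survive & (r > 0)]
    neg = idx[survive & (r < 0)]

    if pos.size == 0 and neg.size == 0:
        return CpmModel(pos, neg, coef=np.zeros(0),
                        intercept=float(y.mean()), terms=(),
                        p_threshold=p_threshold, empty=True)

    if mode == "difference":
        terms: tuple = ("diff",)
        x = (features[:, pos].sum(axis=1)
             - features[:, neg].sum(axis=1))[:, None]
    elif mode == "two":
        terms = tuple(t for t, idx_ in (("pos", pos), ("neg", neg))
                      if idx_.size > 0)
        model_stub = CpmModel(pos, neg, np.zeros(0), 0.0, terms,
                              p_threshold)
        x = _strengths(features, model_stub)
    else:
        raise ValueError("mode must be 'two' or 'difference'")
    xd = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
    return CpmModel(pos, neg, coef=beta[1:], intercept=float(beta[0]),
                    terms=terms, p_threshold=p_threshold)


def cpm_predict(model: CpmModel, features: np.ndarray) -> np.ndarray:
    """Apply strength sums and the stored linear fit; deterministic."""
    features = np.asarray(features, dtype=float)
    if model.empty:
        return np.full(features.shape[0], model.intercept)
    needed = int(max(model.positive_edges.max(initial=-1),
                     model.negative_edges.max(initial=-1)))
    if features.shape[1] <= needed:
        raise ValueError("feature vector shorter than trained edge indices")
    if model.terms == ("diff",):
        x = (features[:, model.positive_edges].sum(axis=1)
             - features[:, model.negative_edges].sum(axis=1))[:, None]
    else:
        x = _strengths(features, model)
    return model.intercept + x @ model.coef


def ridge_baseline(train_features: np.ndarray, y_train: np.ndarray,
                   test_features: np.ndarray,
                   alphas: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
                   cv: int = 5) -> np.ndarray:
    """L2-penalized linear baseline; penalty picked by cross-validation on
    the training set only."""
    alphas = list(alphas)
    if not alphas:
        raise ValueError("penalty grid is empty")
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) feature matrix")
    if len(alphas) == 1:
        est = Ridge(alpha=alphas[0])
    else:
        est = RidgeCV(alphas=alphas, cv=cv)
    est.fit(x, y)
    return est.predict(np.asarray(test_features, dtype=float))
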