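"""NIPALS principal component analysis with cross-validated predictability.

Implements the SIMCA-style workflow: mean-centering and unit-variance scaling
(n−1 denominator), sequential NIPALS extraction with deflation, per-component
and cumulative R²X, and Q² by element-wise deletion cross-validation with
diagonal-striped deletion groups. NIPALS is used (rather than a direct SVD)
because the cross-validation step requires fitting components on matrices
with missing elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "preprocess",
    "NIPALSPCA",
    "q2_cross_validation",
    "Q2Result",
    "group_summary",
]


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        numeric = table.drop(columns=["group"]) if "group" in table.columns else table
        return numeric.to_numpy(dtype=float), list(numeric.columns)
    arr = np.asarray(table, dtype=float)
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def preprocess(table) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-center and unit-variance scale (SD with n−1 denominator).

    Returns (Z, means, sds). A zero-variance column is an error naming the
    column; the transform is invertible as X = Z·diag(sds) + means.
    """
    X, names = _as_matrix(table)
    if X.shape[0] < 2:
        raise ValueError("preprocessing requires at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise ValueError(f"zero-variance column: {names[dead[0]]}")
    return (X - means) / sds, means, sds


def _nipals_component(
    Z: np.ndarray, tol: float, max_iter: int, index: int, strict: bool = True
) -> tuple[np.ndarray, np.ndarray, int]:
    """One NIPALS component; handles missing elements (NaN) by skipping them
    in the score/loading regressions.

    With ``strict=False`` the current component is accepted after ``max_iter``
    iterations instead of raising — used by the cross-validation fits, where
    the iteration can drift arbitrarily slowly inside a near-degenerate noise
    eigenspace while the held-out predictions are already stable."""
    missing = np.isnan(Z)
    has_missing = missing.any()
    if has_missing:
        X0 = np.where(missing, 0.0, Z)
        obs = (~missing).astype(float)
    else:
        X0 = Z
    # start from the column with the largest sum of squares
    t = X0[:, int(np.argmax(np.nansum(X0**2, axis=0)))].copy()
    if not np.any(t):
        t = X0[:, 0] + 1e-12
    for it in range(max_iter):
        if has_missing:
            denom_p = obs.T @ (t**2)
            p = (X0.T @ t) / np.where(denom_p > 0, denom_p, 1.0)
        else:
            p = (X0.T @ t) / (t @ t)
        norm = np.linalg.norm(p)
        if norm == 0:
            raise RuntimeError(f"NIPALS failed on component {index}: zero loading")
        p /= norm
        if has_missing:
            denom_t = obs @ (p**2)
            t_new = (X0 @ p) / np.where(denom_t > 0, denom_t, 1.0)
        else:
            t_new = X0 @ p
        delta = np.linalg.norm(t_new - t)
        t = t_new
        if delta <= tol * max(np.linalg.norm(t), 1e-300):
            return t, p, it + 1
    if not strict:
        return t, p, max_iter
    raise RuntimeError(f"NIPALS did not converge for component {index} after {max_iter} iterations")


def _fix_sign(t: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sign convention: the largest-magnitude loading element is positive."""
    j = int(np.argmax(np.abs(p)))
    if p[j] < 0:
        return -t, -p
    return t, p


class NIPALSPCA(TransformerMixin, BaseEstimator):
    """Principal component analysis by sequential NIPALS (SIMCA-style).

    Parameters
    ----------
    n_components : int, default 2
    center, scale : bool
        Mean-center and unit-variance scale (n−1 SD) before extraction.
    tol : float
        Convergence tolerance on the relative change of the score vector.
    max_iter : int

    Attributes (after ``fit``)
    --------------------------
    mean_, scale_ : ndarray of shape (n_features,)
    scores_ : ndarray of shape (n_samples, n_components)
    loadings_ : ndarray of shape (n_features, n_components), unit-norm columns
    components_ : ndarray of shape (n_components, n_features) — sklearn layout
    r2x_ : per-component fraction of preprocessed variance explained
    r2x_cum_ : cumulative R²X after each component
    n_iter_ : iterations per component
    """

    def __init__(
        self,
        n_components: int = 2,
        center: bool = True,
        scale: bool = True,
        tol: float = 1e-12,
        max_iter: int = 10_000,
    ):
        self.n_components = n_components
        self.center = center
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    def _preprocess_fit(self, table) -> np.ndarray:
        X, names = _as_matrix(table)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = X.shape[1]
        if self.center or self.scale:
            if X.shape[0] < 2:
                raise ValueError("need at least 2 rows")
        self.mean_ = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        if self.scale:
            sds = X.std(axis=0, ddof=1)
            dead = np.flatnonzero(sds == 0)
            if dead.size:
                raise ValueError(f"zero-variance column: {names[dead[0]]}")
            self.scale_ = sds
        else:
            self.scale_ = np.ones(X.shape[1])
        return (X - self.mean_) / self.scale_

    def fit(self, X, y=None) -> "NIPALSPCA":
        Z = self._preprocess_fit(X)
        n, p = Z.shape
        if not 1 <= self.n_components <= min(n, p):
            raise ValueError(f"n_components must be in [1, {min(n, p)}]")
        ss_total = float(np.sum(Z**2))
        R = Z.copy()
        scores, loadings, r2x, n_iter = [], [], [], []
        for a in range(self.n_components):
            t, pvec, iters = _nipals_component(R, self.tol, self.max_iter, a + 1)
            t, pvec = _fix_sign(t, pvec)
            R = R - np.outer(t, pvec)
            scores.append(t)
            loadings.append(pvec)
            n_iter.append(iters)
            r2x.append(1.0 - float(np.sum(R**2)) / ss_total - sum(r2x))
        self.scores_ = np.column_stack(scores)
        self.loadings_ = np.column_stack(loadings)
        self.components_ = self.loadings_.T
        self.r2x_ = np.asarray(r2x)
        self.r2x_cum_ = np.cumsum(self.r2x_)
        self.n_iter_ = np.asarray(n_iter)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "loadings_"):
            raise AttributeError("NIPALSPCA instance is not fitted yet")
        arr, _ = _as_matrix(X)
        return ((arr - self.mean_) / self.scale_) @ self.loadings_

    def inverse_transform(self, T) -> np.ndarray:
        return np.asarray(T) @ self.loadings_.T * self.scale_ + self.mean_


@dataclass(frozen=True)
class Q2Result:
    q2_per_component: np.ndarray
    q2_cumulative: float
    press: np.ndarray
    ss: np.ndarray


def _deletion_groups(shape: tuple[int, int], n_groups: int, offset: int) -> np.ndarray:
    i, j = np.indices(shape)
    return (i + j + offset) % n_groups


def q2_cross_validation(
    table,
    n_components: int = 2,
    n_groups: int = 7,
    seed: int | None = None,
    center: bool = True,
    scale: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> Q2Result:
    """Cross-validated predictability Q² by element-wise deletion.

    Matrix elements are assigned to ``n_groups`` diagonal-striped deletion
    groups (the stripe offset is rotated deterministically by ``seed``). For
    each component, each group of elements is deleted in turn, a NIPALS
    component is fitted with missing-data handling on the current residual
    matrix, and the deleted elements are predicted as t·pᵀ. Q²_a = 1 −
    PRESS_a/SS_a; the cumulative Q² over A components is 1 − Π_a PRESS_a/SS_a.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    X, names = _as_matrix(table)
    if center or scale:
        Z, _, _ = preprocess(X) if (center and scale) else (None, None, None)
        if Z is None:  # pragma: no cover - center/scale used together in practice
            mu = X.mean(axis=0) if center else 0.0
            sd = X.std(axis=0, ddof=1) if scale else 1.0
            Z = (X - mu) / sd
    else:
        Z = X.astype(float)
    groups = _deletion_groups(Z.shape, n_groups, 0 if seed is None else int(seed) % n_groups)
    # every row and column must keep at least one observed element per group
    for g in range(n_groups):
        deleted = groups == g
        if deleted.all(axis=1).any() or deleted.all(axis=0).any():
            warnings.warn(
                f"deletion group {g} removes an entire row/column; reassigning", stacklevel=2
            )
            sel = deleted.all(axis=1)
            groups[sel, 0] = (g + 1) % n_groups
            sel = (groups == g).all(axis=0)
            groups[0, sel] = (g + 1) % n_groups
    R = Z.copy()
    press = np.empty(n_components)
    ss = np.empty(n_components)
    for a in range(n_components):
        ss[a] = float(np.sum(R**2))
        pr = 0.0
        for g in range(np.max(groups) + 1):
            deleted = groups == g
            if not deleted.any():
                continue
            work = R.copy()
            work[deleted] = np.nan
            t, p, _ = _nipals_component(work, tol, max_iter, a + 1, strict=False)
            pred = np.outer(t, p)
            pr += float(np.sum((R[deleted] - pred[deleted]) ** 2))
        press[a] = pr
        # deflate with the full-data component for the next round
        t, p, _ = _nipals_component(R, tol, max_iter, a + 1, strict=False)
        R = R - np.outer(t, p)
    q2 = 1.0 - press / ss
    q2_cum = 1.0 - float(np.prod(press / ss))
    return Q2Result(q2_per_component=q2, q2_cumulative=q2_cum, press=press, ss=ss)


def group_summary(scores: np.ndarray, groups) -> pd.DataFrame:
    """Per-group mean and SD of component scores.

    Single-subject groups get SD 0 with ``single_subject=True`` so callers can
    flag rather than drop them.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(list(groups))
    if labels.shape[0] != scores.shape[0]:
        raise ValueError("one group label per score row is required")
    rows = []
    for g in pd.unique(labels):
        sel = labels == g
        if not sel.any():
            raise ValueError(f"empty group {g}")
        block = scores[sel]
        single = block.shape[0] == 1
        sd = np.zeros(block.shape[1]) if single else block.std(axis=0, ddof=1)
        for comp in range(block.shape[1]):
            rows.append(
                {
                    "group": g,
                    "component": comp + 1,
                    "mean": float(block[:, comp].mean()),
                    "sd": float(sd[comp]),
                    "n": int(sel.sum()),
                    "single_subject": single,
                }
            )
    return pd.DataFrame(rows)
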