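"""Fingerprint mining: unit-variance scaling, PCA and OPLS with S-line output.

Estimators follow scikit-learn conventions (``fit``/``transform``,
``get_params``, fitted attributes with trailing underscores) and compose
with sklearn pipelines.  Sign conventions are fixed for determinism: each
PCA loading vector has its largest-magnitude element positive, and the
OPLS predictive score is oriented so the +1 class has positive mean score
(so a positive S-line covariance means "elevated in the +1 class").

OPLS here is the two-class discriminant variant: y is a +-1 dummy vector;
orthogonal-to-y variation is stripped by Trygg-Wold orthogonal signal
correction before a single predictive PLS component is extracted.  The
orthogonal scores are exactly uncorrelated with y by construction.  The
S-line reports, per variable, the covariance and correlation of the
(scaled) variable with the predictive score -- the standard biomarker
ranking display for spectroscopic fingerprints.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["UnitVarianceScaler", "PCAFingerprint", "OPLS", "uv_scale", "s_line"]


class UnitVarianceScaler(BaseEstimator, TransformerMixin):
    """Column-wise centring and unit-variance (sd, n-1 denominator) scaling.

    Zero-variance columns are centred but left with scale 1 and flagged in
    ``constant_mask_`` instead of producing NaNs.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        self.means_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.constant_mask_ = sd == 0
        self.scales_ = np.where(self.constant_mask_, 1.0, sd)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.means_) / self.scales_

    def inverse_transform(self, X):
        return np.asarray(X, dtype=float) * self.scales_ + self.means_


def uv_scale(X) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Functional wrapper: scaled matrix plus (means, scales)."""
    sc = UnitVarianceScaler().fit(X)
    return sc.transform(X), (sc.means_, sc.scales_)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| element positive."""
    flips = np.ones(loadings.shape[1])
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            flips[k] = -1.0
    return flips


class PCAFingerprint(BaseEstimator, TransformerMixin):
    """PCA via SVD of an already-scaled matrix, with deterministic signs.

    Attributes after ``fit``: ``loadings_`` (variables x components,
    orthonormal columns), ``scores_`` (samples x components),
    ``explained_variance_ratio_``.  Requesting more components than the
    matrix rank truncates with a warning.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
        rank = int((s > tol).sum())
        k = self.n_components
        if k > rank:
            warnings.warn(
                f"requested {k} components but rank is {rank}; truncating",
                stacklevel=2,
            )
            k = rank
        flips = _fix_signs(Vt[:k].T)
        self.loadings_ = Vt[:k].T * flips
        self.scores_ = U[:, :k] * s[:k] * flips
        total_var = float((s ** 2).sum())
        self.explained_variance_ratio_ = s[:k] ** 2 / total_var
        self.singular_values_ = s[:k]
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float) @ self.loadings_

    def inverse_transform(self, T):
        return np.asarray(T, dtype=float) @ self.loadings_.T


class OPLS(BaseEstimator):
    """Two-class OPLS-DA on a scaled matrix with a +-1 dummy response.

    Parameters
    ----------
    n_orthogonal : int
        Number of y-orthogonal components removed before the single
        predictive component (0 reduces to one-component PLS).

    Attributes after ``fit``: ``weights_`` (predictive weight vector),
    ``scores_`` (predictive score t_p), ``loadings_``,
    ``orthogonal_scores_`` / ``orthogonal_loadings_`` /
    ``orthogonal_weights_``, ``r2x_`` (per component, orthogonal then
    predictive), ``r2y_``.
    """

    def __init__(self, n_orthogonal: int = 1):
        self.n_orthogonal = n_orthogonal

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("y must be a two-level +-1 dummy variable")
        yc = y - y.mean()
        ss_x = float((X ** 2).sum())
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("y carries no covariance with any variable")
        w /= nw

        Xd = X.copy()
        t_os, p_os, w_os, r2x = [], [], [], []
        for _ in range(self.n_orthogonal):
            t = Xd @ w
            p = Xd.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            n_o = np.linalg.norm(w_o)
            if n_o < 1e-12:
                break
            w_o /= n_o
            t_o = Xd @ w_o
            p_o = Xd.T @ t_o / (t_o @ t_o)
            Xd = Xd - np.outer(t_o, p_o)
            t_os.append(t_o)
            p_os.append(p_o)
            w_os.append(w_o)
            r2x.append(float((t_o @ t_o) * (p_o @ p_o)) / ss_x)

        t_p = Xd @ w
        # orient so the +1-coded (larger) class has positive mean score
        hi = classes.max()
        if t_p[y == hi].mean() < 0:
            w, t_p = -w, -t_p
        p_p = Xd.T @ t_p / (t_p @ t_p)
        q = (yc @ t_p) / (t_p @ t_p)
        y_hat = t_p * q
        self.weights_ = w
        self.scores_ = t_p
        self.loadings_ = p_p
        self.coef_q_ = q
        self.orthogonal_scores_ = (
            np.column_stack(t_os) if t_os else np.empty((len(y), 0))
        )
        self.orthogonal_loadings_ = (
            np.column_stack(p_os) if p_os else np.empty((X.shape[1], 0))
        )
        self.orthogonal_weights_ = (
            np.column_stack(w_os) if w_os else np.empty((X.shape[1], 0))
        )
        self.r2x_ = np.array(r2x + [float((t_p @ t_p) * (p_p @ p_p)) / ss_x])
        self.r2y_ = 1.0 - float(((yc - y_hat) ** 2).sum()) / float((yc ** 2).sum())
        self.y_mean_ = y.mean()
        self.classes_ = classes
        return self

    def predict_score(self, X):
        Xd = np.asarray(X, dtype=float)
        for k in range(self.orthogonal_weights_.shape[1]):
            t_o = Xd @ self.orthogonal_weights_[:, k]
            Xd = Xd - np.outer(t_o, self.orthogonal_loadings_[:, k])
        return Xd @ self.weights_


def s_line(model: OPLS, X, columns=None) -> pd.DataFrame:
    """Per-variable (covariance, correlation) with the predictive score.

    Positive values mark variables elevated in the +1 class.  Constant
    variables get correlation 0 with a flag instead of NaN.
    """
    X = np.asarray(X, dtype=float)
    t = model.scores_
    n = len(t)
    xc = X - X.mean(axis=0)
    tc = t - t.mean()
    cov = xc.T @ tc / (n - 1)
    sx = X.std(axis=0, ddof=1)
    st = t.std(ddof=1)
    constant = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(constant, 0.0, cov / np.where(constant, 1.0, sx) / st)
    out = pd.DataFrame(
        {"p_cov": cov, "p_corr": corr, "constant_flag": constant}
    )
    if columns is not None:
        out.index = list(columns)
    return out
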