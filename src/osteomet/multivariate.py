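"""Principal component analysis and two-class PLS-DA with VIP scores.

Both decompositions are implemented here directly (SVD for PCA, sequential
NIPALS extraction for PLS) because variable-importance-in-projection ranking
against a class label is the selection engine of the whole pipeline and its
numerical conventions need to be pinned down:

* features are mean-centred and, for PLS-DA, scaled to unit variance
  (ddof=1) by default;
* the two-class response is a single centred 0/1 dummy column (PLS1) —
  equivalent to a two-column indicator for two classes and giving the
  simpler VIP formula;
* sign indeterminacy is resolved by flipping each component so that its
  largest-magnitude weight entry is positive, making outputs deterministic;
* VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ) with SS_a the response
  variance captured by component a and unit-norm weight vectors, so
  mean(VIP^2) = 1 identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PlsModel", "fit_plsda", "vip", "fit_pca", "PcaModel"]

_ORTHO_TOL = 1e-8


@dataclass
class PlsModel:
    """Fitted two-class PLS-DA (PLS1) model."""

    n_components: int
    x_weights: np.ndarray      # (p, A), unit-norm columns
    x_loadings: np.ndarray     # (p, A)
    x_scores: np.ndarray       # (n, A), mutually orthogonal columns
    y_loadings: np.ndarray     # (A,)
    explained_y: np.ndarray    # (A,) response sum-of-squares per component
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    classes: tuple
    feature_names: list = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new samples onto the score space (same preprocessing)."""
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        # R = W (P'W)^-1 gives scores directly from undeflated X
        R = self.x_weights @ np.linalg.inv(self.x_loadings.T @ self.x_weights)
        return Xc @ R

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous class score (predicted centred dummy response)."""
        return self.transform(X) @ self.y_loadings

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels (threshold at the centred midpoint)."""
        yhat = self.decision_scores(X) + self.y_mean
        return np.where(yhat >= 0.5, self.classes[1], self.classes[0])


def _as_two_class_dummy(labels) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = tuple(sorted(pd.unique(labels).tolist()))
    if len(classes) != 2:
        raise ValueError(f"PLS-DA requires exactly two classes, got {classes}")
    y = (labels == classes[1]).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    return y, classes


def fit_plsda(X, labels, n_components: int = 2, scale: bool = True,
              feature_names=None) -> PlsModel:
    """Fit a two-class PLS-DA model by sequential NIPALS extraction.

    Parameters
    ----------
    X:
        (n_samples, n_features) data matrix.
    labels:
        Two-class label vector; classes are ordered lexically and the second
        class is coded 1.
    n_components:
        Number of latent components (default 2, the conventional default of
        discriminant-PLS implementations).
    scale:
        Standardize features to unit variance (default) in addition to
        centering.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, p = X.shape
    y, classes = _as_two_class_dummy(labels)
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components={n_components} outside "
                         f"[1, {min(n - 1, p)}]")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    zero_var = ~(x_scale > 0)
    if zero_var.any():
        idx = int(np.argmax(zero_var))
        name = feature_names[idx] if feature_names is not None else idx
        raise ValueError(f"zero-variance feature {name!r}; remove constant "
                         "features before PLS-DA")
    Xc = (X - x_mean) / x_scale
    y_mean = y.mean()
    yc = y - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    T = np.empty((n, n_components))
    q = np.empty(n_components)
    ss = np.empty(n_components)

    Xd = Xc.copy()
    for a in range(n_components):
        # PLS1: the NIPALS inner loop converges in one pass
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm <= 0:
            raise ValueError(f"component {a + 1}: response is orthogonal to "
                             "the remaining X variation")
        w /= norm
        # deterministic sign: largest-|w| entry positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            raise ValueError(f"component {a + 1} has zero score variance")
        pvec = Xd.T @ t / tt
        qa = float(yc @ t) / tt
        Xd -= np.outer(t, pvec)
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        ss[a] = qa * qa * tt  # response sum of squares captured

    # orthogonality sanity on extracted scores
    G = T.T @ T
    off = np.abs(G - np.diag(np.diag(G))).max() if n_components > 1 else 0.0
    if off > _ORTHO_TOL * max(1.0, np.abs(np.diag(G)).max()):
        raise RuntimeError("extracted score vectors lost orthogonality")

    model = PlsModel(
        n_components=n_components, x_weights=W, x_loadings=P, x_scores=T,
        y_loadings=q, explained_y=ss, x_mean=x_mean, x_scale=x_scale,
        y_mean=float(y_mean), classes=classes,
        feature_names=list(feature_names) if feature_names is not None else [],
    )
    return model


def vip(model: PlsModel) -> pd.Series:
    """Variable importance in projection of a fitted PLS-DA model.

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ); the
    weights are unit-norm already, so mean(VIP^2) = 1 exactly (asserted).
    """
    ss = model.explained_y
    total = ss.sum()
    if not total > 0:
        raise ValueError("model explains zero response variance; VIP is "
                         "undefined")
    p = model.x_weights.shape[0]
    v = np.sqrt(p * (model.x_weights ** 2 @ ss) / total)
    mean_sq = float(np.mean(v ** 2))
    if abs(mean_sq - 1.0) > 1e-8:
        raise AssertionError(f"VIP normalization violated: mean(VIP^2)="
                             f"{mean_sq}")
    index = model.feature_names if model.feature_names else range(p)
    return pd.Series(v, index=index, name="VIP")


@dataclass
class PcaModel:
    """Principal component analysis via singular value decomposition."""

    scores: np.ndarray             # (n, A)
    loadings: np.ndarray           # (p, A), orthonormal columns
    explained_fraction: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray


def fit_pca(X, n_components: int | None = None, scale: bool = False
            ) -> PcaModel:
    """PCA of a samples x features matrix (centred; scaling optional).

    Components are ordered by decreasing explained variance; each loading
    vector's largest-magnitude entry is made positive so output is
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    if scale and not (x_scale > 0).all():
        raise ValueError("zero-variance feature; cannot scale")
    Xc = (X - x_mean) / x_scale
    if not np.any(Xc):
        raise ValueError("input is constant; PCA is undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    max_rank = min(n - 1, p)
    k = max_rank if n_components is None else n_components
    if not 1 <= k <= max_rank:
        raise ValueError(f"n_components={n_components} outside [1, {max_rank}]")
    # sign convention
    for a in range(k):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    var = s ** 2 / (n - 1)
    frac = var / var.sum()
    return PcaModel(scores=U[:, :k] * s[:k], loadings=Vt[:k].T,
                    explained_fraction=frac[:k], x_mean=x_mean,
                    x_scale=x_scale)
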