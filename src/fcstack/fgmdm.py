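"""Fisher's Geodesic Minimum Distance to Mean (FgMDM) classifier.

The classifier operates directly on SPD connectivity matrices:

1. compute the (weighted) manifold mean of the training matrices and map
   every sample to the tangent space at that reference point;
2. apply Fisher's Discriminant Analysis in tangent space, keeping the
   ``n_classes - 1`` discriminant directions, and reconstruct each tangent
   vector from its projection onto that subspace (geodesic filtering);
3. map the filtered vectors back onto the manifold and recompute the class
   means there;
4. classify new samples by distance to the nearest class mean, with
   probabilities given by a softmax over negative squared distances.

The within-class scatter is shrunk toward a scaled identity
(``(1 - shrinkage) * Sw + shrinkage * tr(Sw)/d * I``) because the tangent
dimension n(n+1)/2 typically exceeds the number of training subjects.
Sample weights (conventionally the inverse epoch count per subject)
propagate into the reference mean, the scatter matrices, and the class means.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import spd


class FgMDM(ClassifierMixin, BaseEstimator):
    """Geodesically filtered minimum-distance-to-mean classifier on SPD data.

    Parameters
    ----------
    metric : {"affine_riemannian", "log_euclidean", "euclidean"}
        SPD geometry used for the mean, tangent projection, and distances.
    shrinkage : float in [0, 1]
        Shrinkage intensity of the within-class scatter toward the scaled
        identity.
    eps : float
        SPD eigenvalue floor applied to reconstructed matrices.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    reference_ : ndarray (n, n)
        Manifold mean of the training set (tangent base point).
    filter_basis_ : ndarray (d, n_classes - 1)
        Orthonormal basis of the discriminant subspace in tangent space.
    class_means_ : ndarray (n_classes, n, n)
        Manifold means of the filtered training samples per class.
    """

    def __init__(self, metric="log_euclidean", shrinkage=0.1, eps=1e-10):
        self.metric = metric
        self.shrinkage = shrinkage
        self.eps = eps

    # ------------------------------------------------------------------ fit

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(f"X must be (n_samples, n, n) SPD matrices, got {X.shape}")
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("FgMDM requires at least 2 classes")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 training samples")
        n = X.shape[0]
        if sample_weight is None:
            w = np.full(n, 1.0 / n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("invalid sample_weight")
            w = w / w.sum()

        self.classes_ = classes
        self.reference_ = spd.manifold_mean(X, w, self.metric)
        V = spd.tangent_map(X, self.reference_, self.metric)  # (n, d)
        self.filter_basis_ = self._fda_basis(V, y_idx, w, len(classes))

        # geodesic filtering: reconstruct from the discriminant subspace
        Vf = V @ self.filter_basis_ @ self.filter_basis_.T
        Xf = spd.nearest_spd(
            spd.inverse_tangent_map(Vf, self.reference_, self.metric), eps=self.eps
        )
        self.class_means_ = np.stack(
            [
                spd.manifold_mean(Xf[y_idx == k], w[y_idx == k], self.metric)
                for k in range(len(classes))
            ]
        )
        return self

    def _fda_basis(
        self, V: np.ndarray, y_idx: np.ndarray, w: np.ndarray, n_classes: int
    ) -> np.ndarray:
        d = V.shape[1]
        grand = w @ V
        Sb = np.zeros((d, d))
        Sw = np.zeros((d, d))
        for k in range(n_classes):
            mask = y_idx == k
            wk = w[mask]
            Wk = wk.sum()
            mk = (wk @ V[mask]) / Wk
            dk = mk - grand
            Sb += Wk * np.outer(dk, dk)
            Dk = V[mask] - mk
            Sw += (Dk * wk[:, None]).T @ Dk
        gamma = float(self.shrinkage)
        Sw = (1.0 - gamma) * Sw + gamma * (np.trace(Sw) / d) * np.eye(d)
        # guard exactly singular scatter (e.g. shrinkage=0 with few samples)
        Sw += 1e-12 * np.trace(Sw) / d * np.eye(d)
        evals, evecs = linalg.eigh(Sb, Sw)
        W = evecs[:, np.argsort(evals)[::-1][: n_classes - 1]]
        Q, _ = np.linalg.qr(W)
        return Q

    # ------------------------------------------------------------- predict

    def _filter(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[-1] != self.reference_.shape[-1]:
            raise ValueError(
                f"matrix dimension {X.shape[-1]} does not match training "
                f"dimension {self.reference_.shape[-1]}"
            )
        V = spd.tangent_map(X, self.reference_, self.metric)
        Vf = V @ self.filter_basis_ @ self.filter_basis_.T
        return spd.nearest_spd(
            spd.inverse_tangent_map(Vf, self.reference_, self.metric), eps=self.eps
        )

    def transform(self, X) -> np.ndarray:
        """Geodesically filtered SPD matrices (the FDA reconstruction)."""
        check_is_fitted(self, "class_means_")
        return self._filter(X)

    def decision_distances(self, X) -> np.ndarray:
        """Distances of each (filtered) sample to every class mean."""
        check_is_fitted(self, "class_means_")
        Xf = self._filter(X)
        return spd.pairwise_distances(Xf, self.class_means_, self.metric)

    def predict_proba(self, X) -> np.ndarray:
        """Softmax over negative squared distances to the class means."""
        d2 = self.decision_distances(X) ** 2
        z = -d2 + d2.min(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        d = self.decision_distances(X)
        return self.classes_[np.argmin(d, axis=1)]
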