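"""Geometry of symmetric positive-definite (SPD) matrices.

Connectivity matrices live on the SPD cone, and the base classifiers compare
them with one of three geometries:

- ``affine_riemannian``: the affine-invariant metric,
  d_R(C1, C2) = || log(C1^{-1/2} C2 C1^{-1/2}) ||_F, whose Frechet mean is the
  Karcher mean;
- ``log_euclidean``: d_L(C1, C2) = || log C2 - log C1 ||_F, with the exp of
  the arithmetic mean of logs as its mean;
- ``euclidean``: the flat Frobenius distance with the arithmetic mean.

Tangent vectors use the half-vectorization with off-diagonal entries scaled
by sqrt(2), so the Euclidean norm of a tangent vector equals the manifold
distance to the reference point for every metric.

All matrix functions (log, exp, square root) act through batched symmetric
eigendecompositions, so stacks of matrices are processed without Python loops.
"""

from __future__ import annotations

import numpy as np

METRICS = ("affine_riemannian", "log_euclidean", "euclidean")

_DEFAULT_EPS = 1e-10


def _check_metric(metric: str) -> str:
    if metric not in METRICS:
        raise ValueError(f"unknown SPD metric {metric!r}; choose from {METRICS}")
    return metric


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + np.swapaxes(M, -1, -2))


def _apply_eig(C: np.ndarray, fn, *, spd_required: bool = False) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of symmetric matrices."""
    C = np.asarray(C, dtype=float)
    w, V = np.linalg.eigh(_sym(C))
    if spd_required and np.any(w <= 0):
        raise np.linalg.LinAlgError(
            f"matrix is not positive definite (min eigenvalue {w.min():.3e})"
        )
    return _sym((V * fn(w)[..., None, :]) @ np.swapaxes(V, -1, -2))


def logm(C: np.ndarray) -> np.ndarray:
    """Matrix logarithm of SPD matrices (batched)."""
    return _apply_eig(C, np.log, spd_required=True)


def expm(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of symmetric matrices (batched)."""
    return _apply_eig(S, np.exp)


def sqrtm(C: np.ndarray) -> np.ndarray:
    """Principal square root of SPD matrices (batched)."""
    return _apply_eig(C, np.sqrt, spd_required=True)


def invsqrtm(C: np.ndarray) -> np.ndarray:
    """Inverse principal square root of SPD matrices (batched)."""
    return _apply_eig(C, lambda w: 1.0 / np.sqrt(w), spd_required=True)


def is_spd(C: np.ndarray, eps: float = _DEFAULT_EPS, rtol: float = 1e-8) -> bool:
    """True if ``C`` is symmetric within ``rtol`` and min eigenvalue >= eps.

    The eigenvalue floor is checked up to the reconstruction round-off of an
    eigen-clipped matrix (absolute slack ``1e-12 * scale``).
    """
    C = np.asarray(C, dtype=float)
    if C.shape[-1] != C.shape[-2]:
        return False
    scale = max(np.abs(C).max(), 1.0)
    if not np.allclose(C, np.swapaxes(C, -1, -2), atol=rtol * scale):
        return False
    w = np.linalg.eigvalsh(_sym(C))
    return bool(np.all(w >= eps - 1e-12 * scale))


def nearest_spd(M: np.ndarray, eps: float = _DEFAULT_EPS) -> np.ndarray:
    """Project a square matrix onto the SPD cone (Higham-style eigenvalue clip).

    The symmetric part of ``M`` is eigendecomposed and eigenvalues below
    ``eps`` are raised to ``eps``.  For symmetric input and ``eps=0`` this is
    the Frobenius-nearest positive semidefinite matrix.  Matrices that already
    satisfy the SPD constraint are returned unchanged up to symmetrization.

    Parameters
    ----------
    M : ndarray, shape (..., n, n)
        Square (stack of) matrices.
    eps : float
        Eigenvalue floor; default 1e-10.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[-1] != M.shape[-2]:
        raise ValueError(f"nearest_spd requires square input, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError("nearest_spd requires finite input")
    B = _sym(M)
    w, V = np.linalg.eigh(B)
    if np.all(w >= eps):
        return B
    w = np.maximum(w, eps)
    return _sym((V * w[..., None, :]) @ np.swapaxes(V, -1, -2))


def spd_distance(C1: np.ndarray, C2: np.ndarray, metric: str) -> float:
    """Distance between two SPD matrices under the chosen geometry.

    ``euclidean`` accepts any symmetric matrices; the log-based metrics
    require SPD input and raise ``LinAlgError`` otherwise.
    """
    _check_metric(metric)
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    if C1.shape != C2.shape:
        raise ValueError(f"shape mismatch: {C1.shape} vs {C2.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(C2 - C1))
    if metric == "log_euclidean":
        return float(np.linalg.norm(logm(C2) - logm(C1)))
    W = invsqrtm(C1)
    return float(np.linalg.norm(logm(W @ C2 @ W)))


def manifold_mean(
    Cs: np.ndarray,
    weights: np.ndarray | None = None,
    metric: str = "affine_riemannian",
    *,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Weighted mean of SPD matrices under the chosen geometry.

    - euclidean: weighted arithmetic mean;
    - log_euclidean: exp of the weighted mean of matrix logs;
    - affine_riemannian: weighted Karcher mean by fixed-point iteration,
      initialized at the log-Euclidean mean, stopping when the Frobenius norm
      of the tangent-space gradient drops below ``tol`` (or ``max_iter``).
    """
    _check_metric(metric)
    Cs = np.asarray(Cs, dtype=float)
    if Cs.ndim == 2:
        Cs = Cs[None]
    if Cs.shape[0] == 0:
        raise ValueError("manifold_mean of an empty set")
    n = Cs.shape[0]
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError(f"weights shape {w.shape} does not match {n} matrices")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    if metric == "euclidean":
        return _sym(np.tensordot(w, Cs, axes=1))

    logs = logm(Cs)
    le_mean = expm(np.tensordot(w, logs, axes=1))
    if metric == "log_euclidean":
        return le_mean

    M = le_mean
    for _ in range(max_iter):
        iM = invsqrtm(M)
        sM = sqrtm(M)
        # tangent-space gradient at M: weighted mean of log(M^-1/2 C M^-1/2)
        T = np.tensordot(w, logm(iM @ Cs @ iM), axes=1)
        grad = float(np.linalg.norm(T))
        if grad < tol:
            break
        M = sM @ expm(T) @ sM
    return _sym(M)


def _triu_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n)


def vec_sym(S: np.ndarray) -> np.ndarray:
    """Half-vectorize symmetric matrices with sqrt(2)-scaled off-diagonals.

    The scaling makes the Euclidean norm of the vector equal the Frobenius
    norm of the matrix.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[-1]
    iu, ju = _triu_indices(n)
    scale = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return S[..., iu, ju] * scale


def unvec_sym(v: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vec_sym`."""
    v = np.asarray(v, dtype=float)
    iu, ju = _triu_indices(n)
    scale = np.where(iu == ju, 1.0, np.sqrt(2.0))
    S = np.zeros(v.shape[:-1] + (n, n))
    S[..., iu, ju] = v / scale
    S[..., ju, iu] = S[..., iu, ju]
    return S


def tangent_map(C: np.ndarray, reference: np.ndarray, metric: str) -> np.ndarray:
    """Map SPD matrices to tangent vectors at ``reference``.

    The vectorization is isometric: ``norm(tangent_map(C, R, m)) ==
    spd_distance(C, R, m)`` for every metric.
    """
    _check_metric(metric)
    C = np.asarray(C, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if C.shape[-1] != reference.shape[-1]:
        raise ValueError(
            f"dimension mismatch: matrices are {C.shape[-1]}x{C.shape[-1]}, "
            f"reference is {reference.shape[-1]}x{reference.shape[-1]}"
        )
    if metric == "euclidean":
        S = C - reference
    elif metric == "log_euclidean":
        S = logm(C) - logm(reference)
    else:
        W = invsqrtm(reference)
        S = logm(W @ C @ W)
    return vec_sym(S)


def inverse_tangent_map(
    v: np.ndarray, reference: np.ndarray, metric: str
) -> np.ndarray:
    """Map tangent vectors at ``reference`` back to the SPD manifold."""
    _check_metric(metric)
    reference = np.asarray(reference, dtype=float)
    n = reference.shape[-1]
    S = unvec_sym(v, n)
    if metric == "euclidean":
        return reference + S
    if metric == "log_euclidean":
        return expm(logm(reference) + S)
    R = sqrtm(reference)
    return R @ expm(S) @ R


def pairwise_distances(
    Cs: np.ndarray, refs: np.ndarray, metric: str
) -> np.ndarray:
    """Distances from each matrix in ``Cs`` to each matrix in ``refs``.

    Returns an (n_samples, n_refs) array.  Log-based metrics reuse a single
    eigendecomposition per matrix.
    """
    _check_metric(metric)
    Cs = np.asarray(Cs, dtype=float)
    refs = np.asarray(refs, dtype=float)
    if Cs.ndim == 2:
        Cs = Cs[None]
    if refs.ndim == 2:
        refs = refs[None]
    if metric == "euclidean":
        diff = Cs[:, None] - refs[None]
        return np.linalg.norm(diff, axis=(-2, -1))
    if metric == "log_euclidean":
        diff = logm(Cs)[:, None] - logm(refs)[None]
        return np.linalg.norm(diff, axis=(-2, -1))
    out = np.empty((Cs.shape[0], refs.shape[0]))
    for j in range(refs.shape[0]):
        W = invsqrtm(refs[j])
        out[:, j] = np.linalg.norm(logm(W @ Cs @ W), axis=(-2, -1))
    return out
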