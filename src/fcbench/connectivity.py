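"""Functional-connectivity estimation: Pearson, partial, graphical lasso,
tangent-space parametrization, and edge vectorization.

All four measures operate on (shrinkage-regularized) covariance matrices of
cleaned ROI time series.  The tangent-space measure is the only one with a
train/test contract: its reference point (the affine-invariant Frechet mean
of the training covariances) must be fitted on training scans only, and the
fitted :class:`TangentReference` records the scan ids it saw so leakage can
be audited downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import LedoitWolf


# ---------------------------------------------------------------------------
# Symmetric-matrix helpers
# ---------------------------------------------------------------------------

def _eigh_fun(M: np.ndarray, fun, floor: float | None = None) -> np.ndarray:
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    if floor is not None:
        if (w < floor).any():
            warnings.warn("eigenvalue floored during matrix function",
                          stacklevel=3)
        w = np.maximum(w, floor)
    return (V * fun(w)) @ V.T


def logm_spd(M: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    return _eigh_fun(M, np.log, floor=floor)


def expm_sym(M: np.ndarray) -> np.ndarray:
    return _eigh_fun(M, np.exp)


def powm_spd(M: np.ndarray, p: float) -> np.ndarray:
    return _eigh_fun(M, lambda w: w**p, floor=1e-14)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Symmetric R x R FC estimate.

    Diagonal conventions: 1 for Pearson, 0 for partial/glasso (partial
    correlations), log-eigenvalue scale for tangent (unbounded).
    """

    values: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if not np.isfinite(v).all():
            raise ValueError("non-finite FC entries")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValueError("FC matrix not symmetric within 1e-10")
        self.values = (v + v.T) / 2.0

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class TangentReference:
    """Fitted tangent-space reference point with provenance.

    ``whitening`` is G^(-1/2) for the Frechet mean G; ``train_scan_ids``
    records exactly which scans the mean was fitted on.
    """

    reference_mean: np.ndarray
    whitening: np.ndarray
    train_scan_ids: tuple[str, ...] = field(default_factory=tuple)
    n_iterations: int = 0


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def estimate_covariance(Y: np.ndarray, shrinkage: str = "ledoit_wolf") -> np.ndarray:
    """SPD covariance of a T x R cleaned time-series matrix.

    Default is Ledoit-Wolf shrinkage toward a scaled identity with the
    analytic intensity; ``shrinkage="empirical"`` returns the plain sample
    covariance (not guaranteed well-conditioned).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] <= 3:
        raise ValueError("need a T x R matrix with T > 3")
    sd = Y.std(axis=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant time series in region(s) {bad}")
    if shrinkage == "ledoit_wolf":
        cov = LedoitWolf(assume_centered=False).fit(Y).covariance_
    elif shrinkage == "empirical":
        cov = np.cov(Y, rowvar=False)
    else:
        raise ValueError(f"unknown shrinkage {shrinkage!r}")
    cov = (cov + cov.T) / 2.0
    lam_min = np.linalg.eigvalsh(cov)[0]
    if lam_min <= 0:  # jitter fallback, only reachable for empirical covariance
        cov += (1e-10 - lam_min) * np.eye(cov.shape[0])
    return cov


def pearson_fc(Y: np.ndarray) -> ConnectivityMatrix:
    """Pearson correlation of ROI time-series columns; unit diagonal."""
    Y = np.asarray(Y, dtype=float)
    if (Y.std(axis=0) == 0).any():
        bad = np.flatnonzero(Y.std(axis=0) == 0).tolist()
        raise ValueError(f"constant time series in region(s) {bad}")
    return ConnectivityMatrix(np.corrcoef(Y, rowvar=False), "pearson")


def cov_to_correlation(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def partial_fc(cov: np.ndarray) -> ConnectivityMatrix:
    """Partial correlations from the precision matrix; zero diagonal.

    partial_ij = -P_ij / sqrt(P_ii P_jj) with P = cov^-1.
    """
    cov = np.asarray(cov, dtype=float)
    if np.linalg.cond(cov) > 1e12:
        raise ValueError("covariance is near-singular (cond > 1e12); "
                         "use a shrinkage estimator first")
    return ConnectivityMatrix(_precision_to_partial(np.linalg.inv(cov)), "partial")


def _precision_to_partial(P: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(P))
    out = -P / np.outer(d, d)
    np.fill_diagonal(out, 0.0)
    return out


def graphical_lasso_admm(S: np.ndarray, alpha: float, rho: float = 1.0,
                         max_iter: int = 2000, tol: float = 1e-9) -> np.ndarray:
    """Sparse precision estimate by ADMM on the penalized log-det program.

        minimize  -logdet(P) + tr(S P) + alpha * ||P||_1,off

    The off-diagonal L1 penalty matches the partial-correlation use of the
    estimate (the diagonal is never shrunk).  Splitting P = Z gives a
    closed-form eigenvalue update for P and elementwise soft-thresholding
    for Z; iterations stop when primal and dual residuals drop below
    ``tol`` (Frobenius, relative to the problem size).  Converged solutions
    satisfy the stationarity system to well below 1e-4.
    """
    S = np.asarray(S, dtype=float)
    R = S.shape[0]
    Z = np.diag(1.0 / np.diag(S))
    U = np.zeros_like(S)
    off = ~np.eye(R, dtype=bool)
    for it in range(max_iter):
        # P-step: eigen solve of rho (Z - U) - S
        w, V = np.linalg.eigh(rho * (Z - U) - S)
        p_eig = (w + np.sqrt(w**2 + 4 * rho)) / (2 * rho)
        P = (V * p_eig) @ V.T
        # Z-step: soft-threshold off-diagonal entries
        Q = P + U
        Z_new = Q.copy()
        Z_new[off] = np.sign(Q[off]) * np.maximum(np.abs(Q[off]) - alpha / rho, 0.0)
        dual = rho * np.linalg.norm(Z_new - Z)
        Z = Z_new
        U = U + P - Z
        primal = np.linalg.norm(P - Z)
        if primal < tol * R and dual < tol * R:
            return (Z + Z.T) / 2.0
    raise RuntimeError(
        f"graphical lasso ADMM did not converge in {max_iter} iterations "
        f"(primal residual {primal:.3e}, dual residual {dual:.3e})")


def glasso_fc(cov: np.ndarray, alpha: float = 0.05,
              max_iter: int = 2000, tol: float = 1e-9) -> ConnectivityMatrix:
    """L1-regularized partial correlation via the graphical lasso.

    The input covariance is rescaled to correlation form (the penalty is then
    comparable across regions) and the estimated precision is mapped to the
    partial-correlation scale.  alpha = 0 reduces exactly to
    :func:`partial_fc`.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    cov = np.asarray(cov, dtype=float)
    corr = cov_to_correlation(cov)
    if alpha == 0:
        return ConnectivityMatrix(partial_fc(corr).values, "glasso")
    precision = graphical_lasso_admm(corr, alpha, max_iter=max_iter, tol=tol)
    return ConnectivityMatrix(_precision_to_partial(precision), "glasso")


def glasso_kkt_residual(corr: np.ndarray, precision: np.ndarray,
                        alpha: float) -> float:
    """Max off-diagonal violation of the graphical-lasso stationarity system.

    The objective -logdet(P) + tr(S P) + alpha * ||P||_1,off has stationarity
    S - P^-1 + alpha * sign(P_ij) = 0 on the off-diagonal support and
    |S_ij - (P^-1)_ij| <= alpha off the support.
    """
    W = np.linalg.inv(precision)
    G = corr - W
    off = ~np.eye(corr.shape[0], dtype=bool)
    nz = off & (precision != 0)
    z = off & (precision == 0)
    res = 0.0
    if nz.any():
        res = max(res, np.abs(G[nz] + alpha * np.sign(precision[nz])).max())
    if z.any():
        res = max(res, max(0.0, np.abs(G[z]).max() - alpha))
    return float(res)


def glasso_objective(S: np.ndarray, P: np.ndarray, alpha: float) -> float:
    """Penalized negative log-likelihood of the graphical-lasso program."""
    sign, logdet = np.linalg.slogdet(P)
    if sign <= 0:
        return np.inf
    off = ~np.eye(S.shape[0], dtype=bool)
    return float(-logdet + np.trace(S @ P) + alpha * np.abs(P[off]).sum())


# ---------------------------------------------------------------------------
# Tangent space
# ---------------------------------------------------------------------------

def fit_tangent_reference(train_covs: list[np.ndarray],
                          train_scan_ids: tuple[str, ...] | None = None,
                          tol: float = 1e-8, max_iter: int = 60,
                          mean: str = "frechet") -> TangentReference:
    """Reference point for tangent-space projection.

    ``mean="frechet"`` (default) runs the fixed-point iteration for the
    affine-invariant Frechet mean: G <- G^1/2 exp(mean_i log(G^-1/2 C_i
    G^-1/2)) G^1/2, stopping when the mean tangent vector has Frobenius
    norm below ``tol``.  ``mean="log_euclidean"`` is the documented fallback
    G = exp(mean_i log C_i) for the rare non-convergent case.
    """
    if not train_covs:
        raise ValueError("need at least one training covariance")
    covs = [np.asarray(c, dtype=float) for c in train_covs]
    ids = tuple(train_scan_ids) if train_scan_ids is not None else ()
    if mean == "log_euclidean":
        G = expm_sym(np.mean([logm_spd(c) for c in covs], axis=0))
        return TangentReference(G, powm_spd(G, -0.5), ids, 0)
    if mean != "frechet":
        raise ValueError(f"unknown mean {mean!r}")
    G = np.mean(covs, axis=0)
    for it in range(1, max_iter + 1):
        Gh = powm_spd(G, 0.5)
        Gih = powm_spd(G, -0.5)
        M = np.mean([logm_spd(Gih @ c @ Gih) for c in covs], axis=0)
        if np.linalg.norm(M) < tol:
            return TangentReference(G, Gih, ids, it)
        G = Gh @ expm_sym(M) @ Gh
        G = (G + G.T) / 2.0
    raise RuntimeError(
        f"Frechet mean did not converge in {max_iter} iterations; "
        "consider mean='log_euclidean'")


def tangent_fc(cov: np.ndarray, ref: TangentReference) -> ConnectivityMatrix:
    """Project one covariance to the tangent space at the fitted reference.

    Returns log(G^-1/2 C G^-1/2); symmetric but not bounded in [-1, 1].
    A numerically non-SPD whitened product is floored at 1e-10 (warning).
    """
    W = ref.whitening
    S = W @ np.asarray(cov, dtype=float) @ W
    return ConnectivityMatrix(logm_spd((S + S.T) / 2.0), "tangent")


# ---------------------------------------------------------------------------
# Vectorization
# ---------------------------------------------------------------------------

def edge_index_map(n_regions: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle (i < j) edge ordering shared package-wide."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def vectorize(mat, tol: float = 1e-8) -> np.ndarray:
    """Upper-triangle (diagonal excluded) edge vector of a symmetric matrix."""
    values = mat.values if isinstance(mat, ConnectivityMatrix) else np.asarray(mat, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("need a square matrix")
    if np.abs(values - values.T).max() > tol:
        raise ValueError("matrix asymmetric beyond tolerance")
    iu, ju = np.triu_indices(values.shape[0], k=1)
    return values[iu, ju].copy()


def devectorize(vec: np.ndarray, diagonal: float = 0.0) -> np.ndarray:
    """Symmetric matrix from an edge vector (inverse of :func:`vectorize`)."""
    vec = np.asarray(vec, dtype=float)
    E = vec.size
    R = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
    if R * (R - 1) // 2 != E:
        raise ValueError(f"edge count {E} is not R(R-1)/2 for integer R")
    out = np.full((R, R), 0.0)
    iu, ju = np.triu_indices(R, k=1)
    out[iu, ju] = vec
    out += out.T
    np.fill_diagonal(out, diagonal)
    return out


def fc_matrix(cov: np.ndarray, measure: str,
              tangent_ref: TangentReference | None = None,
              glasso_alpha: float = 0.05) -> ConnectivityMatrix:
    """Dispatch a covariance matrix to one of the four FC measures.

    Pearson here rescales the covariance to correlation form, which matches
    correlating the time series directly when the covariance is empirical.
    """
    if measure == "pearson":
        c = cov_to_correlation(cov)
        np.fill_diagonal(c, 1.0)
        return ConnectivityMatrix(c, "pearson")
    if measure == "partial":
        return partial_fc(cov)
    if measure == "glasso":
        return glasso_fc(cov, alpha=glasso_alpha)
    if measure == "tangent":
        if tangent_ref is None:
            raise ValueError("tangent measure requires a fitted TangentReference")
        return tangent_fc(cov, tangent_ref)
    raise ValueError(f"unknown measure {measure!r}")
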