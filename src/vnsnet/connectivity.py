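"""Dynamic partial-correlation connectivity estimation.

Per epoch: a Gaussian-kernel-weighted time-varying covariance is computed
at each of the 60 seconds, averaged over the epoch, fed to the graphical
lasso to estimate a sparse precision matrix, and rescaled to partial
correlations rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj). The 171
upper-triangle values per epoch are the network features.

The kernel weight of second i for center t is exp(-((i-t)/h)^2 / 2),
normalized to sum to one; boundary centers use the truncated, renormalized
kernel. The default bandwidth is h = n^(1/3) (about 3.91 for n = 60
seconds), a standard kernel-smoothing scale for the epoch length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from vnsnet.montage import edge_labels, edge_pairs
from vnsnet.preprocessing import EpochMatrix

DEFAULT_EPOCH_SECONDS = 60
DEFAULT_BANDWIDTH = float(DEFAULT_EPOCH_SECONDS) ** (1.0 / 3.0)
DEFAULT_LAMBDA = 0.1

CENTERINGS = ("none", "kernel_mean", "epoch_mean")


@dataclass
class KernelWeights:
    weights: np.ndarray
    bandwidth: float
    center: int


@dataclass
class TimeVaryingCovariance:
    matrices: np.ndarray  # [n_seconds, p, p]
    centering: str


@dataclass
class PrecisionMatrix:
    theta: np.ndarray
    penalty: float
    converged: bool


def default_bandwidth(n_seconds: int = DEFAULT_EPOCH_SECONDS) -> float:
    return float(n_seconds) ** (1.0 / 3.0)


def kernel_weights(t: int, n: int = DEFAULT_EPOCH_SECONDS, h: float | None = None) -> KernelWeights:
    """Normalized Gaussian kernel weights over seconds 1..n for center t."""
    if h is None:
        h = default_bandwidth(n)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if not 1 <= t <= n:
        raise ValueError(f"center {t} outside 1..{n}")
    i = np.arange(1, n + 1)
    raw = np.exp(-0.5 * ((i - t) / h) ** 2)
    return KernelWeights(weights=raw / raw.sum(), bandwidth=float(h), center=int(t))


def time_varying_covariance(
    epoch, h: float | None = None, centering: str = "epoch_mean"
) -> TimeVaryingCovariance:
    """Kernel-weighted second-moment matrix at every second of an epoch.

    Sigma_hat_t = sum_i w_it x_i x_i^T / sum_i w_it with x_i the
    (optionally centered) 19-vector at second i.
    """
    values = epoch.values if isinstance(epoch, EpochMatrix) else np.asarray(epoch, float)
    if not np.all(np.isfinite(values)):
        raise ValueError("epoch contains non-finite values")
    if centering not in CENTERINGS:
        raise ValueError(f"centering must be one of {CENTERINGS}")
    n, p = values.shape
    if h is None:
        h = default_bandwidth(n)
    x = values - values.mean(axis=0) if centering == "epoch_mean" else values
    mats = np.empty((n, p, p))
    for t in range(1, n + 1):
        w = kernel_weights(t, n, h).weights
        xt = x - (w @ x) if centering == "kernel_mean" else x
        mats[t - 1] = (xt * w[:, None]).T @ xt
    return TimeVaryingCovariance(matrices=mats, centering=centering)


def epoch_mean_covariance(tvc: TimeVaryingCovariance) -> np.ndarray:
    """Entrywise mean of the 60 per-second covariance matrices."""
    return tvc.matrices.mean(axis=0)


def glasso_precision(S: np.ndarray, lam: float = DEFAULT_LAMBDA) -> PrecisionMatrix:
    """Sparse precision estimate maximizing the L1-penalized Gaussian
    log-likelihood log det(Theta) - tr(S Theta) - lam * ||Theta||_1,offdiag.

    lam = 0 returns the unpenalized MLE S^{-1} (requires nonsingular S).
    """
    S = np.asarray(S, dtype=float)
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("covariance must be square symmetric")
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if lam == 0:
        if np.linalg.cond(S) > 1e12:
            raise ValueError("singular covariance at lambda=0; use lambda > 0")
        theta = np.linalg.inv(S)
        theta = 0.5 * (theta + theta.T)
        return PrecisionMatrix(theta=theta, penalty=0.0, converged=True)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        _, theta = graphical_lasso(S, alpha=lam, max_iter=200, tol=1e-4)
    theta = 0.5 * (theta + theta.T)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not converged or abs(_dual_gap(S, theta, lam)) > 1e-4:
        # coordinate descent can cycle on near-singular epoch covariances
        # at small penalties; an ADMM pass is slower but unconditionally
        # convergent on this problem class
        theta = _admm_glasso(S, lam)
        gap = abs(_dual_gap(S, theta, lam))
        converged = gap <= 1e-4
        if not converged:
            raise RuntimeError(
                f"graphical lasso did not converge (duality gap {gap:.2e})"
            )
    return PrecisionMatrix(theta=theta, penalty=float(lam), converged=converged)


def _dual_gap(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """Duality gap of the penalized log-likelihood at ``theta``."""
    gap = np.sum(S * theta) - S.shape[0]
    gap += lam * (np.abs(theta).sum() - np.abs(np.diag(theta)).sum())
    return float(gap)


def _admm_glasso(
    S: np.ndarray, lam: float, rho: float = 1.0, max_iter: int = 4000
) -> np.ndarray:
    """ADMM splitting for the graphical lasso.

    Alternates an eigendecomposition-based positive-definite update with
    off-diagonal soft thresholding; stops when the duality gap of the
    sparse iterate falls below 1e-5.
    """
    p = S.shape[0]
    X = np.linalg.inv(S + lam * np.eye(p))
    Z = X.copy()
    U = np.zeros_like(S)
    for it in range(max_iter):
        vals, vecs = np.linalg.eigh(rho * (Z - U) - S)
        d = (vals + np.sqrt(vals**2 + 4 * rho)) / (2 * rho)
        X = (vecs * d) @ vecs.T
        A = X + U
        Z = np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0)
        np.fill_diagonal(Z, np.diag(A))
        U += X - Z
        if it % 10 == 9 and abs(_dual_gap(S, Z, lam)) < 1e-5:
            break
    Z = 0.5 * (Z + Z.T)
    if np.linalg.eigvalsh(Z)[0] <= 0:
        Z = 0.5 * (X + X.T)  # PD by construction, nearly identical at exit
    return Z


def partial_correlations(theta) -> np.ndarray:
    """Upper-triangle partial correlations from a precision matrix.

    rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj), emitted in canonical
    row-major upper-triangle order; every value lies in [-1, 1].
    """
    mat = theta.theta if isinstance(theta, PrecisionMatrix) else np.asarray(theta, float)
    d = np.diag(mat)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be strictly positive")
    rho = -mat / np.sqrt(np.outer(d, d))
    iu = np.triu_indices(mat.shape[0], k=1)
    vec = rho[iu]
    return np.clip(vec, -1.0, 1.0)


def select_lambda_ebic(
    S: np.ndarray,
    n_samples: int,
    grid=None,
    gamma: float = 0.5,
) -> float:
    """Pick the glasso penalty minimizing the extended BIC.

    EBIC(lam) = -n * [log det(Theta) - tr(S Theta)] + E log n
    + 4 gamma E log p, with E the number of nonzero off-diagonal pairs of
    the estimate at ``lam``. gamma = 0.5 is the usual sparse-regime
    choice; gamma = 0 recovers plain BIC.
    """
    if grid is None:
        grid = np.logspace(-2, 0, 10)
    p = S.shape[0]
    best_lam, best_score = None, np.inf
    for lam in sorted(grid):
        theta = glasso_precision(S, float(lam)).theta
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            continue
        loglik = logdet - np.sum(S * theta)
        iu = np.triu_indices(p, k=1)
        n_edges_hat = int(np.sum(np.abs(theta[iu]) > 1e-10))
        score = -n_samples * loglik + n_edges_hat * (
            np.log(n_samples) + 4.0 * gamma * np.log(p)
        )
        if score < best_score:
            best_lam, best_score = float(lam), score
    if best_lam is None:
        raise ValueError("no grid point produced a positive-definite estimate")
    return best_lam


def epoch_features(
    epoch, h: float | None = None, lam: float = DEFAULT_LAMBDA, centering: str = "epoch_mean"
) -> np.ndarray:
    """Full per-epoch pipeline: kernel covariance -> glasso -> rho vector."""
    tvc = time_varying_covariance(epoch, h=h, centering=centering)
    S = epoch_mean_covariance(tvc)
    return partial_correlations(glasso_precision(S, lam))


def connectivity_pipeline(
    epochs: list[EpochMatrix],
    h: float | None = None,
    lam: float = DEFAULT_LAMBDA,
    centering: str = "epoch_mean",
) -> pd.DataFrame:
    """Assemble the epoch-by-edge feature table.

    Returns a DataFrame with one row per epoch: metadata columns
    (patient_id, label, origin) followed by one column per electrode pair
    named like ``'C3-C4'``.
    """
    if not epochs:
        raise ValueError("no epochs given")
    p = epochs[0].values.shape[1]
    labels = (
        edge_labels()
        if p == 19
        else [f"ch{i}-ch{j}" for i, j in edge_pairs(p)]
    )
    rows = np.vstack([epoch_features(e, h=h, lam=lam, centering=centering) for e in epochs])
    meta = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in epochs],
            "label": [e.label for e in epochs],
            "origin": [e.origin for e in epochs],
        }
    )
    return pd.concat([meta, pd.DataFrame(rows, columns=labels)], axis=1)


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """Numeric edge columns of a feature table as an array."""
    return table.drop(columns=["patient_id", "label", "origin"]).to_numpy(float)
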