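"""Riemannian (SPD-manifold) covariance features.

The spatial covariance matrix of a band-filtered epoch is symmetric
positive definite (SPD) and therefore a point on the SPD manifold.
Under the affine-invariant metric the distance between two SPD
matrices A, B is

    d(A, B) = || logm(A^{-1/2} B A^{-1/2}) ||_F ,

the Fréchet (Riemannian) mean M of a set of covariances minimises the
sum of squared distances, and the logarithmic map at M sends each
covariance to a Euclidean tangent vector.  Vectorising the tangent
matrices (upper triangle, off-diagonals scaled by sqrt(2)) yields the
design matrix consumed by the penalised-regression feature selector;
with this scaling the Euclidean norm of a tangent vector equals the
manifold distance to the reference exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.covariance import ledoit_wolf

from .exceptions import ConvergenceError, SingularityError

__all__ = [
    "SPDSet",
    "TangentBasis",
    "sample_covariance",
    "covariances_by_band",
    "geodesic_distance",
    "riemannian_mean",
    "geodesic",
    "tangent_project",
    "exp_map",
    "build_feature_matrix",
    "tangent_dim",
]

_SYM_TOL = 1e-10


def _check_spd(A: np.ndarray, name: str = "matrix") -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square, got shape {A.shape}")
    scale = max(1.0, float(np.abs(A).max()))
    if np.abs(A - A.T).max() > _SYM_TOL * scale:
        raise ValueError(f"{name} is not symmetric")
    if eigh(A, eigvals_only=True, subset_by_index=[0, 0])[0] <= 0:
        raise ValueError(f"{name} is not positive definite")
    return 0.5 * (A + A.T)


def _powm(A: np.ndarray, power: float) -> np.ndarray:
    w, V = eigh(A)
    return (V * w**power) @ V.T


def _logm(A: np.ndarray) -> np.ndarray:
    w, V = eigh(A)
    return (V * np.log(w)) @ V.T


def _expm(S: np.ndarray) -> np.ndarray:
    w, V = eigh(0.5 * (S + S.T))
    return (V * np.exp(w)) @ V.T


def tangent_dim(n_channels: int) -> int:
    """Free parameters of a symmetric n x n matrix: n(n+1)/2."""
    return n_channels * (n_channels + 1) // 2


def sample_covariance(trial: np.ndarray, shrinkage: str | None = "ledoit-wolf") -> np.ndarray:
    """Spatial covariance of one (channels x samples) epoch.

    Parameters
    ----------
    trial : ndarray, shape (n_channels, n_samples)
    shrinkage : {"ledoit-wolf", "ridge", None}
        "ledoit-wolf" blends the sample covariance with a scaled
        identity at an analytically chosen intensity and guarantees
        positive definiteness even for rank-deficient epochs.
        "ridge" adds a fixed 1e-6 * trace/C diagonal. None returns
        the plain estimate and raises :class:`SingularityError` if it
        is not positive definite.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim == 1:
        trial = trial[None, :]
    n_c, n_s = trial.shape
    if n_s < 2:
        raise ValueError("need at least 2 samples per trial")
    centered = trial - trial.mean(axis=1, keepdims=True)
    if shrinkage == "ledoit-wolf":
        cov, _ = ledoit_wolf(centered.T, assume_centered=True)
        # LW can return exactly the zero matrix for an all-constant trial
        if np.trace(cov) <= 0:
            raise SingularityError("zero-variance trial: covariance is singular")
        return cov
    cov = centered @ centered.T / (n_s - 1)
    if shrinkage == "ridge":
        tr = np.trace(cov)
        if tr <= 0:
            raise SingularityError("zero-variance trial: covariance is singular")
        return cov + (1e-6 * tr / n_c) * np.eye(n_c)
    if shrinkage is None:
        if eigh(cov, eigvals_only=True, subset_by_index=[0, 0])[0] <= 0:
            raise SingularityError(
                "sample covariance is singular; enable shrinkage or provide more samples"
            )
        return cov
    raise ValueError(f"unknown shrinkage mode {shrinkage!r}")


@dataclass
class SPDSet:
    """Per-trial, per-band covariance matrices with their labels.

    covs has shape (n_trials, n_bands, C, C).
    """

    covs: np.ndarray
    labels: np.ndarray
    bands: list[tuple[float, float]] | None = None

    def __post_init__(self):
        self.covs = np.asarray(self.covs, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.covs.ndim != 4 or self.covs.shape[2] != self.covs.shape[3]:
            raise ValueError("covs must have shape (n_trials, n_bands, C, C)")
        if self.labels.shape != (self.covs.shape[0],):
            raise ValueError("labels length must equal n_trials")

    @property
    def n_trials(self) -> int:
        return self.covs.shape[0]

    @property
    def n_bands(self) -> int:
        return self.covs.shape[1]

    @property
    def n_channels(self) -> int:
        return self.covs.shape[2]


def covariances_by_band(banded_trials, shrinkage: str | None = "ledoit-wolf") -> SPDSet:
    """Covariance of every (trial, band) pair of a filter-bank output."""
    labels = banded_trials[0].labels
    covs = np.stack(
        [
            np.stack([sample_covariance(tr, shrinkage) for tr in ts.data])
            for ts in banded_trials
        ],
        axis=1,
    )
    return SPDSet(covs=covs, labels=labels)


def geodesic_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant distance ||logm(A^{-1/2} B A^{-1/2})||_F."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    # eigenvalues of A^{-1} B == eigenvalues of the whitened matrix
    w = eigh(0.5 * (B + B.T), 0.5 * (A + A.T), eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def geodesic(A: np.ndarray, B: np.ndarray, t: float) -> np.ndarray:
    """Point at parameter t on the geodesic from A (t=0) to B (t=1)."""
    A_h = _powm(A, 0.5)
    A_ih = _powm(A, -0.5)
    return A_h @ _powm(A_ih @ B @ A_ih, t) @ A_h


def riemannian_mean(
    covs,
    tol: float = 1e-8,
    max_iter: int = 50,
    full_output: bool = False,
):
    """Fréchet mean of SPD matrices under the affine-invariant metric.

    Fixed-point iteration M <- M^{1/2} expm(mean_i logm(M^{-1/2} C_i
    M^{-1/2})) M^{1/2}, initialised at the arithmetic mean, stopping
    when the Frobenius norm of the tangent update falls below `tol`.
    At the solution the tangent vectors to the inputs sum to zero
    (the Fréchet stationarity condition).

    Returns the mean, or ``(mean, n_iter)`` if full_output.
    """
    covs = np.asarray(covs, dtype=float)
    if covs.ndim != 3 or covs.shape[0] == 0:
        raise ValueError("need a nonempty stack of same-dimension SPD matrices")
    M = covs.mean(axis=0)
    residual = np.inf
    for it in range(1, max_iter + 1):
        M_h = _powm(M, 0.5)
        M_ih = _powm(M, -0.5)
        T = np.mean([_logm(M_ih @ C @ M_ih) for C in covs], axis=0)
        residual = float(np.linalg.norm(T, "fro"))
        if residual < tol:
            return (M, it) if full_output else M
        M = M_h @ _expm(T) @ M_h
    raise ConvergenceError(
        f"Fréchet mean did not converge in {max_iter} iterations "
        f"(last residual {residual:.3e})",
        residual=residual,
    )


@dataclass
class TangentBasis:
    """Reference point and whitening factor for tangent-space mapping."""

    reference: np.ndarray
    whitener: np.ndarray = None  # M^{-1/2}, computed if not given

    def __post_init__(self):
        self.reference = _check_spd(self.reference, "reference")
        if self.whitener is None:
            self.whitener = _powm(self.reference, -0.5)

    @classmethod
    def fit(cls, covs, tol: float = 1e-8, max_iter: int = 50) -> "TangentBasis":
        """Fit the basis at the Fréchet mean of training covariances."""
        return cls(reference=riemannian_mean(covs, tol=tol, max_iter=max_iter))

    @property
    def dim(self) -> int:
        return self.reference.shape[0]


def _vec_symmetric(S: np.ndarray) -> np.ndarray:
    n = S.shape[0]
    iu, ju = np.triu_indices(n)
    scale = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return S[iu, ju] * scale


def _unvec_symmetric(v: np.ndarray) -> np.ndarray:
    p = v.shape[0]
    n = int((np.sqrt(8 * p + 1) - 1) / 2)
    if tangent_dim(n) != p:
        raise ValueError(f"vector length {p} is not a triangular number")
    iu, ju = np.triu_indices(n)
    scale = np.where(iu == ju, 1.0, 1.0 / np.sqrt(2.0))
    S = np.zeros((n, n))
    S[iu, ju] = v * scale
    S = S + S.T - np.diag(np.diag(S))
    return S


def tangent_project(C: np.ndarray, basis: TangentBasis) -> np.ndarray:
    """Log-map C at the basis reference and vectorise.

    The vector holds the upper triangle of S = logm(M^{-1/2} C M^{-1/2})
    with off-diagonals scaled by sqrt(2), so that ||v||_2 equals
    geodesic_distance(M, C).
    """
    C = _check_spd(C, "C")
    if C.shape[0] != basis.dim:
        raise ValueError("dimension mismatch between C and basis")
    W = basis.whitener
    return _vec_symmetric(_logm(W @ C @ W))


def exp_map(v: np.ndarray, basis: TangentBasis) -> np.ndarray:
    """Inverse of :func:`tangent_project` at the same basis."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.shape[0] != tangent_dim(basis.dim):
        raise ValueError(
            f"tangent vector must have length {tangent_dim(basis.dim)}, got {v.shape}"
        )
    S = _unvec_symmetric(v)
    M_h = _powm(basis.reference, 0.5)
    return M_h @ _expm(S) @ M_h


def build_feature_matrix(spd: SPDSet, bases: list[TangentBasis]):
    """Concatenate per-band tangent vectors into the n x p design matrix.

    bases must have been fitted on training trials only.  Returns
    ``(X, columns)`` where ``columns`` is a list of dicts with the band
    index and matrix entry (i, j) behind each column.
    """
    if len(bases) != spd.n_bands:
        raise ValueError(
            f"got {len(bases)} tangent bases for {spd.n_bands} bands"
        )
    n, C = spd.n_trials, spd.n_channels
    d = tangent_dim(C)
    X = np.empty((n, spd.n_bands * d))
    for b, basis in enumerate(bases):
        if basis.dim != C:
            raise ValueError("tangent basis dimension does not match covariances")
        for i in range(n):
            X[i, b * d : (b + 1) * d] = tangent_project(spd.covs[i, b], basis)
    iu, ju = np.triu_indices(C)
    columns = [
        {"band": b, "i": int(i), "j": int(j)}
        for b in range(spd.n_bands)
        for i, j in zip(iu, ju)
    ]
    return X, columns
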