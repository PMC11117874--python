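"""Synthetic data generators.

Two generators cover the two halves of the method:

* :func:`gen_two_class_trials` emulates the covariance contrast that
  motor imagery induces in band-limited EEG: each class has its own
  target spatial covariance (a base SPD matrix, and the same matrix
  with half the eigenvalues inflated by ``1 + class_sep``), trials are
  band-limited colored noise spatially mixed by the class-specific
  square root, plus additive white sensor noise.  ``class_sep``
  directly controls how far the two class covariances lie apart on the
  SPD manifold.  Real-EEG artifacts (blinks, line noise,
  nonstationarity) are deliberately not modelled.

* :func:`gen_sparse_regression` builds linear-model benches
  y = X beta + eps with block-equicorrelated Gaussian columns and a
  sparse ground-truth beta — the correlated, multicollinear regime the
  fusion penalty is designed for.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import TrialSet, bandpass
from .riemann import _powm

__all__ = [
    "TrialGenSpec",
    "RegressionGenSpec",
    "gen_spd",
    "gen_two_class_trials",
    "gen_sparse_regression",
]


@dataclass(frozen=True)
class TrialGenSpec:
    """Study conditions for the two-class trial generator."""

    n_channels: int = 8
    n_trials_per_class: int = 40
    n_samples: int = 875
    fs: float = 250.0
    class_sep: float = 1.0
    noise_sd: float = 0.5
    band: tuple[float, float] = (8.0, 30.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.n_samples < 2 * self.n_channels:
            raise ValueError("n_samples must be >= 2 * n_channels")
        if self.class_sep < 0:
            raise ValueError("class_sep must be nonnegative")
        if not self.fs > 2 * self.band[1]:
            raise ValueError("fs must exceed twice the band upper edge")


@dataclass(frozen=True)
class RegressionGenSpec:
    """Study conditions for the sparse linear-model bench."""

    n: int = 100
    p: int = 50
    k: int = 5
    rho_block: float = 0.5
    beta_scale: float = 1.0
    noise_sd: float = 0.5
    block_size: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.k > self.p:
            raise ValueError("true support size k cannot exceed p")
        if not 0 <= self.rho_block < 1:
            raise ValueError("rho_block must be in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


def gen_spd(dim: int, scale: float = 1.0, seed: int = 0) -> np.ndarray:
    """Random SPD matrix: random orthogonal frame, log-uniform spectrum.

    Eigenvalues are drawn log-uniformly in [scale/e, scale*e], so the
    matrix is well-conditioned and strictly positive definite.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if not scale > 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    eigs = scale * np.exp(rng.uniform(-1.0, 1.0, size=dim))
    return (Q * eigs) @ Q.T


def _class_targets(spec: TrialGenSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    base = gen_spd(spec.n_channels, scale=1.0,
                   seed=int(rng.integers(0, 2**31 - 1)))
    w, V = np.linalg.eigh(base)
    inflate = np.ones(spec.n_channels)
    inflate[spec.n_channels // 2 :] = 1.0 + spec.class_sep
    other = (V * (w * inflate)) @ V.T
    return base, other


def gen_two_class_trials(spec: TrialGenSpec) -> TrialSet:
    """Two-class labeled trials with controlled covariance separation.

    Returns ``2 * n_trials_per_class`` trials with balanced 0/1 labels.
    The geodesic distance between the empirical class covariances
    grows monotonically with ``class_sep``; at ``class_sep = 0`` the
    classes share one generating law.
    """
    rng = np.random.default_rng(spec.seed)
    targets = _class_targets(spec, rng)
    mixers = [_powm(t, 0.5) for t in targets]
    n_each = spec.n_trials_per_class
    data = np.empty((2 * n_each, spec.n_channels, spec.n_samples))
    labels = np.empty(2 * n_each, dtype=int)
    # interleave classes so any contiguous subset stays balanced
    for i in range(2 * n_each):
        cls = i % 2
        white = rng.standard_normal((spec.n_channels, spec.n_samples))
        src = bandpass(white, spec.fs, spec.band, order=2)
        trial = mixers[cls] @ src
        trial += spec.noise_sd * rng.standard_normal(trial.shape)
        data[i] = trial
        labels[i] = cls
    return TrialSet(data=data, fs=spec.fs, labels=labels, t0=0.0)


def gen_sparse_regression(spec: RegressionGenSpec):
    """Sparse linear bench with block-equicorrelated design.

    Columns are grouped into blocks of ``block_size``; within a block
    every pair has correlation ``rho_block`` (x = sqrt(rho) z_block +
    sqrt(1-rho) eps), across blocks columns are independent.  Columns
    are standardized (zero mean, unit variance) after generation.  The
    true coefficient vector has exactly ``k`` nonzeros of magnitude
    ``beta_scale`` with alternating sign, placed on the first column
    of the first k blocks (wrapping within blocks if k exceeds the
    block count).

    Returns ``(X, y, beta_true)``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, r = spec.n, spec.p, spec.rho_block
    n_blocks = int(np.ceil(p / spec.block_size))
    block_of = np.arange(p) // spec.block_size
    z = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, p))
    X = np.sqrt(r) * z[:, block_of] + np.sqrt(1.0 - r) * eps
    X = (X - X.mean(axis=0)) / X.std(axis=0)

    beta = np.zeros(p)
    for m in range(spec.k):
        block = m % n_blocks
        offset = m // n_blocks
        j = block * spec.block_size + offset
        beta[j] = spec.beta_scale * (1.0 if m % 2 == 0 else -1.0)
    y = X @ beta + spec.noise_sd * rng.standard_normal(n)
    return X, y, beta
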