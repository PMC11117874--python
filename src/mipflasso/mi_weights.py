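"""Mutual-information scores and the adaptive penalty weights.

Each tangent-space feature x_j receives an importance score
I_j = I(x_j; y), the plug-in mutual information (in nats) between the
feature — discretised into equal-frequency bins — and the class label.
The adaptive L1 weight is alpha_j = exp(-r * I_j): informative
features (large I_j) are penalised less, uninformative ones (I_j ~ 0)
carry the full penalty.  The trade-off parameter r defaults to 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "entropy",
    "conditional_entropy",
    "equal_frequency_bins",
    "joint_distribution",
    "mutual_information",
    "mi_profile",
    "AdaptiveWeights",
    "adaptive_weights",
    "ALPHA_FLOOR",
]

#: Lower bound on alpha_j; prevents overflow in beta_hat = beta*/alpha.
ALPHA_FLOOR = 1e-8

_PROB_TOL = 1e-8


def _validate_probs(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-15):
        raise ValueError(f"{name} has negative probabilities")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} probabilities sum to {p.sum():.6g}, not 1")
    return np.clip(p, 0.0, None)


def entropy(p, base: float | None = None) -> float:
    """Shannon entropy -sum p log p of a probability vector, in nats.

    The 0 * log 0 terms are taken as 0.  `base` switches the logarithm
    (e.g. 2 for bits); default is the natural log.
    """
    p = _validate_probs(np.ravel(p), "distribution")
    nz = p[p > 0]
    h = float(-np.sum(nz * np.log(nz)))
    if base is not None:
        h /= np.log(base)
    return h


def conditional_entropy(joint, base: float | None = None) -> float:
    """H(X|Y) from a joint table p(x, y) with x on rows, y on columns.

    Equals H(X,Y) - H(Y); satisfies 0 <= H(X|Y) <= H(X).
    """
    joint = _validate_probs(np.atleast_2d(np.asarray(joint, dtype=float)), "joint")
    p_y = joint.sum(axis=0)
    h = 0.0
    for k in range(joint.shape[1]):
        if p_y[k] <= 0:
            continue
        p_x_given_y = joint[:, k] / p_y[k]
        nz = p_x_given_y[p_x_given_y > 0]
        h -= p_y[k] * float(np.sum(nz * np.log(nz)))
    if base is not None:
        h /= np.log(base)
    return h


def equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretise a real vector into n_bins equal-count bins.

    Ties are broken by rank (stable sort order), so every bin holds
    floor/ceil(n / n_bins) points regardless of duplicated values.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(x, kind="stable")] = np.arange(n)
    return (ranks * n_bins) // n


def joint_distribution(x_codes: np.ndarray, y_codes: np.ndarray) -> np.ndarray:
    """Empirical joint table p(x, y) from two integer-coded vectors."""
    x_codes = np.asarray(x_codes)
    y_codes = np.asarray(y_codes)
    if x_codes.shape != y_codes.shape:
        raise ValueError("x and y must have equal length")
    xs, xi = np.unique(x_codes, return_inverse=True)
    ys, yi = np.unique(y_codes, return_inverse=True)
    table = np.zeros((xs.size, ys.size))
    np.add.at(table, (xi, yi), 1.0)
    return table / x_codes.size


def mutual_information(
    feature: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 8,
    base: float | None = None,
) -> float:
    """Plug-in mutual information (nats) between a feature and labels.

    The continuous feature is discretised into `n_bins` equal-frequency
    bins; the estimate is I = sum p(x,y) log[p(x,y) / (p(x) p(y))] over
    the binned variable, which equals H(X) - H(X|Y) exactly.  Always
    nonnegative.  A constant feature carries no information and returns
    0 with a warning.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if feature.shape != labels.shape:
        raise ValueError("feature and labels must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.unique(feature).size < 2:
        warnings.warn("constant feature: mutual information is 0", stacklevel=2)
        return 0.0
    codes = equal_frequency_bins(feature, n_bins)
    joint = joint_distribution(codes, labels)
    p_x = joint.sum(axis=1, keepdims=True)
    p_y = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    mi = float(np.sum(joint[mask] * np.log(joint[mask] / (p_x @ p_y)[mask])))
    if base is not None:
        mi /= np.log(base)
    return max(mi, 0.0)


def mi_profile(X: np.ndarray, labels: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Per-column mutual information of a design matrix with the labels."""
    X = np.asarray(X, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.array(
            [mutual_information(X[:, j], labels, n_bins=n_bins) for j in range(X.shape[1])]
        )


@dataclass
class AdaptiveWeights:
    """MI scores I_j and the adaptive penalty weights alpha_j = e^{-r I_j}."""

    I: np.ndarray
    r: float
    alpha: np.ndarray

    @property
    def A(self) -> np.ndarray:
        """Diagonal weight-matrix view diag(alpha_1, ..., alpha_p)."""
        return np.diag(self.alpha)

    def __len__(self) -> int:
        return self.alpha.shape[0]


def adaptive_weights(I, r: float = 5.0) -> AdaptiveWeights:
    """Build alpha_j = exp(-r * I_j), floored at ALPHA_FLOOR.

    Weights are strictly decreasing in I_j, so more informative features
    are penalised less.  I_j = 0 gives alpha_j = 1 (full penalty).
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("mutual-information scores must be nonnegative")
    if not r > 0:
        raise ValueError("trade-off parameter r must be positive")
    alpha = np.maximum(np.exp(-r * I), ALPHA_FLOOR)
    return AdaptiveWeights(I=I.copy(), r=float(r), alpha=alpha)
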