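"""Independent oracles used by the test suite.

These deliberately avoid the package's solver path: the penalised
objective is minimised by proximal gradient (FISTA) directly, with no
data augmentation, no coordinate descent and no alpha rescaling trick.
"""

import numpy as np


def penalized_objective(X, y, beta, alpha, lam1, lam2, W):
    resid = y - X @ beta
    val = resid @ resid + lam1 * np.sum(alpha * np.abs(beta))
    if lam2 > 0:
        val += lam2 * beta @ W @ beta
    return float(val)


def prox_grad_mipf(X, y, alpha, lam1, lam2, W=None, max_iter=500_000, tol=1e-13):
    """FISTA minimiser of ||y-Xb||^2 + lam1 sum a|b| + lam2 b'Wb."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    alpha = np.ones(p) if alpha is None else np.asarray(alpha, float)
    if W is None:
        W = np.zeros((p, p))
    H = X.T @ X + lam2 * W  # half-Hessian of the smooth part
    L = 2.0 * max(np.linalg.eigvalsh(H).max(), 1e-12)
    Xty = X.T @ y
    b = np.zeros(p)
    z = b.copy()
    t = 1.0
    thresh = lam1 * alpha / L
    for _ in range(max_iter):
        grad = 2.0 * (H @ z - Xty)
        v = z - grad / L
        b_new = np.sign(v) * np.maximum(np.abs(v) - thresh, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = b_new + ((t - 1.0) / t_new) * (b_new - b)
        delta = np.max(np.abs(b_new - b))
        b, t = b_new, t_new
        if delta < tol:
            break
    return b
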