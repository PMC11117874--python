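"""The MIPF-LASSO estimator.

Given a standardized design X (n x p), response y, and adaptive
weights alpha, the estimator solves

    beta_hat = argmin_beta ||y - X beta||^2
               + lambda1 * sum_j alpha_j |beta_j|
               + lambda2 * J(beta)

where the weighted fusion penalty

    J(beta) = sum_{j < i} (beta_i - beta_j)^2 / (1 - rho_ij)
                        + (beta_i + beta_j)^2 / (1 + rho_ij)

couples coefficients of correlated columns (rho_ij is the sample
correlation of columns i and j): as rho_ij -> 1 the difference term
dominates and the pair is shrunk together, giving the grouping effect
that plain LASSO lacks.  J is a quadratic form beta' W beta with
W_ii = sum_{j != i} 2 / (1 - rho_ij^2) and
W_ij = -2 rho_ij / (1 - rho_ij^2).

The problem is reduced to an ordinary LASSO by data augmentation:
with W = R'R (Cholesky, or a symmetric eigen square root when W is
semidefinite), stacking y_hat = [y; 0] and X_hat = [X; sqrt(lambda2) R]
absorbs the fusion penalty into the residual sum of squares, and
dividing column j of X_hat by alpha_j absorbs the adaptive weights
into a plain L1 term.  Cyclic coordinate descent with soft
thresholding then solves the LASSO; back-transformation is
beta_hat_j = beta*_j / alpha_j.  Because the augmented design has
rank up to n + p, the fusion term also makes the p > n case
well-posed.

Variant flags reduce the model for ablations: ``adaptive_lasso``
forces lambda2 = 0, ``lasso`` additionally forces alpha = 1, and
``none`` performs no selection at all.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh, LinAlgError

from .exceptions import SingularityError
from .mi_weights import ALPHA_FLOOR

__all__ = [
    "FusionWeightMatrix",
    "AugmentedProblem",
    "SolverConfig",
    "MipfLassoFit",
    "standardize_columns",
    "column_correlations",
    "fusion_penalty",
    "fusion_weight_matrix",
    "ridge_fusion",
    "sqrt_factor",
    "augment",
    "soft_threshold",
    "cd_lasso",
    "objective",
    "fit_mipf_lasso",
    "select_features",
    "lambda1_max",
    "tune",
]

#: Correlations are clipped to this magnitude before forming W
#: (the 1 - rho^2 denominators blow up at |rho| = 1).
DEFAULT_CLIP = 0.999

#: Coefficients below this magnitude count as zero for support purposes.
SUPPORT_TOL = 1e-8


def standardize_columns(X: np.ndarray):
    """Center columns and scale to unit Euclidean norm.

    With this scaling the sample correlation of columns i and j is
    simply x_i' x_j.  Returns ``(Xs, means, norms)``.  A zero-variance
    column raises, naming the column.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    Xc = X - means
    norms = np.linalg.norm(Xc, axis=0)
    bad = np.flatnonzero(norms <= 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s) at index {bad.tolist()}")
    return Xc / norms, means, norms


@dataclass
class FusionWeightMatrix:
    """Column correlations rho and the fusion quadratic form W."""

    rho: np.ndarray
    W: np.ndarray | None = None
    clip: float = DEFAULT_CLIP


def column_correlations(X: np.ndarray, clip: float = DEFAULT_CLIP) -> FusionWeightMatrix:
    """Sample correlation matrix of standardized columns, clipped.

    X must already be standardized (zero mean, unit Euclidean norm);
    then rho = X'X.  Off-diagonal entries are clipped to |rho| <= clip
    so the fusion denominators stay finite for duplicated columns.
    """
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X - X.mean(axis=0), axis=0)
    bad = np.flatnonzero(norms <= 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s) at index {bad.tolist()}")
    rho = X.T @ X
    rho = 0.5 * (rho + rho.T)
    rho = np.clip(rho, -clip, clip)
    np.fill_diagonal(rho, 1.0)
    return FusionWeightMatrix(rho=rho, clip=clip)


def _check_rho_offdiag(rho: np.ndarray) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    off = rho.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(np.abs(off) >= 1.0):
        raise ValueError("off-diagonal |rho| must be < 1; clip correlations first")
    return rho


def fusion_penalty(beta: np.ndarray, rho: np.ndarray) -> float:
    """Direct double-sum evaluation of the weighted fusion penalty J(beta)."""
    beta = np.asarray(beta, dtype=float)
    rho = _check_rho_offdiag(rho)
    p = beta.shape[0]
    total = 0.0
    for j in range(p - 1):
        for i in range(j + 1, p):
            r = rho[i, j]
            total += (beta[i] - beta[j]) ** 2 / (1.0 - r)
            total += (beta[i] + beta[j]) ** 2 / (1.0 + r)
    return float(total)


def fusion_weight_matrix(rho: np.ndarray) -> FusionWeightMatrix:
    """Quadratic-form matrix W with beta' W beta = J(beta) exactly.

    W_ii = sum_{j != i} 2/(1 - rho_ij^2), W_ij = -2 rho_ij/(1 - rho_ij^2).
    W is symmetric positive semidefinite.
    """
    rho = _check_rho_offdiag(rho)
    denom = 1.0 - rho**2
    np.fill_diagonal(denom, 1.0)  # excluded from the sums
    W = -2.0 * rho / denom
    np.fill_diagonal(W, 0.0)
    diag = (2.0 / denom).sum(axis=1) - 2.0  # subtract the i == j slot
    W += np.diag(diag)
    return FusionWeightMatrix(rho=rho, W=W)


def ridge_fusion(X: np.ndarray, y: np.ndarray, lambda2: float, W: np.ndarray) -> np.ndarray:
    """Closed-form ridge-fusion solution (X'X + lambda2 W)^{-1} X'y.

    This is the lambda1 = 0 special case of the full estimator; for
    p > n it remains well-defined whenever lambda2 > 0 because W lifts
    the rank of X'X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    A = X.T @ X + lambda2 * np.asarray(W, dtype=float)
    try:
        return cho_solve(cho_factor(A), X.T @ y)
    except LinAlgError:
        if lambda2 > 0:
            # numerically semidefinite system: tiny jitter restores PD
            jitter = 1e-10 * max(np.trace(A) / A.shape[0], 1.0)
            try:
                return cho_solve(cho_factor(A + jitter * np.eye(A.shape[0])), X.T @ y)
            except LinAlgError:
                pass
        raise SingularityError(
            "X'X + lambda2 W is singular (p > n with lambda2 = 0?)"
        ) from None


def sqrt_factor(W: np.ndarray) -> np.ndarray:
    """Factor R with R'R = W for a symmetric PSD matrix.

    Uses the Cholesky factor when W is numerically positive definite;
    otherwise falls back to the symmetric eigen square root with
    negative eigenvalues clipped at zero.
    """
    W = np.asarray(W, dtype=float)
    scale = max(1.0, float(np.abs(W).max()))
    if np.abs(W - W.T).max() > 1e-8 * scale:
        raise ValueError("W must be symmetric")
    try:
        return np.linalg.cholesky(W).T
    except np.linalg.LinAlgError:
        w, V = eigh(0.5 * (W + W.T))
        w = np.clip(w, 0.0, None)
        return (V * np.sqrt(w)) @ V.T


@dataclass
class AugmentedProblem:
    """LASSO-form rewrite of the fusion-penalised problem.

    y_hat stacks y over p zeros; X_hat stacks X over sqrt(lambda2) R,
    so ||y_hat - X_hat b||^2 = ||y - X b||^2 + lambda2 b'Wb; X_star
    divides column j of X_hat by alpha_j, absorbing the adaptive
    weights into a plain L1 penalty.
    """

    y_hat: np.ndarray
    X_hat: np.ndarray
    X_star: np.ndarray
    alpha: np.ndarray
    lambda2: float


def augment(
    X: np.ndarray,
    y: np.ndarray,
    lambda2: float,
    R: np.ndarray,
    alpha: np.ndarray,
) -> AugmentedProblem:
    """Stack the fusion factor under the design and rescale by alpha."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    R = np.asarray(R, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    n, p = X.shape
    if R.shape != (p, p):
        raise ValueError(f"R must be {p}x{p}, got {R.shape}")
    if alpha.shape != (p,):
        raise ValueError(f"alpha must have length {p}")
    if np.any(alpha < ALPHA_FLOOR):
        raise ValueError(f"alpha entries must be >= {ALPHA_FLOOR}")
    if lambda2 < 0:
        raise ValueError("lambda2 must be nonnegative")
    y_hat = np.concatenate([y, np.zeros(p)])
    X_hat = np.vstack([X, np.sqrt(lambda2) * R])
    X_star = X_hat / alpha
    return AugmentedProblem(y_hat=y_hat, X_hat=X_hat, X_star=X_star,
                            alpha=alpha, lambda2=lambda2)


def soft_threshold(z: float, t: float) -> float:
    """S(z, t) = sign(z) max(|z| - t, 0), the prox of t|.|."""
    return np.sign(z) * max(abs(z) - t, 0.0)


@dataclass
class SolverConfig:
    """Tuning pair, convergence controls and model variant."""

    lambda1: float = 0.0
    lambda2: float = 0.0
    tol: float = 1e-6
    max_sweeps: int = 10_000
    standardize: bool = True
    variant: str = "mipf"  # mipf | adaptive_lasso | lasso | none
    clip: float = DEFAULT_CLIP

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be nonnegative")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.variant not in {"mipf", "adaptive_lasso", "lasso", "none"}:
            raise ValueError(f"unknown variant {self.variant!r}")


def cd_lasso(
    X_star: np.ndarray,
    y_hat: np.ndarray,
    lambda1: float,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    beta0: np.ndarray | None = None,
):
    """Cyclic coordinate descent for min ||y - X b||^2 + lambda1 ||b||_1.

    With the un-halved squared loss the coordinate update is
    b_j <- S(x_j' r_{(-j)}, lambda1 / 2) / ||x_j||^2.  The objective is
    non-increasing across sweeps; iteration stops when the largest
    coefficient change in a sweep drops below `tol`.  Each sweep costs
    O(n p) via residual caching.

    Returns ``(beta, n_sweeps, converged)``; hitting max_sweeps flags
    converged = False rather than raising.
    """
    X_star = np.asarray(X_star, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if not (np.all(np.isfinite(X_star)) and np.all(np.isfinite(y_hat))):
        raise ValueError("inputs must be finite")
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    n, p = X_star.shape
    col_sq = np.einsum("ij,ij->j", X_star, X_star)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    resid = y_hat - X_star @ beta
    thresh = lambda1 / 2.0
    for sweep in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(p):
            cj = col_sq[j]
            if cj <= 0.0:
                continue
            xj = X_star[:, j]
            bj = beta[j]
            z = xj @ resid + cj * bj  # x_j' r_{(-j)}
            bj_new = soft_threshold(z, thresh) / cj
            if bj_new != bj:
                resid += xj * (bj - bj_new)
                beta[j] = bj_new
                max_delta = max(max_delta, abs(bj_new - bj))
        if max_delta < tol:
            return beta, sweep, True
    return beta, max_sweeps, False


def objective(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    alpha: np.ndarray,
    lambda1: float,
    lambda2: float,
    rho: np.ndarray | None = None,
    W: np.ndarray | None = None,
) -> float:
    """Penalised loss ||y - Xb||^2 + lambda1 sum alpha|b| + lambda2 b'Wb."""
    resid = y - X @ beta
    val = float(resid @ resid) + lambda1 * float(np.sum(alpha * np.abs(beta)))
    if lambda2 > 0:
        if W is None:
            if rho is None:
                raise ValueError("need rho or W to evaluate the fusion term")
            W = fusion_weight_matrix(rho).W
        val += lambda2 * float(beta @ W @ beta)
    return val


@dataclass
class MipfLassoFit:
    """Fitted coefficients plus solver diagnostics.

    `beta` is on the standardized-column scale (beta_j = beta_star_j /
    alpha_j); `beta_star` is the augmented-solver scale.  `coef_raw`
    and `intercept_raw` express the fit on the original, unstandardized
    feature scale for prediction.
    """

    beta: np.ndarray
    beta_star: np.ndarray
    alpha: np.ndarray
    lambda1: float
    lambda2: float
    support: np.ndarray
    n_sweeps: int
    converged: bool
    objective: float
    variant: str = "mipf"
    coef_raw: np.ndarray | None = None
    intercept_raw: float = 0.0

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        if self.coef_raw is None:
            raise ValueError("fit carries no raw-scale coefficients")
        return np.asarray(X_new, dtype=float) @ self.coef_raw + self.intercept_raw

    def to_dict(self) -> dict:
        """JSON-serialisable summary of the fit."""
        return {
            "variant": self.variant,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "support": self.support.tolist(),
            "beta": self.beta.tolist(),
            "n_sweeps": self.n_sweeps,
            "converged": self.converged,
            "objective": self.objective,
        }


def select_features(fit: MipfLassoFit) -> np.ndarray:
    """Indices (0-based, ascending) of coefficients with |beta_j| > 1e-8."""
    return np.flatnonzero(np.abs(fit.beta) > SUPPORT_TOL)


def lambda1_max(X: np.ndarray, y: np.ndarray, alpha: np.ndarray) -> float:
    """Smallest lambda1 at which the solution is exactly zero.

    From the KKT conditions of the un-halved loss: beta = 0 iff
    lambda1 >= 2 max_j |x_j' y| / alpha_j (on the alpha-rescaled design).
    """
    grad = np.abs(X.T @ y) / np.asarray(alpha, dtype=float)
    return 2.0 * float(grad.max())


def fit_mipf_lasso(
    X: np.ndarray,
    y: np.ndarray,
    alpha: np.ndarray | None = None,
    config: SolverConfig | None = None,
    beta0: np.ndarray | None = None,
) -> MipfLassoFit:
    """Fit the full estimator (or an ablation variant).

    Pipeline: standardize columns -> column correlations -> fusion
    matrix W -> square-root factor R -> data augmentation -> rescale
    by alpha -> coordinate-descent LASSO -> back-transform.  Binary
    responses should be coded +/-1 before centering (done by callers).
    """
    config = config or SolverConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    alpha = np.ones(p) if alpha is None else np.asarray(alpha, dtype=float).copy()

    lambda1, lambda2 = config.lambda1, config.lambda2
    if config.variant == "lasso":
        alpha = np.ones(p)
        lambda2 = 0.0
    elif config.variant == "adaptive_lasso":
        lambda2 = 0.0

    if config.standardize:
        Xs, means, norms = standardize_columns(X)
        y_mean = float(y.mean())
        ys = y - y_mean
    else:
        Xs, means, norms = X, np.zeros(p), np.ones(p)
        y_mean = 0.0
        ys = y

    if config.variant == "none":
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        rho_mat = None
        fit = MipfLassoFit(
            beta=beta, beta_star=beta.copy(), alpha=np.ones(p),
            lambda1=0.0, lambda2=0.0,
            support=np.arange(p), n_sweeps=0, converged=True,
            objective=float(np.sum((ys - Xs @ beta) ** 2)), variant="none",
        )
    else:
        alpha = np.maximum(alpha, ALPHA_FLOOR)
        rho_mat = None
        W = None
        if lambda2 > 0:
            fw = column_correlations(Xs, clip=config.clip)
            rho_mat = fw.rho
            W = fusion_weight_matrix(rho_mat).W
            R = sqrt_factor(W)
            aug = augment(Xs, ys, lambda2, R, alpha)
            X_star, y_hat = aug.X_star, aug.y_hat
        else:
            X_star, y_hat = Xs / alpha, ys
        beta_star, n_sweeps, converged = cd_lasso(
            X_star, y_hat, lambda1, tol=config.tol,
            max_sweeps=config.max_sweeps,
            beta0=None if beta0 is None else beta0 * alpha,
        )
        beta = beta_star / alpha
        fit = MipfLassoFit(
            beta=beta, beta_star=beta_star, alpha=alpha,
            lambda1=lambda1, lambda2=lambda2,
            support=np.flatnonzero(np.abs(beta) > SUPPORT_TOL),
            n_sweeps=n_sweeps, converged=converged,
            objective=objective(Xs, ys, beta, alpha, lambda1, lambda2, W=W),
            variant=config.variant,
        )

    fit.coef_raw = fit.beta / norms
    fit.intercept_raw = y_mean - float(means @ fit.coef_raw)
    return fit


def _grid_scores_regression(X, y, alpha, l1_grid, l2_grid, k_folds, seed, config):
    """CV mean-squared error of a least-squares refit on the support.

    Mirrors the classification scorer: the selector picks features, a
    downstream model fitted on them is scored.  Refitting removes the
    L1 shrinkage bias, so the score reflects the quality of the
    selected support rather than the shrunken coefficients.
    """
    from sklearn.model_selection import KFold

    rows = []
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    for l2 in l2_grid:
        for tr, va in splits:
            warm = None
            for l1 in sorted(l1_grid, reverse=True):
                cfg = replace(config, lambda1=l1, lambda2=l2)
                fit = fit_mipf_lasso(X[tr], y[tr], alpha, cfg, beta0=warm)
                warm = fit.beta
                sel = fit.support
                if sel.size == 0 or sel.size >= tr.size:
                    pred = np.full(va.size, y[tr].mean())
                else:
                    A = np.column_stack([np.ones(tr.size), X[tr][:, sel]])
                    coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
                    pred = np.column_stack([np.ones(va.size), X[va][:, sel]]) @ coef
                err = float(np.mean((y[va] - pred) ** 2))
                rows.append({"lambda1": l1, "lambda2": l2, "score": -err,
                             "n_selected": sel.size})
    return rows


def _grid_scores_classification(X, y, alpha, l1_grid, l2_grid, k_folds, seed, config):
    """CV downstream-classifier accuracy on the selected features."""
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("classification tuning expects binary labels")
    y_pm = np.where(y == classes[1], 1.0, -1.0)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for tr, _ in splits:
        if np.unique(y[tr]).size < 2:
            raise ValueError("a CV fold contains a single class; reduce k_folds")
    rows = []
    for l2 in l2_grid:
        for tr, va in splits:
            warm = None
            for l1 in sorted(l1_grid, reverse=True):
                cfg = replace(config, lambda1=l1, lambda2=l2)
                fit = fit_mipf_lasso(X[tr], y_pm[tr], alpha, cfg, beta0=warm)
                warm = fit.beta
                sel = fit.support
                if sel.size == 0:
                    acc = float(np.mean(y[va] == classes[np.argmax(
                        np.bincount((y[tr] == classes[1]).astype(int)))]))
                else:
                    clf = SVC(kernel="rbf", C=1.0, gamma="scale")
                    clf.fit(X[tr][:, sel], y[tr])
                    acc = float(np.mean(clf.predict(X[va][:, sel]) == y[va]))
                rows.append({"lambda1": l1, "lambda2": l2, "score": acc,
                             "n_selected": sel.size})
    return rows


def tune(
    X: np.ndarray,
    y: np.ndarray,
    alpha: np.ndarray | None,
    lambda1_grid,
    lambda2_grid,
    k_folds: int = 5,
    seed: int = 0,
    scoring: str = "classification",
    config: SolverConfig | None = None,
):
    """Pick (lambda1, lambda2) by k-fold cross-validation.

    scoring="classification" uses stratified folds and downstream
    RBF-SVM accuracy on the selected features; scoring="mse" uses
    plain folds and the mean-squared error of a least-squares refit on
    the selected support.  Selection follows the one-standard-error
    rule: among grid points whose mean CV score is within one standard
    error of the best, the sparsest model wins (fewest selected
    features, then larger lambda1, then larger lambda2).
    Deterministic given the seed.

    Returns ``(best_lambda1, best_lambda2, cv_table)`` where cv_table
    is a tidy DataFrame of per-(grid point, fold) scores.
    """
    import pandas as pd

    l1_grid = list(lambda1_grid)
    l2_grid = list(lambda2_grid)
    if not l1_grid or not l2_grid:
        raise ValueError("grids must be nonempty")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    config = config or SolverConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if scoring == "mse":
        rows = _grid_scores_regression(X, y, alpha, l1_grid, l2_grid,
                                       k_folds, seed, config)
    elif scoring == "classification":
        rows = _grid_scores_classification(X, y, alpha, l1_grid, l2_grid,
                                           k_folds, seed, config)
    else:
        raise ValueError(f"unknown scoring {scoring!r}")
    table = pd.DataFrame(rows)
    grouped = table.groupby(["lambda1", "lambda2"])
    summary = grouped["score"].mean().reset_index()
    summary["sem"] = grouped["score"].sem().fillna(0.0).to_numpy()
    summary["n_selected"] = grouped["n_selected"].mean().to_numpy()
    i_best = summary["score"].idxmax()
    threshold = summary.loc[i_best, "score"] - summary.loc[i_best, "sem"]
    candidates = summary[summary["score"] >= threshold - 1e-12]
    candidates = candidates.sort_values(
        ["n_selected", "lambda1", "lambda2"], ascending=[True, False, False]
    )
    best = candidates.iloc[0]
    return float(best["lambda1"]), float(best["lambda2"]), table
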