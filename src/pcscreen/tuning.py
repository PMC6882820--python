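"""Regularization grids and selection rules for the base estimators.

Eleven method/tuning combinations are supported in total (nineteen
counting the AND/OR nodewise variants separately):

========  =============================================
method    tuning rules
========  =============================================
glasso    cv (likelihood loss), cv-1se, cv2 (prediction
          loss), cv2-1se, bic, ebic
space     cv, cv-1se, bic, fsr
nr-and /  cv, cv-1se, bic, fsr   (per-node selection)
nr-or
ridge     cv
========  =============================================

Cross-validation uses K = 10 folds by default, assigned by a seeded random
permutation.  The CV loss reported for a grid value is the *sum* over
folds; the one-standard-error rule takes the SD of the per-fold losses at
the minimizing grid value, divides by sqrt(K), and picks the most
regularized grid value whose loss stays within that band.  Ties in any
argmin are broken toward the largest penalty (sparser model).

The information criteria are the unit-variance Gaussian forms:
``BIC = ||residual||^2 + k log n`` per regression, and for the graphical
lasso ``EBIC = -2 loglik + k log n + 4 k gamma log p`` with ``k`` the edge
count and ``gamma = 0.5`` by default (``gamma = 0`` is the classical BIC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .core import edge_set, validate_covariance
from .estimators import (
    FirstStageFit,
    _lasso_path_node,
    estimate_network,
    fit_glasso,
    fit_space,
    gaussian_loglik,
)

__all__ = [
    "GRID_SIZE",
    "LambdaGrid",
    "CvCurve",
    "make_folds",
    "glasso_grid",
    "space_grid",
    "glmnet_like_grid",
    "cv_select",
    "cv1_glasso",
    "cv2_glasso",
    "ebic_glasso",
    "bic_nodewise",
    "bic_space",
    "fsr_lambda",
    "cv_nodewise",
    "cv_space",
    "TuningResult",
    "tune_lambda",
    "VARIANTS",
]

GRID_SIZE = 100

#: the full method/tuning roster (method token, tuning token)
VARIANTS = (
    ("glasso", "cv"),
    ("glasso", "cv-1se"),
    ("glasso", "cv2"),
    ("glasso", "cv2-1se"),
    ("glasso", "bic"),
    ("glasso", "ebic"),
    ("space", "cv"),
    ("space", "cv-1se"),
    ("space", "bic"),
    ("space", "fsr"),
    ("nr-and", "cv"),
    ("nr-and", "cv-1se"),
    ("nr-and", "bic"),
    ("nr-and", "fsr"),
    ("nr-or", "cv"),
    ("nr-or", "cv-1se"),
    ("nr-or", "bic"),
    ("nr-or", "fsr"),
    ("ridge", "cv"),
)

# path-fit tolerances: looser than a single final fit, tight enough that
# selected supports are stable in the tested regimes
_PATH_TOL = 1e-3
_PATH_MAX_ITER = 100


@dataclass(frozen=True)
class LambdaGrid:
    values: np.ndarray
    spacing: str  # "equidistant" | "log"
    source: str  # "glasso" | "space" | "glmnet-like"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or np.any(np.diff(v) <= 0) or np.any(v <= 0):
            raise ValueError("grid must be strictly increasing and positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CvCurve:
    """Per-grid-value CV losses: ``loss`` is the sum of ``fold_losses`` rows."""

    grid: LambdaGrid
    fold_losses: np.ndarray  # K x len(grid)
    loss: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.fold_losses = np.asarray(self.fold_losses, dtype=float)
        if self.fold_losses.shape[1] != len(self.grid):
            raise ValueError("fold_losses width must match grid length")
        self.loss = self.fold_losses.sum(axis=0)

    @property
    def k(self) -> int:
        return self.fold_losses.shape[0]

    def se(self, index: int) -> float:
        """Standard error of the loss at one grid value: sd(fold losses)/sqrt(K)."""
        return float(np.std(self.fold_losses[:, index], ddof=1) / np.sqrt(self.k))


@dataclass
class TuningResult:
    """Outcome of one selection: grid, criterion values, chosen value, rule."""

    grid: LambdaGrid
    criterion: np.ndarray
    selected: float
    selected_index: int
    rule: str
    fold_losses: np.ndarray | None = None
    had_nan: bool = False

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "grid": self.grid.values.tolist(),
            "criterion": np.asarray(self.criterion, dtype=float).tolist(),
            "selected": self.selected,
            "selected_index": int(self.selected_index),
            "had_nan": self.had_nan,
        }


def make_folds(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold labels in [0, k) by seeded random permutation; sizes differ by <= 1."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= K <= n, got K={k}, n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    labels = np.empty(n, dtype=int)
    labels[perm] = np.arange(n) % k
    return labels


# ---------------------------------------------------------------------------
# grids


def glasso_grid(S: np.ndarray, p: int | None = None) -> LambdaGrid:
    """100 equidistant penalties from 0.001 (0.05 when p >= 100) to max|S|.

    The upper endpoint is the maximum absolute entry of S (diagonal
    included), which is at least the largest off-diagonal and therefore
    guarantees the path reaches the empty model.
    """
    S = validate_covariance(S)
    if p is None:
        p = S.shape[0]
    lo = 0.001 if p < 100 else 0.05
    hi = float(np.abs(S).max())
    if hi <= lo:
        raise ValueError(f"degenerate penalty grid: max|S|={hi:g} <= {lo}")
    return LambdaGrid(np.linspace(lo, hi, GRID_SIZE), "equidistant", "glasso")


def space_grid(n: int, p: int) -> LambdaGrid:
    """100 equidistant values from sqrt(n) Phi^-1(1 - 0.9/2p^2) to sqrt(n) Phi^-1(1 - 1e-4/2p^2)."""
    if n < 2 or p < 2:
        raise ValueError("need n >= 2 and p >= 2")
    lo = np.sqrt(n) * norm.ppf(1 - 0.9 / (2 * p**2))
    hi = np.sqrt(n) * norm.ppf(1 - 1e-4 / (2 * p**2))
    return LambdaGrid(np.linspace(lo, hi, GRID_SIZE), "equidistant", "space")


def glmnet_like_grid(X: np.ndarray, node: int, ratio: float | None = None) -> LambdaGrid:
    """100 log-spaced penalties for one nodewise regression.

    The upper endpoint is the smallest penalty that zeroes every weight of
    the node's lasso problem, ``max_j |X_j' X_i| / n`` on the
    per-observation loss scale; the lower endpoint is ``ratio`` times
    that, with ratio 1e-4 when n > p and 1e-2 otherwise (the glmnet
    defaults).
    """
    n, p = X.shape
    y = X[:, node]
    if np.allclose(y.std(), 0):
        raise ValueError(f"constant response column {node}")
    others = [j for j in range(p) if j != node]
    lam_max = float(np.abs(X[:, others].T @ y).max() / n)
    if lam_max <= 0:
        raise ValueError(f"degenerate grid for node {node}: all inner products zero")
    if ratio is None:
        ratio = 1e-4 if n > p else 1e-2
    values = np.geomspace(ratio * lam_max, lam_max, GRID_SIZE)
    return LambdaGrid(values, "log", "glmnet-like")


# ---------------------------------------------------------------------------
# selection rules


def _argmin_largest(values: np.ndarray) -> int:
    """Index of the minimum; ties broken toward the largest grid value."""
    values = np.asarray(values, dtype=float)
    finite = np.where(np.isfinite(values))[0]
    if len(finite) == 0:
        raise ValueError("no finite criterion values")
    vmin = values[finite].min()
    return int(finite[values[finite] <= vmin][-1])


def cv_select(curve: CvCurve, rule: str = "min") -> TuningResult:
    """Pick a grid value from a CV curve by the min or one-standard-error rule.

    ``one_se`` returns the largest grid value whose loss does not exceed
    the minimum loss plus one standard error of the per-fold losses at the
    minimizer; on a flat curve this is the largest grid value.
    """
    if rule not in ("min", "one_se"):
        raise ValueError("rule must be 'min' or 'one_se'")
    loss = curve.loss
    had_nan = bool(np.isnan(loss).any())
    idx = _argmin_largest(loss)
    if rule == "one_se":
        band = loss[idx] + curve.se(idx)
        ok = np.where(np.isfinite(loss) & (loss <= band))[0]
        idx = int(ok[-1])
    return TuningResult(
        grid=curve.grid,
        criterion=loss,
        selected=float(curve.grid.values[idx]),
        selected_index=idx,
        rule="cv" if rule == "min" else "cv-1se",
        fold_losses=curve.fold_losses,
        had_nan=had_nan,
    )


# ---------------------------------------------------------------------------
# graphical lasso tuning


def _fold_cov(X: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Sample covariance of a subset of rows, fold-centered, 1/n_k normalized."""
    sub = X[rows]
    if sub.shape[0] < 2:
        raise ValueError(f"fold of size {sub.shape[0]} is too small for a covariance")
    return np.cov(sub, rowvar=False, bias=True)


def _glasso_path(S: np.ndarray, grid: LambdaGrid) -> list:
    """Fit the whole penalty path; failed fits are recorded as None."""
    fits = []
    for lam in grid.values:
        try:
            fits.append(fit_glasso(S, lam, tol=_PATH_TOL, max_iter=_PATH_MAX_ITER))
        except (RuntimeError, np.linalg.LinAlgError):
            fits.append(None)
    return fits


def cv1_glasso(X: np.ndarray, grid: LambdaGrid, folds: np.ndarray) -> CvCurve:
    """K-fold CV with the Gaussian likelihood loss tr(S_k Omega) - log det Omega."""
    k = int(folds.max()) + 1
    losses = np.full((k, len(grid)), np.nan)
    for fold in range(k):
        test = folds == fold
        S_train = _fold_cov(X, ~test)
        S_test = _fold_cov(X, test)
        for a, fit in enumerate(_glasso_path(S_train, grid)):
            if fit is None:
                continue
            sign, logdet = np.linalg.slogdet(fit.omega)
            if sign <= 0:
                continue
            losses[fold, a] = float(np.sum(S_test * fit.omega)) - logdet
    return CvCurve(grid=grid, fold_losses=losses)


def cv2_glasso(X: np.ndarray, grid: LambdaGrid, folds: np.ndarray) -> CvCurve:
    """K-fold CV with the summed nodewise prediction error of the implied regressions.

    The precision fit on the training folds implies regression weights
    ``-omega_ij / omega_ii``; the loss is the held-out squared prediction
    error summed over nodes.
    """
    k = int(folds.max()) + 1
    losses = np.full((k, len(grid)), np.nan)
    for fold in range(k):
        test = folds == fold
        S_train = _fold_cov(X, ~test)
        X_test = X[test]
        for a, fit in enumerate(_glasso_path(S_train, grid)):
            if fit is None:
                continue
            d = np.diag(fit.omega)
            if np.any(d <= 0):
                continue
            B = -fit.omega / d[:, None]  # row i: weights of the regression of X_i
            np.fill_diagonal(B, 0.0)
            resid = X_test - X_test @ B.T
            losses[fold, a] = float((resid**2).sum())
    return CvCurve(grid=grid, fold_losses=losses)


def ebic_glasso(
    X: np.ndarray,
    grid: LambdaGrid,
    gamma: float = 0.5,
    edge_tol: float = 1e-8,
) -> TuningResult:
    """(E)BIC selection on the glasso path fitted to the full-sample covariance.

    ``EBIC = -2 loglik + kappa log n + 4 kappa gamma log p``; gamma = 0 is
    the classical BIC.  ``kappa`` is the count of non-zero off-diagonal
    entries of the estimated precision matrix — both symmetric entries of
    an edge, i.e. twice the edge count.  (With kappa equal to the edge
    count the criterion keeps moderately dense chain networks even at
    p=60, n=100; the doubled count is the convention consistent with the
    near-empty networks this selector is known to produce in that regime.)
    """
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must be in [0, 1]")
    n, p = X.shape
    S = np.cov(X, rowvar=False, bias=True)
    crit = np.full(len(grid), np.nan)
    for a, fit in enumerate(_glasso_path(S, grid)):
        if fit is None:
            continue
        kappa = 2 * len(edge_set(fit.partial_correlations(), edge_tol))
        ll = gaussian_loglik(S, fit.omega, n)
        crit[a] = -2.0 * ll + kappa * np.log(n) + 4.0 * kappa * gamma * np.log(p)
    idx = _argmin_largest(crit)
    return TuningResult(
        grid=grid,
        criterion=crit,
        selected=float(grid.values[idx]),
        selected_index=idx,
        rule="ebic" if gamma > 0 else "bic",
        had_nan=bool(np.isnan(crit).any()),
    )


# ---------------------------------------------------------------------------
# nodewise tuning


def cv_nodewise(
    X: np.ndarray,
    node: int,
    grid: LambdaGrid,
    folds: np.ndarray,
    penalty: str = "lasso",
) -> CvCurve:
    """K-fold held-out squared prediction error for one nodewise regression."""
    if penalty not in ("lasso", "ridge"):
        raise ValueError("penalty must be 'lasso' or 'ridge'")
    n, p = X.shape
    k = int(folds.max()) + 1
    others = [j for j in range(p) if j != node]
    losses = np.zeros((k, len(grid)))
    for fold in range(k):
        test = folds == fold
        X_train, X_test = X[~test], X[test]
        if penalty == "lasso":
            path = _lasso_path_node(X_train, node, grid.values)  # (L, p)
            W = path[:, others]
        else:
            W = _ridge_path_node(X_train, node, grid.values)
        pred = X_test[:, others] @ W.T  # n_test x L
        losses[fold] = ((X_test[:, node][:, None] - pred) ** 2).sum(axis=0)
    return CvCurve(grid=grid, fold_losses=losses)


def _ridge_path_node(X: np.ndarray, node: int, lambdas: np.ndarray) -> np.ndarray:
    """Ridge weights of one node for a whole per-observation penalty grid.

    One eigendecomposition of the Gram matrix gives the entire path:
    ``delta(lam) = V diag(1/(e + 2 n lam)) V' X' y`` for the per-observation
    penalty ``lam`` (equivalent to lambda4 = n*lam on the unscaled loss).
    """
    n, p = X.shape
    others = [j for j in range(p) if j != node]
    G = X[:, others].T @ X[:, others]
    b = X[:, others].T @ X[:, node]
    evals, vecs = np.linalg.eigh(G)
    vb = vecs.T @ b
    out = np.empty((len(lambdas), p - 1))
    for a, lam in enumerate(lambdas):
        out[a] = vecs @ (vb / (evals + 2 * n * lam))
    return out


def bic_nodewise(X: np.ndarray, node: int, grid: LambdaGrid) -> TuningResult:
    """BIC selection for one nodewise lasso: ||residual||^2 + k log n.

    The unit-variance Gaussian BIC; k is the size of the selected
    neighborhood.
    """
    n, p = X.shape
    others = [j for j in range(p) if j != node]
    path = _lasso_path_node(X, node, grid.values)
    resid = X[:, node][:, None] - X[:, others] @ path[:, others].T
    rss = (resid**2).sum(axis=0)
    kappa = (np.abs(path[:, others]) > 0).sum(axis=1)
    crit = rss + kappa * np.log(n)
    idx = _argmin_largest(crit)
    return TuningResult(
        grid=grid,
        criterion=crit,
        selected=float(grid.values[idx]),
        selected_index=idx,
        rule="bic",
    )


def fsr_lambda(n: int, p: int, alpha: float = 0.05, family: str = "nr") -> float:
    """Closed-form penalty bounding the expected false positives per neighborhood.

    ``nr``:    lambda2(alpha) = (2 / sqrt(n)) Phi^-1(1 - alpha / 2p^2)
    ``space``: lambda3(alpha) = sqrt(n)     Phi^-1(1 - alpha / 2p^2)

    The nodewise form lives on the per-observation loss scale, the SPACE
    form on the unscaled joint loss, matching each estimator's convention.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if family not in ("nr", "space"):
        raise ValueError("family must be 'nr' or 'space'")
    q = norm.ppf(1 - alpha / (2 * p**2))
    return float(2 / np.sqrt(n) * q) if family == "nr" else float(np.sqrt(n) * q)


# ---------------------------------------------------------------------------
# SPACE tuning


def _space_path(X: np.ndarray, grid: LambdaGrid, **kwargs) -> list:
    """SPACE fits over the grid, warm-started from large to small penalties."""
    fits = [None] * len(grid)
    gamma_init = None
    omega_init = None
    for a in range(len(grid) - 1, -1, -1):
        fit = fit_space(X, grid.values[a], gamma_init=gamma_init, omega_init=omega_init, **kwargs)
        rho = fit.gamma.copy()
        np.fill_diagonal(rho, 0.0)
        gamma_init, omega_init = rho, fit.omega_diag
        fits[a] = fit
    return fits


def _space_rss(X: np.ndarray, fit, X_eval: np.ndarray) -> np.ndarray:
    """Per-node squared prediction error of a SPACE fit on held-out rows."""
    from .estimators import _space_weights

    rho = fit.gamma.copy()
    np.fill_diagonal(rho, 0.0)
    C = _space_weights(rho, fit.omega_diag)
    resid = X_eval - X_eval @ C.T
    return (resid**2).sum(axis=0)


def cv_space(X: np.ndarray, grid: LambdaGrid, folds: np.ndarray, **kwargs) -> CvCurve:
    """K-fold CV for SPACE: held-out prediction error of rho_ij sqrt(w_j/w_i) weights."""
    k = int(folds.max()) + 1
    losses = np.zeros((k, len(grid)))
    for fold in range(k):
        test = folds == fold
        for a, fit in enumerate(_space_path(X[~test], grid, **kwargs)):
            losses[fold, a] = float(_space_rss(X, fit, X[test]).sum())
    return CvCurve(grid=grid, fold_losses=losses)


def bic_space(X: np.ndarray, grid: LambdaGrid, edge_tol: float = 1e-8, **kwargs) -> TuningResult:
    """BIC for SPACE: sum over nodes of ||residual||^2 + k_i log n."""
    n, p = X.shape
    crit = np.empty(len(grid))
    for a, fit in enumerate(_space_path(X, grid, **kwargs)):
        rss = _space_rss(X, fit, X)
        nbrs = (np.abs(fit.gamma - np.eye(p)) > edge_tol).sum(axis=1)
        crit[a] = float(rss.sum() + np.log(n) * nbrs.sum())
    idx = _argmin_largest(crit)
    return TuningResult(
        grid=grid,
        criterion=crit,
        selected=float(grid.values[idx]),
        selected_index=idx,
        rule="bic",
    )


# ---------------------------------------------------------------------------
# high-level selection


def tune_lambda(
    X: np.ndarray,
    method: str,
    tuning: str,
    folds: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
    gamma: float = 0.5,
    alpha: float = 0.05,
) -> tuple:
    """Select the regularization for one method/tuning combination.

    Returns ``(lam, details)`` where ``lam`` is a scalar for glasso/space
    and a per-node array for the regression methods, and ``details`` is a
    TuningResult (or list of per-node TuningResults).
    """
    n, p = X.shape
    if folds is None and tuning in ("cv", "cv-1se", "cv2", "cv2-1se"):
        folds = make_folds(n, k, seed)

    if method == "glasso":
        S = np.cov(X, rowvar=False, bias=True)
        grid = glasso_grid(S, p)
        if tuning in ("cv", "cv-1se"):
            curve = cv1_glasso(X, grid, folds)
            res = cv_select(curve, "min" if tuning == "cv" else "one_se")
        elif tuning in ("cv2", "cv2-1se"):
            curve = cv2_glasso(X, grid, folds)
            res = cv_select(curve, "min" if tuning == "cv2" else "one_se")
        elif tuning == "bic":
            res = ebic_glasso(X, grid, gamma=0.0)
        elif tuning == "ebic":
            res = ebic_glasso(X, grid, gamma=gamma)
        else:
            raise ValueError(f"unsupported tuning {tuning!r} for glasso")
        return res.selected, res

    if method == "space":
        grid = space_grid(n, p)
        if tuning in ("cv", "cv-1se"):
            curve = cv_space(X, grid, folds)
            res = cv_select(curve, "min" if tuning == "cv" else "one_se")
        elif tuning == "bic":
            res = bic_space(X, grid)
        elif tuning == "fsr":
            lam = fsr_lambda(n, p, alpha, "space")
            return lam, None
        else:
            raise ValueError(f"unsupported tuning {tuning!r} for space")
        return res.selected, res

    if method in ("nr-and", "nr-or", "ridge"):
        penalty = "ridge" if method == "ridge" else "lasso"
        if tuning == "fsr":
            if method == "ridge":
                raise ValueError("FSR is not defined for ridge")
            lam = fsr_lambda(n, p, alpha, "nr")
            return np.full(p, lam), None
        if tuning == "bic":
            if method == "ridge":
                raise ValueError("BIC tuning is not used for ridge")
            results = [bic_nodewise(X, i, glmnet_like_grid(X, i)) for i in range(p)]
        elif tuning in ("cv", "cv-1se"):
            rule = "min" if tuning == "cv" else "one_se"
            results = []
            for i in range(p):
                grid = glmnet_like_grid(X, i)
                curve = cv_nodewise(X, i, grid, folds, penalty=penalty)
                results.append(cv_select(curve, rule))
        else:
            raise ValueError(f"unsupported tuning {tuning!r} for {method}")
        lam = np.array([r.selected for r in results])
        if method == "ridge":
            # convert per-observation penalty to the unscaled-loss lambda4
            lam = n * lam
        return lam, results

    raise ValueError(f"unknown method {method!r}")


def tuned_network(
    X: np.ndarray,
    method: str,
    tuning: str,
    folds: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
    gamma: float = 0.5,
    alpha: float = 0.05,
) -> FirstStageFit:
    """Tune the penalty and fit the first-stage network on the full sample."""
    lam, _ = tune_lambda(X, method, tuning, folds=folds, k=k, seed=seed, gamma=gamma, alpha=alpha)
    return estimate_network(X, method, lam)
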