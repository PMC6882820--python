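"""Partial correlation screening (PCS): cross-validated thresholding.

Sparse first-stage estimators of a Gaussian graphical model tend to keep
too many edges.  PCS post-processes any first-stage estimate: every
partial correlation with ``|rho_ij| <= tau`` is removed, and the cutoff
``tau`` is chosen by K-fold cross-validation of the prediction error of
per-node OLS refits on the screened neighborhoods.

The selection is a double loop.  The regularization penalty of the first
stage is chosen once, on the full sample.  Then, for each fold, the first
stage is re-estimated at that fixed penalty on the retained folds; for
every threshold on a fixed grid (100 equidistant values in
[0.0001, 1]) the surviving neighborhoods are refit by OLS on the same
training rows and scored on the held-out fold.  The threshold minimizing
the summed held-out error wins, ties going to the largest threshold
(sparsest network).

Screening can only delete edges, so a first stage that already misses
true edges cannot be repaired; PCS targets false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EdgeSet, edge_set
from .estimators import FirstStageFit, estimate_network
from .tuning import TuningResult, make_folds, tune_lambda

__all__ = [
    "tau_grid",
    "screen",
    "refit_ols",
    "select_tau",
    "pcs_pipeline",
    "ScreenedNetwork",
    "TauCurve",
]


def tau_grid(size: int = 100) -> np.ndarray:
    """Equidistant threshold grid from 0.0001 to 1."""
    return np.linspace(0.0001, 1.0, size)


def screen(gamma_hat: np.ndarray, tau: float) -> EdgeSet:
    """Edges whose estimated partial correlation exceeds tau in absolute value.

    Strict inequality, so the result is always a subset of the first-stage
    support and is monotone decreasing in tau.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    return edge_set(gamma_hat, tol=tau)


def refit_ols(
    X: np.ndarray, neighborhoods: list
) -> tuple[dict, np.ndarray, bool]:
    """OLS refit of every node on its screened neighborhood.

    Returns ``(theta, residuals, saturated)``: ``theta[i]`` maps each
    neighbor index to its weight (empty neighborhood -> zero prediction),
    ``residuals`` is the n x p matrix of refit residuals, and
    ``saturated`` flags any node whose neighborhood size reached the row
    count (solved by minimum-norm least squares).
    """
    n, p = X.shape
    theta: dict = {}
    resid = X.copy()
    saturated = False
    for i, nbrs in enumerate(neighborhoods):
        nbrs = sorted(nbrs)
        if not nbrs:
            theta[i] = {}
            continue
        if len(nbrs) >= n:
            saturated = True
        A = X[:, nbrs]
        coef, *_ = np.linalg.lstsq(A, X[:, i], rcond=None)
        theta[i] = dict(zip(nbrs, coef.tolist()))
        resid[:, i] = X[:, i] - A @ coef
    return theta, resid, saturated


@dataclass
class TauCurve:
    """CV loss over the threshold grid (summed over folds and nodes)."""

    taus: np.ndarray
    loss: np.ndarray
    selected: float
    selected_index: int
    degenerate: bool = False  # every threshold emptied every per-fold network


@dataclass
class ScreenedNetwork:
    """Final PCS output: screened edges plus all reporting artifacts."""

    method: str
    tuning: str
    lam: object
    tau: float
    edges: EdgeSet
    gamma: np.ndarray  # first-stage partial correlations with screened entries zeroed
    theta: dict
    first_stage: FirstStageFit = field(repr=False)
    tau_curve: TauCurve | None = field(default=None, repr=False)
    lambda_details: object = field(default=None, repr=False)

    @property
    def neighborhoods(self) -> list:
        return self.edges.neighborhoods()


def _fold_loss_over_taus(
    X_train: np.ndarray,
    X_test: np.ndarray,
    gamma_hat: np.ndarray,
    taus: np.ndarray,
) -> np.ndarray:
    """Held-out loss for every threshold, one training fit.

    The loss is piecewise constant in tau with breakpoints at the sorted
    |rho_hat| values, so each distinct neighborhood pattern is refit once
    and cached by its support signature.
    """
    p = gamma_hat.shape[0]
    absg = np.abs(gamma_hat).copy()
    np.fill_diagonal(absg, 0.0)
    losses = np.empty(len(taus))
    cache: dict = {}
    node_cache: dict = {}
    for t_idx, tau in enumerate(taus):
        nbr_sets = tuple(
            tuple(np.where(absg[i] > tau)[0].tolist()) for i in range(p)
        )
        if nbr_sets in cache:
            losses[t_idx] = cache[nbr_sets]
            continue
        total = 0.0
        for i, nbrs in enumerate(nbr_sets):
            key = (i, nbrs)
            if key not in node_cache:
                if nbrs:
                    A = X_train[:, list(nbrs)]
                    coef, *_ = np.linalg.lstsq(A, X_train[:, i], rcond=None)
                    pred = X_test[:, list(nbrs)] @ coef
                else:
                    pred = 0.0
                node_cache[key] = float(((X_test[:, i] - pred) ** 2).sum())
            total += node_cache[key]
        cache[nbr_sets] = total
        losses[t_idx] = total
    return losses


def select_tau(
    X: np.ndarray,
    method: str,
    lam,
    folds: np.ndarray,
    taus: np.ndarray | None = None,
    estimator_kwargs: dict | None = None,
) -> TauCurve:
    """Cross-validate the screening threshold with the first-stage penalty fixed.

    ``lam`` is the penalty already selected on the full sample.  For each
    fold the first stage is re-estimated on the retained rows at that
    penalty, the thresholded neighborhoods are refit by OLS on the same
    rows, and the held-out prediction error is accumulated.
    """
    if taus is None:
        taus = tau_grid()
    estimator_kwargs = estimator_kwargs or {}
    k = int(folds.max()) + 1
    loss = np.zeros(len(taus))
    any_edges = False
    for fold in range(k):
        test = folds == fold
        first = estimate_network(X[~test], method, lam, **estimator_kwargs)
        if len(first.edges):
            any_edges = True
        loss += _fold_loss_over_taus(X[~test], X[test], first.gamma, taus)
    finite_min = loss.min()
    ties = np.where(loss <= finite_min + 1e-9 * max(1.0, abs(finite_min)))[0]
    idx = int(ties[-1])
    degenerate = not any_edges
    if degenerate:
        idx = 0  # every candidate equivalent; report the smallest threshold
    return TauCurve(
        taus=np.asarray(taus, dtype=float),
        loss=loss,
        selected=float(taus[idx]),
        selected_index=idx,
        degenerate=degenerate,
    )


def pcs_pipeline(
    X: np.ndarray,
    method: str,
    tuning: str,
    k: int = 10,
    seed: int = 0,
    gamma: float = 0.5,
    alpha: float = 0.05,
    taus: np.ndarray | None = None,
    folds: np.ndarray | None = None,
) -> ScreenedNetwork:
    """Full PCS run: tune penalty, fit first stage, select tau, screen, refit.

    The same seeded fold assignment is used for the penalty CV and the
    threshold CV unless ``folds`` overrides it.  The reported gamma keeps
    the first-stage partial correlation values on the surviving edges.
    """
    n, p = X.shape
    if folds is None:
        folds = make_folds(n, k, seed)
    lam, details = tune_lambda(
        X, method, tuning, folds=folds, k=k, seed=seed, gamma=gamma, alpha=alpha
    )
    first = estimate_network(X, method, lam)
    curve = select_tau(X, method, lam, folds, taus=taus)
    edges = screen(first.gamma, curve.selected)
    edges = EdgeSet(edges.pairs & first.edges.pairs, p)  # never add edges
    gamma_screened = np.where(edges.adjacency().astype(bool), first.gamma, 0.0)
    np.fill_diagonal(gamma_screened, 1.0)
    theta, _, _ = refit_ols(X, edges.neighborhoods())
    return ScreenedNetwork(
        method=method,
        tuning=tuning,
        lam=lam,
        tau=curve.selected,
        edges=edges,
        gamma=gamma_screened,
        theta=theta,
        first_stage=first,
        tau_curve=curve,
        lambda_details=details,
    )
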