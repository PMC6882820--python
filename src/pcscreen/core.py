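"""Core types and conversions for partial-correlation networks.

A Gaussian graphical model (GGM) on variables ``X_1 .. X_p`` is encoded by
any one of three equivalent objects:

* the precision matrix ``Omega = Sigma^{-1}`` (inverse covariance),
* the matrix of nodewise regression weights ``beta[i, j]`` (weight of
  ``X_j`` in the best linear predictor of ``X_i`` from the rest), and
* the partial correlation matrix ``Gamma`` with entries
  ``rho_ij = -omega_ij / sqrt(omega_ii * omega_jj)``.

An edge ``{i, j}`` of the network is a non-zero partial correlation; under
Gaussianity it marks conditional dependence of ``X_i`` and ``X_j`` given
all remaining variables.  This module holds the conversions between the
three representations, the edge-set container, and the true/false positive
rates used to score edge recovery against a known network.

Matrices are plain ``numpy`` arrays indexed from 0 internally; user-facing
output (edge tables) is 1-indexed unless column labels are given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "EdgeSet",
    "RecoveryMetrics",
    "center_columns",
    "validate_data",
    "validate_covariance",
    "precision_to_partial",
    "partial_to_precision",
    "regression_to_partial",
    "edge_set",
    "recovery_metrics",
]

#: Default tolerance below which an estimated partial correlation is
#: treated as an exact zero.  Lasso-type solvers produce exact zeros, so
#: this only has to clear solver noise; ridge produces no exact zeros and
#: therefore yields complete graphs at this tolerance, by construction.
EDGE_TOL = 1e-8


def center_columns(X: np.ndarray, standardize: bool = False) -> np.ndarray:
    """Subtract the column means (and optionally divide by column SDs).

    The estimation objectives carry no intercepts, so data are centered
    once at ingestion.  Scaling to unit variance is optional and off by
    default.
    """
    X = np.asarray(X, dtype=float)
    out = X - X.mean(axis=0)
    if standardize:
        sd = out.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("cannot standardize: constant column present")
        out = out / sd
    return out


def validate_data(X: np.ndarray) -> np.ndarray:
    """Check an n x p data matrix: shape, finiteness, non-constant columns."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"data matrix must be 2-D, got shape {X.shape}")
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError(f"need n >= 2 and p >= 2, got n={n}, p={p}")
    if not np.isfinite(X).all():
        raise ValueError("data matrix contains NaN or infinite values")
    if np.any(X.std(axis=0) == 0):
        bad = np.where(X.std(axis=0) == 0)[0]
        raise ValueError(f"constant column(s) at index {bad.tolist()}")
    return X


def validate_covariance(S: np.ndarray, sym_tol: float = 1e-10) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance matrix must be square")
    if not np.allclose(S, S.T, atol=sym_tol * max(1.0, np.abs(S).max())):
        raise ValueError("covariance matrix is not symmetric")
    if np.any(np.diag(S) <= 0):
        raise ValueError("covariance matrix has non-positive diagonal entries")
    return 0.5 * (S + S.T)


@dataclass(frozen=True)
class EdgeSet:
    """An undirected network: unordered node pairs on ``p`` nodes (0-indexed)."""

    pairs: frozenset
    p: int

    def __post_init__(self) -> None:
        for i, j in self.pairs:
            if not (0 <= i < j < self.p):
                raise ValueError(f"invalid edge ({i}, {j}) for p={self.p}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], p: int) -> "EdgeSet":
        norm = frozenset((min(i, j), max(i, j)) for i, j in pairs)
        return cls(norm, p)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def __iter__(self):
        return iter(sorted(self.pairs))

    def union(self, other: "EdgeSet") -> "EdgeSet":
        self._check_p(other)
        return EdgeSet(self.pairs | other.pairs, self.p)

    def intersection(self, other: "EdgeSet") -> "EdgeSet":
        self._check_p(other)
        return EdgeSet(self.pairs & other.pairs, self.p)

    def issubset(self, other: "EdgeSet") -> bool:
        return self.pairs <= other.pairs

    def neighborhoods(self) -> list:
        """Per-node neighbor index sets implied by the edge pairs."""
        nbrs = [set() for _ in range(self.p)]
        for i, j in self.pairs:
            nbrs[i].add(j)
            nbrs[j].add(i)
        return nbrs

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.p, self.p), dtype=int)
        for i, j in self.pairs:
            A[i, j] = A[j, i] = 1
        return A

    def _check_p(self, other: "EdgeSet") -> None:
        if self.p != other.p:
            raise ValueError(f"node count mismatch: {self.p} != {other.p}")


@dataclass(frozen=True)
class RecoveryMetrics:
    """Edge-recovery confusion counts and rates against a known network.

    ``tpr = tp / (tp + fn)`` over the true edges and
    ``fpr = fp / (tn + fp)`` over the true non-edges; a rate whose
    denominator is zero is reported as NaN.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float = field(init=False)
    fpr: float = field(init=False)

    def __post_init__(self) -> None:
        pos = self.tp + self.fn
        neg = self.tn + self.fp
        object.__setattr__(self, "tpr", self.tp / pos if pos else float("nan"))
        object.__setattr__(self, "fpr", self.fp / neg if neg else float("nan"))


def precision_to_partial(omega: np.ndarray) -> np.ndarray:
    """Normalize a precision matrix to partial correlations.

    ``rho_ij = -omega_ij / sqrt(omega_ii * omega_jj)`` for ``i != j``;
    the diagonal is 1.  The sign flip makes the off-diagonal entries equal
    to the correlations of the nodewise regression residuals.
    """
    omega = np.asarray(omega, dtype=float)
    d = np.diag(omega)
    if np.any(d <= 0):
        raise ValueError("precision matrix has non-positive diagonal entries")
    scale = np.sqrt(d)
    gamma = -omega / np.outer(scale, scale)
    np.fill_diagonal(gamma, 1.0)
    return gamma


def partial_to_precision(gamma: np.ndarray, omega_diag: np.ndarray | None = None) -> np.ndarray:
    """Rebuild a precision matrix from partial correlations.

    Partial correlations fix Omega only up to its diagonal scale; by
    default the unit-diagonal representative is returned
    (``omega_ij = -rho_ij``), which is the canonical choice when a
    population model is specified through Gamma alone.
    """
    gamma = np.asarray(gamma, dtype=float)
    if omega_diag is None:
        omega_diag = np.ones(gamma.shape[0])
    scale = np.sqrt(np.asarray(omega_diag, dtype=float))
    omega = -gamma * np.outer(scale, scale)
    np.fill_diagonal(omega, omega_diag)
    return omega


def regression_to_partial(beta: np.ndarray, resid_var: np.ndarray | None = None) -> np.ndarray:
    """Partial correlations from nodewise regression weights.

    For population weights ``beta_ij = -omega_ij / omega_ii`` the identity
    ``rho_ij = sign(beta_ij) * sqrt(beta_ij * beta_ji)`` holds.  In finite
    samples the two estimated weights of a pair can disagree in sign, in
    which case the geometric mean is undefined; such pairs are set to 0
    (consistent with the sparsity goal).  A pair with either weight zero
    is likewise 0.

    ``resid_var`` (the per-node residual variances ``1/omega_ii``) is not
    needed for the magnitude and is accepted for validation only.
    """
    beta = np.asarray(beta, dtype=float)
    if resid_var is not None:
        resid_var = np.asarray(resid_var, dtype=float)
        if np.any(resid_var < 0):
            raise ValueError("negative residual variance")
    prod = beta * beta.T
    concordant = (prod > 0) & (np.sign(beta) == np.sign(beta.T))
    gamma = np.where(concordant, np.sign(beta) * np.sqrt(np.abs(prod)), 0.0)
    np.fill_diagonal(gamma, 1.0)
    # numerical guard: |rho| cannot exceed 1 in the population; clip solver noise
    off = ~np.eye(beta.shape[0], dtype=bool)
    gamma[off] = np.clip(gamma[off], -1.0, 1.0)
    return 0.5 * (gamma + gamma.T)


def edge_set(gamma: np.ndarray, tol: float = EDGE_TOL) -> EdgeSet:
    """Support of a partial correlation matrix: pairs with ``|rho_ij| > tol``."""
    gamma = np.asarray(gamma, dtype=float)
    p = gamma.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    mask = np.abs(gamma[iu, ju]) > tol
    pairs = frozenset(zip(iu[mask].tolist(), ju[mask].tolist()))
    return EdgeSet(pairs, p)


def recovery_metrics(estimated: EdgeSet, truth: EdgeSet) -> RecoveryMetrics:
    """Confusion counts of an estimated edge set against the true network.

    Counts are over all p(p-1)/2 unordered pairs, so
    ``tp + fp + tn + fn == p(p-1)/2`` always.
    """
    if estimated.p != truth.p:
        raise ValueError(f"node count mismatch: {estimated.p} != {truth.p}")
    total = truth.p * (truth.p - 1) // 2
    tp = len(estimated.pairs & truth.pairs)
    fp = len(estimated.pairs - truth.pairs)
    fn = len(truth.pairs - estimated.pairs)
    tn = total - tp - fp - fn
    return RecoveryMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
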