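"""Marginal transformations for non-Gaussian data.

The nonparanormal (Gaussian copula) transform replaces every column by
normal scores of its ranks, making rank-preserved but non-normal marginals
(skewed scales, Likert items) amenable to Gaussian graphical modeling.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["nonparanormal"]


def nonparanormal(X: np.ndarray) -> np.ndarray:
    """Truncated (Winsorized) normal-score transform, column by column.

    Each column is mapped through its empirical CDF (midranks, so ties map
    to identical scores), Winsorized at the truncation level
    ``delta_n = 1 / (4 n^{1/4} sqrt(pi log n))`` to tame the extreme
    quantiles, passed through the standard normal quantile function, and
    rescaled to unit variance.  The map is monotone in each column and
    invariant to strictly increasing marginal transformations of the
    input.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant column cannot be transformed")
    delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
    out = np.empty_like(X)
    for j in range(p):
        u = rankdata(X[:, j], method="average") / n
        z = norm.ppf(np.clip(u, delta, 1.0 - delta))
        out[:, j] = z / z.std()
    return out
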