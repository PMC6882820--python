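"""Combining networks estimated by different method/tuning variants.

When several estimation variants are run on the same data (the standard
roster is nineteen method/tuning combinations, each post-processed by
PCS), a consensus network keeps the edges supported by at least
``min_support`` of the individual networks — by default 2, i.e. an edge
must be found by at least two variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EdgeSet
from .pcs import pcs_pipeline
from .tuning import VARIANTS

__all__ = ["NetworkEnsemble", "combine_networks", "run_variant_ensemble", "STANDARD19"]

#: the full 19-variant roster as "method-tuning" labels
STANDARD19 = tuple(f"{m}-{t}" for m, t in VARIANTS)


@dataclass
class NetworkEnsemble:
    networks: list  # list[EdgeSet]
    labels: list

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("ensemble needs at least one network")
        ps = {net.p for net in self.networks}
        if len(ps) != 1:
            raise ValueError(f"networks disagree on node count: {sorted(ps)}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate ensemble labels")
        if len(self.labels) != len(self.networks):
            raise ValueError("labels/networks length mismatch")

    @property
    def p(self) -> int:
        return self.networks[0].p


def combine_networks(ensemble: NetworkEnsemble, min_support: int = 2) -> EdgeSet:
    """Edges occurring in at least ``min_support`` ensemble members.

    ``min_support=1`` is the union, ``min_support=len(ensemble)`` the
    intersection.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    counts: dict = {}
    for net in ensemble.networks:
        for pair in net.pairs:
            counts[pair] = counts.get(pair, 0) + 1
    keep = {pair for pair, c in counts.items() if c >= min_support}
    return EdgeSet(frozenset(keep), ensemble.p)


def run_variant_ensemble(
    X: np.ndarray,
    variants=STANDARD19,
    k: int = 10,
    seed: int = 0,
    pcs: bool = True,
    **kwargs,
) -> NetworkEnsemble:
    """Run every variant (PCS by default) on one dataset and collect the networks."""
    from .simulation import _parse_variant
    from .tuning import tuned_network

    networks, labels = [], []
    for label in variants:
        method, tuning = _parse_variant(label)
        if pcs:
            net = pcs_pipeline(X, method, tuning, k=k, seed=seed, **kwargs)
            networks.append(net.edges)
        else:
            networks.append(tuned_network(X, method, tuning, k=k, seed=seed, **kwargs).edges)
        labels.append(label)
    return NetworkEnsemble(networks=networks, labels=labels)
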