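"""Matrix, edge-list and report I/O.

Data matrices and square matrices travel as CSV/TSV with a header row of
variable names; square matrices also carry row labels so they round-trip.
Edge lists are TSV with columns ``node_i``, ``node_j``,
``partial_correlation`` — 1-indexed node numbers unless variable names are
available.  Run reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EdgeSet

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_edges",
    "read_edges",
    "write_report",
    "edges_to_frame",
    "export_graphml",
]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_matrix(path, square: bool = False) -> tuple[np.ndarray, list]:
    """Read a numeric matrix; returns (values, column names).

    ``square=True`` expects row labels in the first column (as written by
    :func:`write_matrix`).  NaN cells and non-numeric columns are
    rejected with a descriptive error.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0 if square else None,
        float_precision="round_trip",
    )
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path}: non-numeric column(s) {bad}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values present")
    values = df.to_numpy(dtype=float)
    if square and values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {values.shape}")
    return values, [str(c) for c in df.columns]


def write_matrix(path, values: np.ndarray, names: list | None = None, square: bool = False) -> None:
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if names is None:
        names = [f"V{i + 1}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=names)
    if square:
        df.index = pd.Index(names)
    df.to_csv(path, sep=_sep_for(path), index=square, float_format="%.17g")


def edges_to_frame(edges: EdgeSet, gamma: np.ndarray | None = None, names: list | None = None) -> pd.DataFrame:
    """Edge table with 1-indexed nodes (or variable names) and edge weights."""
    rows = []
    for i, j in edges:
        w = float(gamma[i, j]) if gamma is not None else np.nan
        if names is not None:
            rows.append({"node_i": names[i], "node_j": names[j], "partial_correlation": w})
        else:
            rows.append({"node_i": i + 1, "node_j": j + 1, "partial_correlation": w})
    return pd.DataFrame(rows, columns=["node_i", "node_j", "partial_correlation"])


def write_edges(path, edges: EdgeSet, gamma: np.ndarray | None = None, names: list | None = None) -> None:
    edges_to_frame(edges, gamma, names).to_csv(path, sep="\t", index=False)


def read_edge_labels(path) -> list:
    """Raw (node_i, node_j, weight) rows of an edge-list file, labels as strings."""
    df = pd.read_csv(path, sep="\t")
    return [
        (str(a), str(b), float(w))
        for a, b, w in zip(df["node_i"], df["node_j"], df["partial_correlation"])
    ]


def read_edges(path, p: int, names: list | None = None) -> EdgeSet:
    """Edge set from a TSV edge list.

    Node columns are either 1-based integers or variable names; in the
    latter case ``names`` must give the label order.
    """
    pairs = set()
    for a, b, _ in read_edge_labels(path):
        if names is not None:
            i, j = names.index(a), names.index(b)
        else:
            try:
                i, j = int(a) - 1, int(b) - 1
            except ValueError as err:
                raise ValueError(
                    f"{path}: labeled edge list requires the `names` argument"
                ) from err
        pairs.add((min(i, j), max(i, j)))
    return EdgeSet.from_pairs(pairs, p)


def write_report(path, report: dict) -> None:
    """JSON run report: config, seeds, selected penalties/thresholds, curves."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, EdgeSet):
            return sorted([list(pair) for pair in obj.pairs])
        raise TypeError(f"unserializable object of type {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, default=default) + "\n")


def export_graphml(path, edges: EdgeSet, gamma: np.ndarray | None = None, names: list | None = None) -> None:
    """GraphML export for downstream visualization tools."""
    import networkx as nx

    g = nx.Graph()
    labels = names if names is not None else [str(i + 1) for i in range(edges.p)]
    g.add_nodes_from(labels)
    for i, j in edges:
        attrs = {}
        if gamma is not None:
            attrs["partial_correlation"] = float(gamma[i, j])
        g.add_edge(labels[i], labels[j], **attrs)
    nx.write_graphml(g, path)
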