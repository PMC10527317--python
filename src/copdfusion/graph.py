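"""Pearson-correlation feature graph over PB indicators.

Nodes are indicators; an undirected edge joins two indicators whose
absolute Pearson correlation across the *training* samples exceeds the
threshold (default 0.3).  Edges are binary and unweighted in the GNN's
mean aggregation; the correlation is kept for inspection/export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import FeatureTable

__all__ = ["FeatureGraph", "build_feature_graph", "write_edge_list",
           "read_edge_list"]


@dataclass
class FeatureGraph:
    n_nodes: int
    edges: list[tuple[int, int]]
    correlation: list[float] = field(default_factory=list)

    def __post_init__(self):
        for (i, j) in self.edges:
            if i == j:
                raise ValueError(f"self-edge ({i},{j}) not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) out of range")
        if len(set((min(i, j), max(i, j)) for i, j in self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def mean_aggregation_matrix(self) -> np.ndarray:
        """Row-normalised adjacency: (A_norm @ H) is the neighbour mean;
        isolated nodes get the zero vector."""
        a = self.adjacency()
        deg = a.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(deg > 0, a / deg, 0.0)
        return a

    def degree(self) -> np.ndarray:
        return self.adjacency().sum(axis=1).astype(int)


def build_feature_graph(train_table: FeatureTable,
                        threshold: float = 0.3) -> FeatureGraph:
    """Edge (i, j) iff |pearson(x_i, x_j)| > threshold over training samples.

    Constant columns (zero variance) produce no edges.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    x = train_table.values
    if x.shape[0] < 3:
        raise ValueError("need at least 3 training samples to correlate")
    if not np.isfinite(x).all():
        raise ValueError("missing values present; impute before graph building")
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    n = x.shape[1]
    edges, corr = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                continue
            if abs(r[i, j]) > threshold:
                edges.append((i, j))
                corr.append(float(r[i, j]))
    return FeatureGraph(n_nodes=n, edges=edges, correlation=corr)


def write_edge_list(graph: FeatureGraph, path: str | Path,
                    feature_names: list[str] | None = None) -> None:
    lines = ["i\tj\tr"]
    for (i, j), r in zip(graph.edges, graph.correlation):
        a = feature_names[i] if feature_names else str(i)
        b = feature_names[j] if feature_names else str(j)
        lines.append(f"{a}\t{b}\t{r:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path, n_nodes: int,
                   feature_names: list[str] | None = None) -> FeatureGraph:
    lines = Path(path).read_text().strip().splitlines()[1:]
    edges, corr = [], []
    lookup = {n: i for i, n in enumerate(feature_names)} if feature_names else None
    for line in lines:
        a, b, r = line.split("\t")
        i = lookup[a] if lookup else int(a)
        j = lookup[b] if lookup else int(b)
        edges.append((i, j))
        corr.append(float(r))
    return FeatureGraph(n_nodes=n_nodes, edges=edges, correlation=corr)
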