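"""Weighted undirected ceRNA network container."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CeRNANetwork"]

#: columns every edge frame carries; extra statistic columns are preserved
EDGE_KEY = ["gene_a", "gene_b"]


class CeRNANetwork:
    """Undirected weighted graph over genes with per-edge statistics.

    Edges are stored as a DataFrame with at least ``gene_a``, ``gene_b``
    and ``weight`` (strictly positive); pair statistics (partial
    correlation, collective regulation, hypergeometric p, deconvolved
    score) ride along as extra columns. Endpoints are kept in sorted
    order so each unordered pair appears exactly once.
    """

    def __init__(self, edges: pd.DataFrame, nodes: list[str] | None = None):
        if "weight" not in edges.columns or not set(EDGE_KEY) <= set(edges.columns):
            raise ValueError("edge frame needs gene_a, gene_b and weight columns")
        df = edges.copy()
        a = df["gene_a"].astype(str).to_numpy()
        b = df["gene_b"].astype(str).to_numpy()
        if (a == b).any():
            raise ValueError("self-loop edge in network")
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        df["gene_a"], df["gene_b"] = lo, hi
        if df.duplicated(EDGE_KEY).any():
            raise ValueError("duplicate edge in network")
        w = df["weight"].to_numpy(dtype=float)
        if not (np.isfinite(w).all() and (w > 0).all()):
            raise ValueError("edge weights must be finite and strictly positive")
        self.edges = df.sort_values(EDGE_KEY, kind="mergesort").reset_index(drop=True)
        edge_nodes = sorted(set(lo) | set(hi))
        if nodes is None:
            self.nodes = edge_nodes
        else:
            if not set(edge_nodes) <= set(nodes):
                raise ValueError("edge endpoints outside the declared node set")
            self.nodes = sorted(set(map(str, nodes)))

    # -- views -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["gene_a"], self.edges["gene_b"]))

    def degrees(self) -> pd.Series:
        d = pd.Series(0, index=self.nodes, dtype=int)
        counts = pd.concat([self.edges["gene_a"], self.edges["gene_b"]]).value_counts()
        d.loc[counts.index] = counts
        return d

    def neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for a, b in zip(self.edges["gene_a"], self.edges["gene_b"]):
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def adjacency_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dense symmetric weight matrix (zero diagonal) and its node order."""
        pos = {n: i for i, n in enumerate(self.nodes)}
        A = np.zeros((len(self.nodes), len(self.nodes)))
        for a, b, w in zip(self.edges["gene_a"], self.edges["gene_b"],
                           self.edges["weight"]):
            A[pos[a], pos[b]] = A[pos[b], pos[a]] = w
        return A, list(self.nodes)

    def subgraph(self, nodes) -> "CeRNANetwork":
        keep = set(nodes)
        m = self.edges["gene_a"].isin(keep) & self.edges["gene_b"].isin(keep)
        return CeRNANetwork(self.edges.loc[m], nodes=sorted(keep))

    def to_igraph(self):
        import igraph as ig

        g = ig.Graph()
        g.add_vertices(self.nodes)
        g.add_edges(list(zip(self.edges["gene_a"], self.edges["gene_b"])))
        g.es["weight"] = self.edges["weight"].tolist()
        return g

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CeRNANetwork":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str}))

    def __repr__(self) -> str:
        return f"<CeRNANetwork {self.n_nodes} nodes, {self.n_edges} edges>"
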