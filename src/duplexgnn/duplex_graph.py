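"""Duplex graph construction.

The two embedded word sequences of a duplex become one undirected graph:
chain edges join consecutive words within each sequence, and the sequences
are aligned at their starting words so that word i of the miRNA is linked
to word i of the target site for i < min(n, m).  Trailing words of the
longer sequence get no cross edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_encoding import Origin

__all__ = ["DuplexGraph", "build_duplex_graph"]


@dataclass
class DuplexGraph:
    node_features: np.ndarray          # (V, F)
    edges: list[tuple[int, int]]       # undirected, no self-edges, no duplicates
    node_origin: list[Origin]          # per-node sequence of origin tags
    node_position: np.ndarray          # word index within the source sequence

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def save(self, prefix: str | Path) -> None:
        """Dump edge list and feature matrix as plain text (for inspection)."""
        prefix = Path(prefix)
        with open(f"{prefix}.edges.tsv", "w") as fh:
            for u, v in self.edges:
                fh.write(f"{u}\t{v}\n")
        header = "\t".join(f"f{j}" for j in range(self.node_features.shape[1]))
        with open(f"{prefix}.nodes.tsv", "w") as fh:
            fh.write(f"origin\tposition\t{header}\n")
            for i in range(self.n_nodes):
                feats = "\t".join(f"{x:.6g}" for x in self.node_features[i])
                fh.write(f"{self.node_origin[i].value}\t{self.node_position[i]}\t{feats}\n")


def build_duplex_graph(mirna_rows: np.ndarray, mrna_rows: np.ndarray) -> DuplexGraph:
    """Assemble the duplex graph from two embedded word matrices.

    Node 0..n-1 are miRNA words, node n..n+m-1 are target-site words.
    Edge count is (n-1) + (m-1) + min(n, m) and the graph is connected.
    """
    mirna_rows = np.asarray(mirna_rows, dtype=np.float64)
    mrna_rows = np.asarray(mrna_rows, dtype=np.float64)
    if mirna_rows.ndim != 2 or mrna_rows.ndim != 2:
        raise ValueError("feature inputs must be 2-D matrices")
    n, m = mirna_rows.shape[0], mrna_rows.shape[0]
    if n == 0 or m == 0:
        raise ValueError("both sequences must contribute at least one word")
    if mirna_rows.shape[1] != mrna_rows.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {mirna_rows.shape[1]} vs {mrna_rows.shape[1]}")

    edges: list[tuple[int, int]] = []
    edges += [(i, i + 1) for i in range(n - 1)]                 # miRNA chain
    edges += [(n + i, n + i + 1) for i in range(m - 1)]         # site chain
    edges += [(i, n + i) for i in range(min(n, m))]             # aligned cross edges

    return DuplexGraph(
        node_features=np.vstack([mirna_rows, mrna_rows]),
        edges=edges,
        node_origin=[Origin.MIRNA] * n + [Origin.MRNA] * m,
        node_position=np.concatenate([np.arange(n), np.arange(m)]),
    )
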