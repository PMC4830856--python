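"""Weighted closeness centrality for partial-correlation networks.

Edges are read as conduits: the stronger the (absolute) partial correlation,
the shorter the path between two nodes.  Each edge therefore gets length
``1 / |w_ij|`` and closeness is the reciprocal of a node's summed
shortest-path distances to every other node in its connected component:

    c_i = 1 / sum_{j in component(i), j != i} d(i, j).

Negative edges conduct exactly like positive ones (the absolute weight sets
the distance).  Disconnected graphs are handled within components: an
isolated node has closeness 0 and its own component id.  For reporting,
closeness is z-standardised over nodes so that values are comparable across
networks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .exceptions import EstimationError

logger = logging.getLogger(__name__)


@dataclass
class CentralityTable:
    """Per-node raw and z-standardised closeness plus component membership."""

    labels: list[str]
    raw: np.ndarray
    z: np.ndarray
    component: np.ndarray
    network: str = ""

    def to_tsv(self, path: str | Path, k: int = 5) -> None:
        top, bottom = rank_extremes(self, k=min(k, len(self.labels)))
        top_set, bottom_set = set(top), set(bottom)
        with open(path, "w") as fh:
            fh.write("label\traw_closeness\tz_closeness\tcomponent\tmarker\n")
            for i, lab in enumerate(self.labels):
                marker = (
                    "top" if lab in top_set else "bottom" if lab in bottom_set else ""
                )
                fh.write(
                    f"{lab}\t{self.raw[i]:.10g}\t{self.z[i]:.10g}\t"
                    f"{self.component[i]}\t{marker}\n"
                )


def weights_to_distances(weights: np.ndarray) -> np.ndarray:
    """Edge distances d_ij = 1/|w_ij|; absent edges get +inf (no direct hop)."""
    weights = np.asarray(weights, dtype=float)
    if not np.allclose(weights, weights.T, atol=1e-10):
        raise EstimationError("weight matrix must be symmetric")
    if np.any(np.diag(weights) != 0):
        raise EstimationError("weight matrix must have a zero diagonal")
    with np.errstate(divide="ignore"):
        dist = 1.0 / np.abs(weights)
    np.fill_diagonal(dist, 0.0)
    return dist


def closeness(
    weights: np.ndarray, labels: list[str] | None = None, network: str = ""
) -> CentralityTable:
    """Raw and z-standardised closeness of every node of a weighted network."""
    weights = np.asarray(weights, dtype=float)
    p = weights.shape[0]
    if p < 2:
        raise EstimationError("closeness needs at least two nodes")
    labels = list(labels) if labels is not None else [f"v{i}" for i in range(p)]
    dist = weights_to_distances(weights)
    finite = np.where(np.isfinite(dist), dist, 0.0)
    graph = csr_matrix(finite)
    _, comp = connected_components(graph, directed=False)
    sp = shortest_path(graph, method="D", directed=False)
    raw = np.zeros(p)
    for i in range(p):
        mask = (comp == comp[i]) & (np.arange(p) != i)
        if mask.any():
            raw[i] = 1.0 / sp[i, mask].sum()
    z = standardize(raw)
    return CentralityTable(labels=labels, raw=raw, z=z, component=comp, network=network)


def standardize(values: np.ndarray) -> np.ndarray:
    """z-scores with sample SD (n-1); a constant vector maps to zeros."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise EstimationError("need at least two values to standardise")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("constant vector: z-scores set to 0", stacklevel=2)
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def rank_extremes(table: CentralityTable, k: int = 5) -> tuple[list[str], list[str]]:
    """Top-k and bottom-k node labels by z-closeness (ties broken by label)."""
    if k > len(table.labels):
        raise EstimationError("k exceeds the number of nodes")
    order = sorted(
        range(len(table.labels)), key=lambda i: (-table.z[i], table.labels[i])
    )
    z_sorted = [table.z[i] for i in order]
    if len(set(np.round(z_sorted, 12))) < len(z_sorted):
        logger.info("ties in closeness ranking broken lexicographically by label")
    top = [table.labels[i] for i in order[:k]]
    bottom = [table.labels[i] for i in order[-k:]][::-1]
    return top, bottom


def strength(weights: np.ndarray) -> np.ndarray:
    """Node strength (sum of absolute incident weights). Extra, unvalidated index."""
    weights = np.asarray(weights, dtype=float)
    return np.abs(weights).sum(axis=1)


def betweenness(weights: np.ndarray) -> np.ndarray:
    """Betweenness on 1/|w| distances via networkx. Extra, unvalidated index."""
    import networkx as nx

    weights = np.asarray(weights, dtype=float)
    g = nx.Graph()
    p = weights.shape[0]
    g.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if weights[i, j] != 0:
                g.add_edge(i, j, distance=1.0 / abs(weights[i, j]))
    bc = nx.betweenness_centrality(g, weight="distance", normalized=True)
    return np.array([bc[i] for i in range(p)])
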