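"""Core in-memory containers shared across the pipeline.

All containers carry string identifier registries alongside their numeric
payload; matrix indices are an internal detail and are never serialized on
their own.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDAG",
    "HeteroGraph",
    "FeatureBlock",
]

SIM_MEASURES = ("seq", "gipk", "functional", "semantic", "integrated")


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate {what} identifiers: {dup[:5]}")


@dataclass
class AssociationMatrix:
    """Binary m x n miRNA-by-disease association matrix.

    ``values[i, j] == 1`` records a confirmed association between
    ``mirna_ids[i]`` and ``disease_ids[j]``; 0 means unknown (not a
    verified negative).
    """

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("association matrix must be at least 1x1")
        if len(self.mirna_ids) != m or len(self.disease_ids) != n:
            raise ValueError("identifier registries do not match matrix shape")
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.disease_ids, "disease")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("association entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mirna_index(self) -> dict[str, int]:
        return {mid: i for i, mid in enumerate(self.mirna_ids)}

    def disease_index(self) -> dict[str, int]:
        return {did: j for j, did in enumerate(self.disease_ids)}

    def positive_pairs(self) -> np.ndarray:
        """(P, 2) array of (mirna_index, disease_index) for every 1-cell."""
        return np.argwhere(self.values == 1)

    def n_zero_cells(self) -> int:
        return int(self.values.size - self.values.sum())

    def disease_sets(self) -> dict[str, set[str]]:
        """Per-miRNA set of associated disease ids (rows of A)."""
        out: dict[str, set[str]] = {}
        for i, mid in enumerate(self.mirna_ids):
            js = np.flatnonzero(self.values[i])
            out[mid] = {self.disease_ids[j] for j in js}
        return out


@dataclass
class SimilarityMatrix:
    """Square symmetric [0, 1] similarity over one entity type."""

    values: np.ndarray
    entity_ids: list[str]
    measure: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.entity_ids)
        if self.values.shape != (k, k):
            raise ValueError("similarity matrix shape does not match ids")
        _check_unique(self.entity_ids, "entity")
        if self.measure not in SIM_MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        asym = np.abs(self.values - self.values.T).max(initial=0.0)
        if asym > 1e-12:
            raise ValueError(f"similarity matrix asymmetric (max dev {asym:g})")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("similarity entries must lie in [0, 1]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.entity_ids)}

    def reorder(self, ids: list[str]) -> "SimilarityMatrix":
        idx = self.index()
        order = [idx[i] for i in ids]
        return SimilarityMatrix(self.values[np.ix_(order, order)], list(ids), self.measure)


@dataclass
class DiseaseDAG:
    """Disease ontology fragment: child->parent edges, decay factor.

    Multiple parents are allowed (a true DAG); every non-root node must
    reach at least one root through parent edges.
    """

    nodes: list[str]
    parent_edges: list[tuple[str, str]]
    decay: float = 0.5

    def __post_init__(self) -> None:
        _check_unique(self.nodes, "DAG node")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")
        node_set = set(self.nodes)
        for c, p in self.parent_edges:
            if c not in node_set or p not in node_set:
                raise ValueError(f"edge ({c!r}, {p!r}) references unknown node")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.parent_edges)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("disease DAG contains a cycle")
        self._graph = g
        self._parents = {n: sorted(g.successors(n)) for n in self.nodes}
        self._children = {n: sorted(g.predecessors(n)) for n in self.nodes}

    def parents(self, node: str) -> list[str]:
        return self._parents[node]

    def children(self, node: str) -> list[str]:
        return self._children[node]

    def ancestors_or_self(self, node: str) -> set[str]:
        if node not in self._parents:
            raise KeyError(f"unknown disease id {node!r}")
        return nx.descendants(self._graph, node) | {node}


@dataclass
class HeteroGraph:
    """Heterogeneous miRNA-disease graph with block adjacency.

    ``block_adjacency`` is the (m+n) x (m+n) matrix [[SS, A], [A^T, DS]]
    with miRNA nodes first.  ``assoc_edges`` are (mirna_idx, disease_idx)
    pairs in matrix coordinates; similarity edges (if thresholded in) are
    intra-type index pairs.  All edges are undirected.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    block_adjacency: np.ndarray
    assoc_edges: np.ndarray  # (E, 2) int: (i, j) into A
    mirna_sim_edges: np.ndarray  # (Em, 2) int pairs i < i'
    disease_sim_edges: np.ndarray  # (Ed, 2) int pairs j < j'
    node_features: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_disease(self) -> int:
        return len(self.disease_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_mirna + self.n_disease

    def disease_node(self, j: int) -> int:
        """Global node index of disease column ``j``."""
        return self.n_mirna + j


@dataclass
class FeatureBlock:
    """Per-type node feature matrices produced by one feature source."""

    mirna_features: np.ndarray
    disease_features: np.ndarray
    source: str  # {"mdmf", "gipk", "similarity"}
    d: int

    def __post_init__(self) -> None:
        self.mirna_features = np.asarray(self.mirna_features, dtype=float)
        self.disease_features = np.asarray(self.disease_features, dtype=float)
        if self.mirna_features.shape[1] != self.d or self.disease_features.shape[1] != self.d:
            raise ValueError("feature dimension does not match d")
        if not (np.isfinite(self.mirna_features).all() and np.isfinite(self.disease_features).all()):
            raise ValueError("non-finite feature values")
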