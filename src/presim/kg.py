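"""Heterogeneous TCM knowledge-graph data model.

A prescription (a fixed multi-herb formulation) is described along three
dimensions: its identity, its disease information (diseases, symptoms,
disease targets) and its herb information (herbs, their pharmacopoeia
attributes — property, flavor, meridian, category — their chemical
ingredients and the ingredient targets).  All of this is held as a typed,
undirected, unweighted graph whose adjacency matrix ``A`` and node-feature
matrix ``X`` feed the GCN encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

#: Closed vocabulary of node types (the dataset's three "dimensions").
NODE_TYPES: tuple[str, ...] = (
    "prescription",
    "disease",
    "symptom",
    "disease_target",
    "herb",
    "property",
    "flavor",
    "meridian",
    "category",
    "ingredient",
    "ingredient_target",
)

#: relation name -> (endpoint type, endpoint type).  Edges are undirected;
#: an edge row may list its endpoints in either order.
RELATIONS: dict[str, tuple[str, str]] = {
    "prescription-disease": ("prescription", "disease"),
    "prescription-symptom": ("prescription", "symptom"),
    "prescription-herb": ("prescription", "herb"),
    "disease-disease_target": ("disease", "disease_target"),
    "herb-property": ("herb", "property"),
    "herb-flavor": ("herb", "flavor"),
    "herb-meridian": ("herb", "meridian"),
    "herb-category": ("herb", "category"),
    "herb-ingredient": ("herb", "ingredient"),
    "ingredient-ingredient_target": ("ingredient", "ingredient_target"),
}

HERB_ATTRIBUTE_TYPES = frozenset({"property", "flavor", "meridian", "category"})

#: Node types entering the Jaccard attribute set by default: macro-level
#: prescription information only, molecular nodes excluded.
DEFAULT_ATTRIBUTE_TYPES = frozenset(
    {"disease", "symptom", "herb"} | HERB_ATTRIBUTE_TYPES
)

PRESCRIPTION_ROLES = ("target", "candidate", "none")


class GraphSchemaError(ValueError):
    """Node/edge table violates the type or relation schema."""


class GraphReferenceError(ValueError):
    """An edge endpoint is not present in the node table."""


@dataclass(frozen=True)
class NodeRecord:
    id: str
    node_type: str
    label: str = ""
    role: str = "none"

    def __post_init__(self):
        if self.node_type not in NODE_TYPES:
            raise GraphSchemaError(f"unknown node_type {self.node_type!r} for node {self.id!r}")
        if self.role not in PRESCRIPTION_ROLES:
            raise GraphSchemaError(f"unknown role {self.role!r} for node {self.id!r}")
        if self.role != "none" and self.node_type != "prescription":
            raise GraphSchemaError(
                f"node {self.id!r}: role {self.role!r} only valid for prescriptions"
            )


@dataclass(frozen=True)
class EdgeRecord:
    source: str
    target: str
    relation: str

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise GraphSchemaError(f"unknown relation {self.relation!r}")
        if self.source == self.target:
            raise GraphSchemaError(f"self-edge on node {self.source!r}")


@dataclass
class KnowledgeGraph:
    """Typed nodes plus a binary symmetric adjacency in input node order."""

    nodes: list[NodeRecord]
    edges: list[EdgeRecord]
    A: sp.csr_matrix
    index: dict[str, int] = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def node(self, node_id: str) -> NodeRecord:
        return self.nodes[self.index[node_id]]

    def neighbors(self, node_id: str) -> list[str]:
        row = self.A.indices[self.A.indptr[self.index[node_id]]:
                             self.A.indptr[self.index[node_id] + 1]]
        return [self.nodes[j].id for j in row]

    def prescriptions(self, role: str | None = None) -> list[str]:
        """Ids of prescription nodes, optionally filtered by role."""
        return [
            n.id
            for n in self.nodes
            if n.node_type == "prescription" and (role is None or n.role == role)
        ]

    def type_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in NODE_TYPES}
        for n in self.nodes:
            counts[n.node_type] += 1
        return counts

    def relation_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.edges:
            counts[e.relation] = counts.get(e.relation, 0) + 1
        return counts


def build_graph(nodes, edges) -> KnowledgeGraph:
    """Assemble a :class:`KnowledgeGraph` from node/edge records.

    Node order is input order (all matrices and embeddings align to it).
    Edges are symmetrized and duplicates collapse to a single 1: the graph
    is unweighted, A_ij = 1 iff an edge joins i and j.
    """
    nodes = [n if isinstance(n, NodeRecord) else NodeRecord(**n) for n in nodes]
    edges = [e if isinstance(e, EdgeRecord) else EdgeRecord(**e) for e in edges]

    index: dict[str, int] = {}
    for n in nodes:
        if n.id in index:
            raise GraphSchemaError(f"duplicate node id {n.id!r}")
        index[n.id] = len(index)

    rows, cols = [], []
    for e in edges:
        for endpoint in (e.source, e.target):
            if endpoint not in index:
                raise GraphReferenceError(
                    f"edge {e.source!r}-{e.target!r}: unknown node {endpoint!r}"
                )
        types = (nodes[index[e.source]].node_type, nodes[index[e.target]].node_type)
        sig = RELATIONS[e.relation]
        if types != sig and types != sig[::-1]:
            raise GraphSchemaError(
                f"edge {e.source!r}-{e.target!r}: endpoint types {types} do not "
                f"match relation {e.relation!r} signature {sig}"
            )
        i, j = index[e.source], index[e.target]
        rows += [i, j]
        cols += [j, i]

    n = len(nodes)
    A = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.float64), (rows, cols)), shape=(n, n)
    ).tocsr()
    A.data[:] = 1.0  # duplicate edges collapse: unweighted graph
    A.sum_duplicates()
    A.data[:] = 1.0
    return KnowledgeGraph(nodes=nodes, edges=edges, A=A, index=index)


def normalize_adjacency(A) -> sp.csr_matrix:
    """Symmetric GCN normalization with self-loops, D̃^{-1/2} (A+I) D̃^{-1/2}.

    Isolated nodes (degree 0 before the self-loop) get a diagonal entry of 1.
    """
    A = sp.csr_matrix(A, dtype=np.float64)
    n, m = A.shape
    if n != m:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    if (A != A.T).nnz != 0:
        raise ValueError("adjacency must be symmetric")
    A_tilde = (A + sp.eye(n, format="csr")).tocsr()
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return (D @ A_tilde @ D).tocsr()


FEATURE_SCHEMES = ("identity", "type-onehot-plus-identity")


def init_features(graph: KnowledgeGraph, scheme: str = "identity") -> sp.csr_matrix:
    """Initial node features X (the dataset carries no numeric node features).

    ``identity``: one-hot per node (X = I, the standard featureless
    transductive setting).  ``type-onehot-plus-identity``: appends an
    11-way node-type indicator, so each row sums to 2.
    """
    n = graph.n_nodes
    if scheme == "identity":
        return sp.eye(n, format="csr")
    if scheme == "type-onehot-plus-identity":
        type_idx = np.array([NODE_TYPES.index(node.node_type) for node in graph.nodes])
        onehot = sp.csr_matrix(
            (np.ones(n), (np.arange(n), type_idx)), shape=(n, len(NODE_TYPES))
        )
        return sp.hstack([sp.eye(n, format="csr"), onehot], format="csr")
    raise ValueError(f"unknown feature scheme {scheme!r}; choose from {FEATURE_SCHEMES}")


def attribute_set(
    graph: KnowledgeGraph,
    prescription_id: str,
    included_types: frozenset[str] | set[str] = DEFAULT_ATTRIBUTE_TYPES,
) -> set[str]:
    """Attribute set of a prescription for the Jaccard coefficient.

    Union of (a) the prescription's direct neighbors whose type is in
    ``included_types`` and (b) the pharmacopoeia attributes (property,
    flavor, meridian, category) of its herbs, for attribute types in
    ``included_types``.  Molecular types (disease_target, ingredient,
    ingredient_target), excluded by default, are reached through the
    disease -> target and herb -> ingredient -> target chains when
    requested.  Intermediate nodes are always traversed, so the result is
    monotone in ``included_types``.
    """
    node = graph.node(prescription_id)
    if node.node_type != "prescription":
        raise ValueError(f"{prescription_id!r} is a {node.node_type}, not a prescription")
    included = frozenset(included_types)
    out: set[str] = set()

    def keep(nid: str) -> None:
        if graph.node(nid).node_type in included:
            out.add(nid)

    for nb in graph.neighbors(prescription_id):
        keep(nb)
        nb_type = graph.node(nb).node_type
        if nb_type == "herb":
            for second in graph.neighbors(nb):
                keep(second)
                if (
                    graph.node(second).node_type == "ingredient"
                    and "ingredient_target" in included
                ):
                    for tgt in graph.neighbors(second):
                        keep(tgt)
        elif nb_type == "disease" and "disease_target" in included:
            for tgt in graph.neighbors(nb):
                keep(tgt)
    return out
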