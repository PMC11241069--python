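"""Homogeneous patient graph from per-node attention scores.

Nodes (patient records) are grouped class-conditionally by their scalar
attention scores: within each (provisional) class, nodes are inserted in
ascending score order; a node joins the first existing group whose running
mean score is within ``node_threshold`` of its own score and which still
has capacity, linking to that group's members (and to members of further
admitting groups) until it has created ``node_connections`` links.  A node
no group admits seeds a new singleton group.  Defaults: threshold 200 on
the token-count-scaled score, connection/group cap 5.

Edges never cross classes; the score gap recorded at link time never
exceeds the threshold; per-node created links and group sizes never exceed
the cap.  Insertion edges are directed (new node -> member) and are
symmetrised by default before message passing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NodeRecord",
    "ClassGroup",
    "GraphDataset",
    "assign_provisional_class",
    "get_node_adjacents",
    "build_graph",
    "threshold_sweep",
]


@dataclass
class NodeRecord:
    """One patient node: id, scalar attention score, class, feature vector."""

    record_id: str
    score: float
    cls: int
    features: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("attention score must be finite")
        if self.cls not in (0, 1):
            raise ValueError("cls must be 0 or 1")


@dataclass
class ClassGroup:
    """A same-class cluster of nodes with a running mean attention score."""

    cls: int
    members: list[str] = field(default_factory=list)
    _score_sum: float = 0.0

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def running_mean(self) -> float:
        return self._score_sum / len(self.members)

    def admit(self, record_id: str, score: float) -> None:
        self.members.append(record_id)
        self._score_sum += score


@dataclass
class GraphDataset:
    """Node feature matrix, labels, and the edge list G = (V, E).

    ``edges`` holds directed (source_index, target_index) pairs as created
    at insertion time; ``edge_gaps`` records |source score - group running
    mean| at link time.  ``message_edges()`` returns the (by default
    symmetrised, deduplicated) edge array used for graph convolution.
    """

    record_ids: list[str]
    features: np.ndarray
    labels: np.ndarray
    edges: list[tuple[int, int]]
    edge_gaps: list[float]
    scores: np.ndarray
    symmetrise: bool = True

    def __post_init__(self) -> None:
        n = len(self.record_ids)
        for s, t in self.edges:
            if not (0 <= s < n and 0 <= t < n):
                raise ValueError("edge endpoint out of range")
            if s == t:
                raise ValueError("self-loops are not allowed")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.record_ids)

    def message_edges(self) -> np.ndarray:
        """Edge array for message passing, shape (m, 2) of (source, target)."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        e = set(self.edges)
        if self.symmetrise:
            e |= {(t, s) for s, t in self.edges}
        arr = np.array(sorted(e), dtype=np.int64)
        return arr

    def to_networkx(self):
        """Export as a networkx graph (directed iff not symmetrised)."""
        import networkx as nx

        g = nx.Graph() if self.symmetrise else nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.message_edges()))
        return g


def assign_provisional_class(
    scores: np.ndarray,
    train_idx: np.ndarray,
    train_labels: np.ndarray,
    use_true_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Provisional class per node for graph construction.

    Training nodes keep their true labels; held-out nodes get the label of
    the nearer training-class score centroid (ties -> class 0): a
    one-dimensional nearest-centroid rule on the attention score.  Passing
    ``use_true_labels`` (all-node labels) bypasses the centroid rule — this
    leaks held-out labels into the graph and exists only for comparison.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if use_true_labels is not None:
        return np.asarray(use_true_labels, dtype=np.int64).copy()
    train_idx = np.asarray(train_idx)
    train_labels = np.asarray(train_labels)
    if train_idx.size == 0:
        raise ValueError("training subset is empty")
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training labels must contain both classes")
    c0 = scores[train_idx][train_labels == 0].mean()
    c1 = scores[train_idx][train_labels == 1].mean()
    cls = (np.abs(scores - c1) < np.abs(scores - c0)).astype(np.int64)
    cls[train_idx] = train_labels
    return cls


def get_node_adjacents(
    node: NodeRecord,
    groups: list[ClassGroup],
    node_threshold: float,
    node_connections: int,
    id_to_index: dict[str, int],
) -> list[tuple[int, int, float]]:
    """Insert one node into its class's group registry; return created edges.

    Groups are scanned in ascending running-mean order (stable ties by
    creation order).  A group admits the node when the absolute gap between
    the node's score and the group's running mean is within the threshold
    and the group has free capacity.  The node links to every member of
    each admitting group until it holds ``node_connections`` links; the
    first admitting group also receives it as a member (updating that
    group's running mean).  If nothing admits it, it seeds a new group.

    Returns (source_index, target_index, gap_at_link_time) triples and
    mutates ``groups`` in place.
    """
    if node_threshold < 0 or node_connections < 0:
        raise ValueError("threshold and connection cap must be >= 0")
    order = sorted(range(len(groups)), key=lambda g: (groups[g].running_mean, g))
    edges: list[tuple[int, int, float]] = []
    links = 0
    home: ClassGroup | None = None
    src = id_to_index[node.record_id]
    for gi in order:
        grp = groups[gi]
        if grp.size >= node_connections and node_connections > 0:
            continue
        gap = abs(node.score - grp.running_mean)
        if gap > node_threshold:
            continue
        if node_connections == 0:
            continue
        for member in grp.members:
            if links >= node_connections:
                break
            edges.append((src, id_to_index[member], gap))
            links += 1
        if home is None:
            home = grp
        if links >= node_connections:
            break
    if home is not None:
        home.admit(node.record_id, node.score)
    else:
        fresh = ClassGroup(cls=node.cls)
        fresh.admit(node.record_id, node.score)
        groups.append(fresh)
    return edges


def build_graph(
    nodes: list[NodeRecord],
    node_threshold: float = 200.0,
    node_connections: int = 5,
    symmetrise: bool = True,
) -> GraphDataset:
    """Build the homogeneous graph over all nodes.

    Within each class, nodes are processed in ascending score order (stable
    ties by record id); edges are created by :func:`get_node_adjacents`.
    """
    if not nodes:
        raise ValueError("need at least one node")
    record_ids = [n.record_id for n in nodes]
    if len(set(record_ids)) != len(record_ids):
        raise ValueError("record ids must be unique")
    id_to_index = {rid: i for i, rid in enumerate(record_ids)}
    edges: list[tuple[int, int]] = []
    gaps: list[float] = []
    for cls in (0, 1):
        members = [n for n in nodes if n.cls == cls]
        members.sort(key=lambda n: (n.score, n.record_id))
        groups: list[ClassGroup] = []
        for node in members:
            for s, t, gap in get_node_adjacents(
                node, groups, node_threshold, node_connections, id_to_index
            ):
                edges.append((s, t))
                gaps.append(gap)
    features = np.asarray([n.features for n in nodes], dtype=np.float64)
    labels = np.asarray([n.cls for n in nodes], dtype=np.int64)
    scores = np.asarray([n.score for n in nodes], dtype=np.float64)
    return GraphDataset(
        record_ids=record_ids,
        features=features,
        labels=labels,
        edges=edges,
        edge_gaps=gaps,
        scores=scores,
        symmetrise=symmetrise,
    )


def threshold_sweep(candidates, evaluate) -> tuple[float, list[tuple[float, float]]]:
    """Evaluate a metric callback at each candidate threshold.

    Returns the candidate maximising the callback (ties -> smallest
    threshold) together with the full (threshold, metric) table.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("need at least one candidate threshold")
    table = [(float(t), float(evaluate(t))) for t in candidates]
    best = max(table, key=lambda row: (row[1], -row[0]))
    return best[0], table
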