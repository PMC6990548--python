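"""District adjacency and the intrinsic CAR (ICAR) precision structure.

Two districts are neighbours when they share a common boundary (rook
contiguity for polygon input).  The structured spatial effect carries the
intrinsic Gaussian Markov random field prior whose joint precision is
tau2_str * Q with Q_hh = n_h (the neighbour count) and Q_hi = -1 for
neighbouring pairs: conditionally, each district's effect is Gaussian
around the mean of its neighbours with precision n_h * tau2_str.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from shapely.geometry import shape


@dataclass
class AdjacencyGraph:
    """Symmetric neighbour structure over an ordered list of district ids."""

    nodes: list
    neighbours: dict

    def __post_init__(self):
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node ids in adjacency graph")
        for node in self.nodes:
            self.neighbours.setdefault(node, set())
        for node, nbrs in self.neighbours.items():
            if node not in node_set:
                raise ValueError(f"neighbour list for unknown node {node!r}")
            if node in nbrs:
                raise ValueError(f"node {node!r} listed as its own neighbour")
            for other in nbrs:
                if other not in node_set:
                    raise ValueError(f"node {node!r} has unknown neighbour {other!r}")
                if node not in self.neighbours.get(other, set()):
                    raise ValueError(
                        f"asymmetric adjacency: {node!r} lists {other!r} but not vice versa"
                    )

    @property
    def n(self) -> int:
        return len(self.nodes)

    def degree(self, node) -> int:
        return len(self.neighbours[node])

    @property
    def degrees(self) -> dict:
        return {node: len(self.neighbours[node]) for node in self.nodes}

    def index(self) -> dict:
        return {node: i for i, node in enumerate(self.nodes)}

    def adjacency_matrix(self) -> np.ndarray:
        idx = self.index()
        A = np.zeros((self.n, self.n))
        for node, nbrs in self.neighbours.items():
            for other in nbrs:
                A[idx[node], idx[other]] = 1.0
        return A

    def component_labels(self) -> np.ndarray:
        n_comp, labels = connected_components(self.adjacency_matrix(), directed=False)
        return labels

    def __eq__(self, other) -> bool:
        if not isinstance(other, AdjacencyGraph):
            return NotImplemented
        return self.nodes == other.nodes and {
            k: set(v) for k, v in self.neighbours.items()
        } == {k: set(v) for k, v in other.neighbours.items()}


@dataclass
class ICARStructure:
    """Joint ICAR precision structure Q with connected-component labels."""

    nodes: list
    Q: np.ndarray = field(repr=False)
    components: np.ndarray = field(repr=False)

    @property
    def n_components(self) -> int:
        return int(self.components.max()) + 1 if len(self.components) else 0

    @property
    def rank(self) -> int:
        return self.Q.shape[0] - self.n_components


def read_gal(path) -> AdjacencyGraph:
    """Read a GAL spatial-weights file.

    Layout: a header line whose last integer is the node count, then per
    node a line ``id degree`` followed by a line of neighbour ids (empty
    for isolated nodes).
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError("empty GAL file")
    header = lines[0].split()
    try:
        n = int(header[1] if len(header) > 1 else header[0])
    except (ValueError, IndexError):
        raise ValueError(f"malformed GAL header: {lines[0]!r}") from None
    nodes: list = []
    neighbours: dict = {}
    pos = 1
    for _ in range(n):
        if pos >= len(lines):
            raise ValueError("GAL file truncated: fewer nodes than header declares")
        head = lines[pos].split()
        if len(head) != 2:
            raise ValueError(f"malformed GAL node line: {lines[pos]!r}")
        node, degree = head[0], int(head[1])
        nbrs = lines[pos + 1].split() if pos + 1 < len(lines) else []
        if degree != len(nbrs):
            raise ValueError(
                f"node {node!r}: declared degree {degree} but {len(nbrs)} neighbours listed"
            )
        if degree == 0:
            warnings.warn(f"isolated district {node!r} in GAL file", stacklevel=2)
        nodes.append(node)
        neighbours[node] = set(nbrs)
        pos += 2
    return AdjacencyGraph(nodes=nodes, neighbours=neighbours)


def write_gal(graph: AdjacencyGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{graph.n}\n")
        for node in graph.nodes:
            nbrs = sorted(graph.neighbours[node])
            fh.write(f"{node} {len(nbrs)}\n")
            fh.write(" ".join(str(b) for b in nbrs) + "\n")


def adjacency_from_polygons(geojson_path) -> AdjacencyGraph:
    """Rook-contiguity adjacency from a GeoJSON FeatureCollection.

    Each feature must carry a district identifier in ``properties.id``.
    Two districts are neighbours iff their geometries intersect in a set
    of positive length (a shared edge); a single shared corner does not
    qualify.
    """
    with open(geojson_path, encoding="utf-8") as fh:
        gj = json.load(fh)
    ids, geoms = [], []
    for feat in gj["features"]:
        fid = feat.get("properties", {}).get("id")
        if fid is None:
            raise ValueError("feature without a properties.id district identifier")
        fid = str(fid)
        if fid in ids:
            raise ValueError(f"duplicate district id {fid!r} in GeoJSON")
        ids.append(fid)
        geoms.append(shape(feat["geometry"]))
    neighbours = {fid: set() for fid in ids}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if not geoms[i].intersects(geoms[j]):
                continue
            inter = geoms[i].intersection(geoms[j])
            if getattr(inter, "length", 0.0) > 1e-12:
                neighbours[ids[i]].add(ids[j])
                neighbours[ids[j]].add(ids[i])
    return AdjacencyGraph(nodes=ids, neighbours=neighbours)


def icar_structure(graph: AdjacencyGraph) -> ICARStructure:
    """Build the ICAR joint precision structure Q from an adjacency graph.

    Isolated districts contribute a zero row/column (their structured
    effect is undefined and pinned to 0) and are reported with a warning.
    """
    A = graph.adjacency_matrix()
    Q = np.diag(A.sum(axis=1)) - A
    isolated = [node for node in graph.nodes if graph.degree(node) == 0]
    if isolated:
        warnings.warn(
            f"isolated districts {isolated}: structured effect pinned to 0", stacklevel=2
        )
    return ICARStructure(nodes=list(graph.nodes), Q=Q, components=graph.component_labels())


def sum_to_zero_basis(icar: ICARStructure, tol: float = 1e-9):
    """Orthonormal basis of the per-component sum-to-zero subspace of Q.

    Returns ``(V, lam)`` where the columns of V are the eigenvectors of Q
    with eigenvalue above ``tol`` and lam the matching eigenvalues, so
    V' Q V = diag(lam) is the full-rank precision of the reparametrised
    structured effect f_str = V u.  Eigenvectors of isolated nodes and the
    component-constant directions fall in the discarded null space, which
    enforces both the sum-to-zero constraint and the pin-to-zero rule.
    """
    lam, vec = np.linalg.eigh(icar.Q)
    keep = lam > tol
    return vec[:, keep], lam[keep]
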