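"""Identity-derived distances, neighbor joining, rooting and Newick export.

The candidate tree is a visual grouping device: distances are the simple
transform d = 1 - identity (no multiple-substitution correction), the tree is
built with Saitou-Nei neighbor joining (negative branch-length estimates
clamped to zero with the deficit moved to the sister branch), re-rooted on the
pendant edge of a chosen reference leaf, and exported as Newick plus a
per-leaf annotation sidecar (bar heights from the energy scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .sequence_mining import IdentityMatrix

__all__ = [
    "PhyloTree",
    "distance_matrix",
    "neighbor_joining",
    "root_and_annotate",
    "to_newick",
    "leaf_path_lengths",
]


@dataclass
class PhyloTree:
    """An (un)rooted tree as an undirected weighted adjacency map.

    ``adjacency[u][v]`` is the branch length of edge (u, v); leaves are the
    nodes named in ``leaves``.  ``root`` is None for unrooted trees.
    ``annotations`` maps leaf ids to a bar-height scalar.
    """

    adjacency: dict[str, dict[str, float]]
    leaves: tuple[str, ...]
    root: str | None = None
    annotations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("leaf ids must be unique")
        for u, nbrs in self.adjacency.items():
            for v, w in nbrs.items():
                if w < 0:
                    raise ValueError(f"negative branch length on edge ({u}, {v})")
                if abs(self.adjacency[v][u] - w) > 1e-12:
                    raise ValueError(f"asymmetric edge weights on ({u}, {v})")

    @property
    def total_length(self) -> float:
        return sum(w for u, nbrs in self.adjacency.items() for v, w in nbrs.items() if u < v)

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            adjacency={u: dict(nbrs) for u, nbrs in self.adjacency.items()},
            leaves=self.leaves,
            root=self.root,
            annotations=dict(self.annotations),
        )


def distance_matrix(identity: IdentityMatrix) -> np.ndarray:
    """Distance matrix d_ij = 1 - identity_ij (zero diagonal)."""
    d = 1.0 - identity.values
    np.fill_diagonal(d, 0.0)
    return d


def _check_distances(d: np.ndarray, n: int) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.shape != (n, n):
        raise ValueError(f"distance matrix shape {d.shape} does not match {n} taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    return d


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    # negative NJ estimate: clamp to 0, transfer the deficit to the sister
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def neighbor_joining(distances: np.ndarray, ids: list[str] | tuple[str, ...]) -> PhyloTree:
    """Saitou-Nei neighbor joining over a symmetric zero-diagonal matrix.

    For additive input matrices the generating topology and branch lengths
    are recovered.  Returns an unrooted tree (internal nodes named
    ``_nj0``, ``_nj1``, ...); with two taxa the single edge is split evenly
    across an implicit midpoint node.
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    if len(set(ids)) != n:
        raise ValueError("taxon ids must be unique")
    d = _check_distances(distances, n).copy()

    adj: dict[str, dict[str, float]] = {name: {} for name in ids}

    def add_edge(u: str, v: str, w: float) -> None:
        w = max(float(w), 0.0)
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    if n == 2:
        mid = "_nj0"
        half = d[0, 1] / 2.0
        add_edge(ids[0], mid, half)
        add_edge(ids[1], mid, half)
        return PhyloTree(adjacency=adj, leaves=tuple(ids))

    active = list(range(n))
    names = list(ids)
    next_internal = 0

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(q), q.shape)  # first minimum: deterministic
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        a, b = active[i_s], active[j_s]
        dij = d[a, b]
        la = dij / 2.0 + (r[i_s] - r[j_s]) / (2.0 * (m - 2))
        lb = dij - la
        la, lb = _clamp_pair(la, lb)

        new_name = f"_nj{next_internal}"
        next_internal += 1
        add_edge(names[a], new_name, la)
        add_edge(names[b], new_name, lb)

        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (a, b):
                continue
            new_row[k] = (d[a, k] + d[b, k] - dij) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        names.append(new_name)
        active = [k for k in active if k not in (a, b)] + [d.shape[0] - 1]

    # resolve the final three nodes around one internal vertex (closed form)
    a, b, c = active
    center = f"_nj{next_internal}"
    xa = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    xb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    xc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    for node, x in ((a, xa), (b, xb), (c, xc)):
        add_edge(names[node], center, max(x, 0.0))

    return PhyloTree(adjacency=adj, leaves=tuple(ids))


def root_and_annotate(
    tree: PhyloTree,
    root_leaf_id: str,
    annotations: Mapping[str, float] | None = None,
) -> PhyloTree:
    """Re-root on the pendant edge of ``root_leaf_id`` and attach bar heights.

    The pendant edge is split at its midpoint by a new node ``_root``; the
    reference leaf becomes a child of the root and total tree length is
    unchanged.  Leaves without an annotation get height 0.
    """
    if root_leaf_id not in tree.leaves:
        raise ValueError(f"unknown root leaf {root_leaf_id!r}")
    annotations = dict(annotations or {})
    unknown = set(annotations) - set(tree.leaves)
    if unknown:
        raise ValueError(f"annotations for unknown leaves: {sorted(unknown)}")

    out = tree.copy()
    (parent, length), = out.adjacency[root_leaf_id].items()
    del out.adjacency[root_leaf_id][parent]
    del out.adjacency[parent][root_leaf_id]
    root = "_root"
    half = length / 2.0
    out.adjacency.setdefault(root, {})
    out.adjacency[root][root_leaf_id] = half
    out.adjacency[root_leaf_id][root] = half
    out.adjacency[root][parent] = half
    out.adjacency[parent][root] = half
    out.root = root
    out.annotations = {leaf: float(annotations.get(leaf, 0.0)) for leaf in out.leaves}
    return out


def to_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Newick string with fixed-precision branch lengths, no internal labels."""
    if tree.root is not None:
        start = tree.root
    else:
        internal = [u for u in tree.adjacency if u not in tree.leaves]
        start = internal[0] if internal else tree.leaves[0]

    def render(node: str, parent: str | None) -> str:
        children = [v for v in tree.adjacency[node] if v != parent]
        if not children:
            return node
        inner = ",".join(
            f"{render(c, node)}:{tree.adjacency[node][c]:.{precision}f}" for c in children
        )
        return f"({inner})"

    body = render(start, None)
    if body == start:  # degenerate single-node tree
        return f"{start};"
    return f"{body};"


def leaf_path_lengths(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """Patristic (path) length between every unordered pair of leaves."""
    out: dict[tuple[str, str], float] = {}
    for src in tree.leaves:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in tree.adjacency[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in tree.leaves:
            if src < dst:
                out[(src, dst)] = dist[dst]
    return out


def write_annotation_sidecar(annotations: Mapping[str, float], path) -> None:
    """Write an annotation sidecar TSV (id, height), iTOL-style."""
    with open(path, "w") as fh:
        fh.write("id\theight\n")
        for leaf, h in annotations.items():
            fh.write(f"{leaf}\t{h:.6f}\n")
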