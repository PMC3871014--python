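"""Dendritic trees as linear networks, and the metric primitives on them.

A dendrite centerline is modelled as a rooted tree of straight segments
embedded in the image plane.  All statistics downstream (K-functions, soma
distances, nearest neighbors) are *intrinsic*: they use the shortest-path
distance along the network, never the Euclidean distance between points.
Locations are therefore addressed as (segment, offset-from-parent-end) in μm;
planar coordinates are carried only for image-border logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import StructuralError, ValidationError

SPINE_TYPES = ("mushroom", "stubby", "thin")

_LOC_TOL = 1e-9


@dataclass(frozen=True)
class NetworkLocation:
    """A point on the network: a segment id and the arc offset (μm) from the
    segment's parent endpoint."""

    segment: int
    offset: float


@dataclass(frozen=True)
class SpineRecord:
    """One annotated spine.

    ``soma_distance`` (SD) is the network distance from the root to the spine
    and ``branch_order`` (BO) is the centrifugal order of the host segment;
    both are derived from the location and kept redundantly because the
    categorical models consume them directly.
    """

    location: NetworkLocation
    spine_type: str
    soma_distance: float
    branch_order: int
    div: int = 7
    experiment: int = 1
    xy: tuple[float, ...] | None = None


class LinearNetwork:
    """A rooted tree of centerline segments with lengths in μm.

    Segments are keyed by their child (distal) node id, matching the SWC
    convention that every non-root sample point identifies the edge to its
    parent.  Branch orders are centrifugal: segments leaving the root have
    order 1 and the order increments by exactly one at each bifurcation.
    """

    def __init__(
        self,
        node_ids: Sequence[int],
        coords: np.ndarray,
        root: int,
        seg_ids: Sequence[int],
        seg_parent: Sequence[int],
        seg_child: Sequence[int],
        seg_length: Sequence[float],
        seg_order: Sequence[int],
    ):
        self.node_ids = list(node_ids)
        self.coords = np.asarray(coords, dtype=float)
        self.root = root
        self._node_index = {nid: i for i, nid in enumerate(self.node_ids)}
        self.seg_ids = list(seg_ids)
        self._seg_index = {sid: i for i, sid in enumerate(self.seg_ids)}
        self.seg_parent = np.asarray(seg_parent, dtype=int)  # node index
        self.seg_child = np.asarray(seg_child, dtype=int)  # node index
        self.seg_length = np.asarray(seg_length, dtype=float)
        self.seg_order = np.asarray(seg_order, dtype=int)
        if np.any(self.seg_length <= 0):
            raise ValidationError("all segment lengths must be positive")
        self._node_dist: np.ndarray | None = None
        self._degree = np.zeros(len(self.node_ids), dtype=int)
        np.add.at(self._degree, self.seg_parent, 1)
        np.add.at(self._degree, self.seg_child, 1)

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_segments(self) -> int:
        return len(self.seg_ids)

    @property
    def total_length(self) -> float:
        """ℓ_T, the total network length in μm."""
        return float(self.seg_length.sum())

    def segment_index(self, seg_id: int) -> int:
        try:
            return self._seg_index[seg_id]
        except KeyError:
            raise ValidationError(f"unknown segment id {seg_id}") from None

    def node_degree(self, node_index: int) -> int:
        return int(self._degree[node_index])

    # ---------------------------------------------------------------- distances
    @property
    def node_distances(self) -> np.ndarray:
        """All-pairs shortest-path distance matrix over nodes (μm), cached."""
        if self._node_dist is None:
            V = self.n_nodes
            adj: list[list[tuple[int, float]]] = [[] for _ in range(V)]
            for p, c, L in zip(self.seg_parent, self.seg_child, self.seg_length):
                adj[p].append((c, L))
                adj[c].append((p, L))
            D = np.full((V, V), np.inf)
            # tree: one DFS per source suffices (no priority queue needed)
            for s in range(V):
                D[s, s] = 0.0
                stack = [s]
                while stack:
                    u = stack.pop()
                    for v, w in adj[u]:
                        if not np.isfinite(D[s, v]):
                            D[s, v] = D[s, u] + w
                            stack.append(v)
            self._node_dist = D
        return self._node_dist

    @property
    def node_depth(self) -> np.ndarray:
        """Distance from the root to every node (μm)."""
        return self.node_distances[self._node_index[self.root]]

    def validate_location(self, loc: NetworkLocation) -> int:
        si = self.segment_index(loc.segment)
        if not (-_LOC_TOL <= loc.offset <= self.seg_length[si] + _LOC_TOL):
            raise ValidationError(
                f"offset {loc.offset} outside segment {loc.segment} "
                f"of length {self.seg_length[si]}"
            )
        return si

    def location_to_node_distances(self, loc: NetworkLocation) -> np.ndarray:
        """Distance from an on-network point to every node (μm)."""
        si = self.validate_location(loc)
        D = self.node_distances
        via_parent = loc.offset + D[self.seg_parent[si]]
        via_child = (self.seg_length[si] - loc.offset) + D[self.seg_child[si]]
        return np.minimum(via_parent, via_child)

    def distance(self, a: NetworkLocation, b: NetworkLocation) -> float:
        """Shortest-path distance along the network between two points (μm)."""
        sa = self.validate_location(a)
        sb = self.validate_location(b)
        if sa == sb:
            return abs(a.offset - b.offset)
        D = self.node_distances
        La, Lb = self.seg_length[sa], self.seg_length[sb]
        combos = (
            a.offset + D[self.seg_parent[sa], self.seg_parent[sb]] + b.offset,
            a.offset + D[self.seg_parent[sa], self.seg_child[sb]] + (Lb - b.offset),
            (La - a.offset) + D[self.seg_child[sa], self.seg_parent[sb]] + b.offset,
            (La - a.offset) + D[self.seg_child[sa], self.seg_child[sb]] + (Lb - b.offset),
        )
        return float(min(combos))

    def soma_distance(self, loc: NetworkLocation) -> float:
        """SD: network distance from the root attachment point to ``loc``."""
        si = self.validate_location(loc)
        return float(self.node_depth[self.seg_parent[si]] + loc.offset)

    def eccentricity(self, loc: NetworkLocation) -> float:
        """Largest network distance from ``loc`` to any point (attained at a tip)."""
        return float(self.location_to_node_distances(loc).max())

    @property
    def diameter(self) -> float:
        """Largest pairwise network distance (between two tips, μm)."""
        return float(self.node_distances.max())

    @property
    def radius(self) -> float:
        """Smallest eccentricity over the network; diameter/2 on a tree.

        For t ≤ radius every point's circle of radius t is non-empty, the
        condition under which the geometrically corrected K-function is
        exactly unbiased.
        """
        return self.diameter / 2.0

    # ----------------------------------------------------------- ball & circle
    def ball_length(self, p: NetworkLocation, t: float) -> float:
        """ℓ_p(t): total length of the network within distance t of p (μm).

        Computed exactly from per-segment coverage: on the host segment the
        ball is the two arms of length min(offset, t) and min(L−offset, t);
        on any other segment the covered set is the union of the two intervals
        reachable through its endpoints.
        """
        if t < 0:
            raise ValidationError("t must be non-negative")
        si = self.validate_location(p)
        d = self.location_to_node_distances(p)
        du = d[self.seg_parent]
        dv = d[self.seg_child]
        L = self.seg_length
        a = np.clip(t - du, 0.0, L)
        b = np.clip(t - dv, 0.0, L)
        cover = np.minimum(L, a + b)
        cover[si] = min(p.offset, t) + min(L[si] - p.offset, t)
        return float(cover.sum())

    def circle_count(self, p: NetworkLocation, r: float) -> int:
        """m(p, r): number of network points at distance exactly r from p.

        Convention for measure-zero coincidences: a circle point landing
        exactly on a node of degree d counts as d−1 (the limit from below),
        hence 0 on a tip.
        """
        if r <= 0:
            raise ValidationError("r must be positive")
        si = self.validate_location(p)
        d = self.location_to_node_distances(p)
        du = d[self.seg_parent]
        dv = d[self.seg_child]
        L = self.seg_length
        count = self._circle_interior(si, p.offset, r, du, dv, L)
        # exact node coincidences
        count += int(np.sum(np.maximum(self._degree[np.abs(d - r) == 0.0] - 1, 0)))
        return count

    def _circle_interior(self, si, offset, r, du, dv, L):
        """Circle points strictly inside segments (host handled as two arms)."""
        peak = (du + dv + L) / 2.0
        asc = (du < r) & (r < peak)
        desc = (dv < r) & (r < peak)
        tangent = (r == peak) & (peak > du) & (peak > dv)
        n = asc.astype(int) + desc.astype(int) + tangent.astype(int)
        # host segment: two straight arms from p
        n[si] = int(r < offset) + int(r < L[si] - offset)
        return int(n.sum())

    def circle_counts_batch(self, p: NetworkLocation, radii: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`circle_count` over an array of radii."""
        radii = np.asarray(radii, dtype=float)
        si = self.validate_location(p)
        d = self.location_to_node_distances(p)
        du = d[self.seg_parent][None, :]
        dv = d[self.seg_child][None, :]
        L = self.seg_length[None, :]
        r = radii[:, None]
        peak = (du + dv + L) / 2.0
        n = ((du < r) & (r < peak)).astype(int)
        n += ((dv < r) & (r < peak)).astype(int)
        n += ((r == peak) & (peak > du) & (peak > dv)).astype(int)
        # host segment: replace the generic tent by the two straight arms from p
        n[:, si] = (radii < p.offset).astype(int) + (
            radii < self.seg_length[si] - p.offset
        ).astype(int)
        counts = n.sum(axis=1)
        # exact node coincidences: degree-d node counts d-1 (0 at tips)
        coincide = d[None, :] == radii[:, None]
        counts += (coincide * np.maximum(self._degree - 1, 0)[None, :]).sum(axis=1)
        return counts

    # ------------------------------------------------------------- arc sampling
    def cumulative_lengths(self) -> np.ndarray:
        """Cumulative segment lengths; maps [0, ℓ_T) linearly onto the network."""
        return np.concatenate([[0.0], np.cumsum(self.seg_length)])

    def location_at_arc(self, s: float) -> NetworkLocation:
        """The point at arc coordinate s ∈ [0, ℓ_T] under the segment order."""
        if not 0 <= s <= self.total_length + _LOC_TOL:
            raise ValidationError("arc coordinate outside [0, total_length]")
        cum = self.cumulative_lengths()
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, self.n_segments - 1)
        return NetworkLocation(self.seg_ids[i], min(s - cum[i], self.seg_length[i]))

    def location_xy(self, loc: NetworkLocation) -> np.ndarray:
        """Planar coordinates of a network point (linear interpolation)."""
        si = self.validate_location(loc)
        a = self.coords[self.seg_parent[si]]
        b = self.coords[self.seg_child[si]]
        f = loc.offset / self.seg_length[si]
        return a + f * (b - a)

    def branch_order(self, loc: NetworkLocation) -> int:
        return int(self.seg_order[self.validate_location(loc)])


def build_network(node_table, edge_table=None) -> LinearNetwork:
    """Build a :class:`LinearNetwork` from node and edge tables.

    ``node_table``: DataFrame (or records) with columns ``id, x, y[, z]`` and,
    if ``edge_table`` is omitted, a ``parent`` column (SWC-style; parent −1
    marks the root).  ``edge_table``: columns ``parent, child`` with optional
    ``length`` (default: Euclidean distance between node coordinates) and
    ``order`` (default: computed centrifugally).

    Raises :class:`StructuralError` for cycles, multiple roots or disconnected
    components and :class:`ValidationError` for nonpositive lengths.
    """
    nodes = pd.DataFrame(node_table)
    coord_cols = [c for c in ("x", "y", "z") if c in nodes.columns]
    if edge_table is None:
        if "parent" not in nodes.columns:
            raise StructuralError("node table without edge table needs a 'parent' column")
        edges = nodes.loc[nodes["parent"] != -1, ["parent", "id"]].rename(
            columns={"id": "child"}
        )
    else:
        edges = pd.DataFrame(edge_table)

    node_ids = list(nodes["id"].astype(int))
    if len(set(node_ids)) != len(node_ids):
        raise StructuralError("duplicate node ids")
    index = {nid: i for i, nid in enumerate(node_ids)}
    coords = nodes[coord_cols].to_numpy(dtype=float) if coord_cols else np.zeros((len(node_ids), 2))

    child_ids = list(edges["child"].astype(int))
    parent_ids = list(edges["parent"].astype(int))
    if len(set(child_ids)) != len(child_ids):
        raise StructuralError("a node appears as child of two edges (cycle or multi-parent)")
    for cid, pid in zip(child_ids, parent_ids):
        if cid not in index or pid not in index:
            raise StructuralError(f"edge references unknown node ({pid}->{cid})")

    roots = [nid for nid in node_ids if nid not in set(child_ids)]
    if len(roots) != 1:
        raise StructuralError(f"expected exactly one root, found {len(roots)}")
    root = roots[0]

    if "length" in edges.columns:
        lengths = edges["length"].to_numpy(dtype=float)
    else:
        if not coord_cols:
            raise ValidationError("edges need an explicit length or node coordinates")
        a = coords[[index[p] for p in parent_ids]]
        b = coords[[index[c] for c in child_ids]]
        lengths = np.linalg.norm(a - b, axis=1)
    if np.any(lengths <= 0):
        raise ValidationError("nonpositive segment length")

    # connectivity & acyclicity: a rooted tree has V-1 edges all reachable from root
    if len(child_ids) != len(node_ids) - 1:
        raise StructuralError("edge count does not match a single tree (cycle or disconnect)")
    children: dict[int, list[int]] = {nid: [] for nid in node_ids}
    for cid, pid in zip(child_ids, parent_ids):
        children[pid].append(cid)
    seen = {root}
    stack = [root]
    while stack:
        u = stack.pop()
        for v in children[u]:
            if v in seen:
                raise StructuralError("cycle detected")
            seen.add(v)
            stack.append(v)
    if len(seen) != len(node_ids):
        raise StructuralError("disconnected components")

    # centrifugal branch orders: start at 1, +1 at every bifurcation
    edge_of_child = {c: k for k, c in enumerate(child_ids)}
    if "order" in edges.columns and edges["order"].notna().all():
        orders = edges["order"].to_numpy(dtype=int)
    else:
        orders = np.zeros(len(child_ids), dtype=int)
        stack = [(c, 1) for c in children[root]]
        while stack:
            c, o = stack.pop()
            orders[edge_of_child[c]] = o
            kids = children[c]
            o_next = o + 1 if len(kids) >= 2 else o
            stack.extend((k, o_next) for k in kids)

    return LinearNetwork(
        node_ids=node_ids,
        coords=coords,
        root=root,
        seg_ids=child_ids,
        seg_parent=[index[p] for p in parent_ids],
        seg_child=[index[c] for c in child_ids],
        seg_length=lengths,
        seg_order=orders,
    )


# ---------------------------------------------------------------- spine pattern
@dataclass
class SpinePattern:
    """A set of located, typed spines on one dendrite network."""

    network: LinearNetwork
    spines: list[SpineRecord] = field(default_factory=list)
    window: tuple[float, float, float, float] | None = None  # (xmin, xmax, ymin, ymax)
    dendrite_id: str = "dendrite"

    @property
    def n(self) -> int:
        return len(self.spines)

    def locations(self) -> list[NetworkLocation]:
        return [s.location for s in self.spines]

    def types(self) -> list[str]:
        return [s.spine_type for s in self.spines]

    def validate(self, tol: float = 1e-6) -> None:
        """Check SD/BO consistency of every record against the network."""
        for s in self.spines:
            sd = self.network.soma_distance(s.location)
            if abs(sd - s.soma_distance) > tol:
                raise ValidationError(
                    f"soma distance mismatch: stored {s.soma_distance}, computed {sd}"
                )
            if s.branch_order != self.network.branch_order(s.location):
                raise ValidationError("branch order mismatch")

    def pairwise_distances(self) -> np.ndarray:
        """N×N matrix of network distances between spines (single shared pass)."""
        net = self.network
        N = self.n
        if N == 0:
            return np.zeros((0, 0))
        segs = np.array([net.segment_index(s.location.segment) for s in self.spines])
        offs = np.array([s.location.offset for s in self.spines])
        D = net.node_distances
        L = net.seg_length[segs]
        # point-to-node matrix M (N × V)
        M = np.minimum(
            offs[:, None] + D[net.seg_parent[segs]],
            (L - offs)[:, None] + D[net.seg_child[segs]],
        )
        dist = np.minimum(
            M[:, net.seg_parent[segs]] + offs[None, :],
            M[:, net.seg_child[segs]] + (L - offs)[None, :],
        )
        same = segs[:, None] == segs[None, :]
        direct = np.abs(offs[:, None] - offs[None, :])
        dist[same] = direct[same]
        np.fill_diagonal(dist, 0.0)
        return dist

    def as_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.spines):
            xy = s.xy if s.xy is not None else tuple(self.network.location_xy(s.location))
            rows.append(
                dict(
                    spine_id=i,
                    segment_id=s.location.segment,
                    offset_um=s.location.offset,
                    type=s.spine_type,
                    soma_distance=s.soma_distance,
                    branch_order=s.branch_order,
                    div=s.div,
                    experiment=s.experiment,
                    x=xy[0],
                    y=xy[1] if len(xy) > 1 else 0.0,
                )
            )
        return pd.DataFrame(rows)


def make_spine(
    net: LinearNetwork,
    loc: NetworkLocation,
    spine_type: str,
    div: int = 7,
    experiment: int = 1,
) -> SpineRecord:
    """Construct a consistent :class:`SpineRecord` (SD/BO derived from the net)."""
    if spine_type not in SPINE_TYPES:
        raise ValidationError(f"unknown spine type {spine_type!r}")
    return SpineRecord(
        location=loc,
        spine_type=spine_type,
        soma_distance=net.soma_distance(loc),
        branch_order=net.branch_order(loc),
        div=div,
        experiment=experiment,
        xy=tuple(net.location_xy(loc)),
    )


def nearest_neighbors(
    pattern: SpinePattern,
    spine_index: int,
    k: int,
    dist_matrix: np.ndarray | None = None,
) -> list[tuple[int, float]]:
    """The k nearest spines (by network distance) to one spine, ascending.

    Ties in distance are broken by spine index.  Raises
    :class:`InsufficientNeighborsError` when fewer than k other spines exist.
    """
    from .exceptions import InsufficientNeighborsError

    if pattern.n - 1 < k:
        raise InsufficientNeighborsError(
            f"spine {spine_index}: need {k} neighbors, have {pattern.n - 1}"
        )
    d = (dist_matrix if dist_matrix is not None else pattern.pairwise_distances())[spine_index]
    order = np.lexsort((np.arange(pattern.n), d))
    order = order[order != spine_index]
    return [(int(j), float(d[j])) for j in order[:k]]
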