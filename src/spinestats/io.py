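"""Reading and writing dendrite reconstructions and spine annotations.

Trees travel as standard 7-column SWC (id, type, x, y, z, radius, parent;
one root with parent −1); spines as a CSV with either an on-network address
(``segment_id, offset_um``) or planar coordinates (``x, y[, z]``) that are
snapped to the nearest centerline point within a tolerance.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import StructuralError, ValidationError
from .network import (
    LinearNetwork,
    NetworkLocation,
    SpinePattern,
    build_network,
    make_spine,
)

logger = logging.getLogger(__name__)

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


def read_swc(path) -> LinearNetwork:
    """Parse a 7-column SWC file into a :class:`LinearNetwork`.

    Type codes are ignored except that the (single) root marks the soma
    attachment.  Raises :class:`StructuralError` on multiple roots or cycles.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValidationError(f"malformed SWC line: {line!r}")
        rows.append(
            dict(
                id=int(parts[0]),
                type=int(parts[1]),
                x=float(parts[2]),
                y=float(parts[3]),
                z=float(parts[4]),
                radius=float(parts[5]),
                parent=int(parts[6]),
            )
        )
    if not rows:
        raise StructuralError(f"empty SWC file: {path}")
    nodes = pd.DataFrame(rows)
    n_roots = int((nodes["parent"] == -1).sum())
    if n_roots != 1:
        raise StructuralError(f"SWC must have exactly one root, found {n_roots}")
    return build_network(nodes[["id", "x", "y", "z", "parent"]])


def write_swc(net: LinearNetwork, path) -> None:
    """Write the network as SWC (root type 1/soma, other nodes type 3)."""
    parent_of = {net.seg_child[i]: net.seg_parent[i] for i in range(net.n_segments)}
    lines = ["# id type x y z radius parent"]
    root_idx = net.node_ids.index(net.root)
    for idx in _topo_order(net, root_idx):
        nid = net.node_ids[idx]
        xyz = list(net.coords[idx]) + [0.0, 0.0]
        x, y, z = xyz[0], xyz[1], xyz[2]
        if idx == root_idx:
            lines.append(f"{nid} 1 {x:.6f} {y:.6f} {z:.6f} 0.5 -1")
        else:
            pid = net.node_ids[parent_of[idx]]
            lines.append(f"{nid} 3 {x:.6f} {y:.6f} {z:.6f} 0.5 {pid}")
    Path(path).write_text("\n".join(lines) + "\n")


def _topo_order(net: LinearNetwork, root_idx: int):
    children: dict[int, list[int]] = {}
    for i in range(net.n_segments):
        children.setdefault(net.seg_parent[i], []).append(net.seg_child[i])
    order, stack = [], [root_idx]
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(reversed(children.get(u, [])))
    return order


def snap_to_network(net: LinearNetwork, xy, tolerance: float = 2.0):
    """Nearest centerline point to a planar coordinate, or None beyond tolerance."""
    xy = np.asarray(xy, dtype=float)
    dim = min(len(xy), net.coords.shape[1])
    xy = xy[:dim]
    best = (np.inf, None)
    for si in range(net.n_segments):
        a = net.coords[net.seg_parent[si]][:dim]
        b = net.coords[net.seg_child[si]][:dim]
        ab = b - a
        denom = float(ab @ ab)
        t = float(np.clip((xy - a) @ ab / denom, 0.0, 1.0)) if denom > 0 else 0.0
        proj = a + t * ab
        d = float(np.linalg.norm(xy - proj))
        if d < best[0]:
            best = (d, NetworkLocation(net.seg_ids[si], t * float(net.seg_length[si])))
    if best[0] > tolerance:
        return None
    return best[1]


def read_annotations(
    swc_path, spine_table_path, snap_tolerance: float = 2.0
) -> SpinePattern:
    """Load a dendrite tree and its spine table into a :class:`SpinePattern`.

    Spines addressed by (segment_id, offset_um) are placed directly; spines
    given only as planar coordinates are snapped to the nearest centerline
    point, and any spine farther than ``snap_tolerance`` μm from the network
    is dropped with a logged warning count.
    """
    net = read_swc(swc_path)
    table = pd.read_csv(spine_table_path)
    spines = []
    dropped = 0
    for _, row in table.iterrows():
        if "segment_id" in table.columns and not pd.isna(row.get("segment_id")):
            loc = NetworkLocation(int(row["segment_id"]), float(row["offset_um"]))
            net.validate_location(loc)
        else:
            loc = snap_to_network(net, (row["x"], row["y"]), tolerance=snap_tolerance)
            if loc is None:
                dropped += 1
                continue
        spines.append(
            make_spine(
                net,
                loc,
                str(row["type"]),
                div=int(row.get("div", 7)),
                experiment=int(row.get("experiment", 1)),
            )
        )
    if dropped:
        logger.warning("dropped %d spines beyond %.2f μm snap tolerance", dropped, snap_tolerance)
    pat = SpinePattern(network=net, spines=spines, dendrite_id=Path(swc_path).stem)
    pat.n_dropped = dropped
    return pat


def write_annotations(pattern: SpinePattern, swc_path, spine_table_path) -> None:
    """Write the tree as SWC and the spines as CSV (lossless round trip)."""
    write_swc(pattern.network, swc_path)
    df = pattern.as_dataframe()
    df.to_csv(spine_table_path, index=False, float_format="%.9f")
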