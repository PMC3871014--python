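"""Synthetic dendrites and spine patterns with controllable spatial structure.

The generator produces the conditions the analyses assume or must detect:
random binary trees with centrifugal branch orders, spine placement that is
homogeneous Poisson along the network (the CSR null), network Neyman–Scott
clustering and hard-core repulsion as detectable alternatives, and spine-type
sequences that are i.i.d. or carry same-type neighbor persistence (the
clustering-of-types signal).  Everything is seeded and file-writable, so the
whole pipeline is testable without any external download.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .io import write_annotations
from .network import (
    LinearNetwork,
    NetworkLocation,
    SpinePattern,
    build_network,
    make_spine,
)

DEFAULT_PROPORTIONS = (0.39, 0.44, 0.17)  # mushroom, stubby, thin
TYPE_NAMES = ("mushroom", "stubby", "thin")

#: Spine densities (spines per μm) by DIV; density grows with culture age.
DEFAULT_DENSITY_BY_DIV = {7: 0.25, 14: 0.45, 21: 0.65}


@dataclass
class TreeSpec:
    """Random binary tree: at every segment end, bifurcate with probability
    ``branch_prob`` (until ``max_order``) or terminate; lognormal segment
    lengths with median ``length_median`` μm."""

    branch_prob: float = 0.7
    length_median: float = 30.0
    length_sigma: float = 0.45
    max_order: int = 5
    turn_sd_deg: float = 25.0


@dataclass
class PlacementSpec:
    mode: str = "csr"  # csr | cluster | hardcore
    intensity: float = 0.4  # spines per μm (csr, hardcore)
    parent_intensity: float = 0.02  # parents per μm (cluster)
    offspring_mean: float = 8.0  # mean offspring per parent (cluster)
    offspring_scale: float = 2.0  # half-normal displacement scale, μm
    hardcore_radius: float = 2.0  # minimum gap, μm


@dataclass
class TypeSpec:
    mode: str = "iid"  # iid | markov
    proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    persistence: float = 0.0  # rho: probability of copying the previous type


# ----------------------------------------------------------------- tree growth
def generate_tree(
    spec: TreeSpec, rng: np.random.Generator, origin=(0.0, 0.0)
) -> LinearNetwork:
    """Grow a seeded random dendrite tree with centrifugal branch orders."""
    mu = np.log(spec.length_median)
    nodes = [dict(id=1, x=float(origin[0]), y=float(origin[1]), parent=-1)]
    next_id = 2
    # (parent node id, parent coords, direction angle) for pending segments
    initial_angle = rng.uniform(0, 2 * np.pi)
    stack = [(1, np.asarray(origin, dtype=float), initial_angle, 1)]
    while stack:
        pid, pxy, angle, order = stack.pop()
        L = float(rng.lognormal(mu, spec.length_sigma))
        xy = pxy + L * np.array([np.cos(angle), np.sin(angle)])
        nid = next_id
        next_id += 1
        nodes.append(dict(id=nid, x=float(xy[0]), y=float(xy[1]), parent=pid))
        if order < spec.max_order and rng.random() < spec.branch_prob:
            spread = np.deg2rad(rng.normal(30.0, 8.0))
            for sgn in (-1.0, 1.0):
                turn = sgn * spread / 2 + np.deg2rad(rng.normal(0, spec.turn_sd_deg / 4))
                stack.append((nid, xy, angle + turn, order + 1))
    if len(nodes) < 2:
        raise ValidationError("tree generation yielded zero segments")
    import pandas as pd

    return build_network(pd.DataFrame(nodes))


# ------------------------------------------------------------- spine placement
def _adjacency(net: LinearNetwork):
    """node index -> list of (segment index, 'toward child'? direction flag)."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for si in range(net.n_segments):
        adj.setdefault(net.seg_parent[si], []).append((si, +1))
        adj.setdefault(net.seg_child[si], []).append((si, -1))
    return adj


def _network_walk(
    net: LinearNetwork, loc: NetworkLocation, r: float, rng: np.random.Generator, adj
) -> NetworkLocation:
    """Move distance r from loc in a uniformly random direction, choosing
    uniformly among continuations at nodes; stops early at tips."""
    si = net.segment_index(loc.segment)
    pos = loc.offset
    direction = 1 if rng.random() < 0.5 else -1
    remaining = r
    while remaining > 0:
        room = net.seg_length[si] - pos if direction > 0 else pos
        if remaining <= room:
            pos = pos + direction * remaining
            return NetworkLocation(net.seg_ids[si], float(pos))
        remaining -= room
        node = net.seg_child[si] if direction > 0 else net.seg_parent[si]
        options = [(s, d) for s, d in adj[node] if s != si]
        if not options:  # tip: stop here
            return NetworkLocation(
                net.seg_ids[si], float(net.seg_length[si] if direction > 0 else 0.0)
            )
        si, d = options[rng.integers(len(options))]
        direction = d
        pos = 0.0 if d > 0 else float(net.seg_length[si])
    return NetworkLocation(net.seg_ids[si], float(pos))


def place_spines(
    net: LinearNetwork,
    placement: PlacementSpec,
    rng: np.random.Generator,
    div: int = 7,
    experiment: int = 1,
    dendrite_id: str = "synthetic",
) -> SpinePattern:
    """Place a spine pattern on the network under the requested mode.

    ``csr``: Poisson(λ·ℓ_T) spines uniform by arc length.  ``cluster``:
    network Neyman–Scott — CSR parents, Poisson offspring counts, offspring
    displaced along the network by half-normal distances.  ``hardcore``: CSR
    followed by sequential thinning to a minimum pairwise gap.
    """
    lT = net.total_length
    locs: list[NetworkLocation] = []
    if placement.mode == "csr":
        if placement.intensity <= 0:
            raise ValidationError("csr mode needs intensity > 0")
        n = rng.poisson(placement.intensity * lT)
        locs = [net.location_at_arc(a) for a in np.sort(rng.uniform(0, lT, n))]
    elif placement.mode == "cluster":
        if placement.parent_intensity <= 0:
            raise ValidationError("cluster mode needs parent_intensity > 0")
        adj = _adjacency(net)
        n_par = max(int(rng.poisson(placement.parent_intensity * lT)), 1)
        parents = [net.location_at_arc(a) for a in rng.uniform(0, lT, n_par)]
        for par in parents:
            for _ in range(rng.poisson(placement.offspring_mean)):
                r = abs(rng.normal(0, placement.offspring_scale))
                locs.append(_network_walk(net, par, r, rng, adj))
        locs.sort(key=lambda l: (net.segment_index(l.segment), l.offset))
    elif placement.mode == "hardcore":
        n = rng.poisson(placement.intensity * lT)
        cand = [net.location_at_arc(a) for a in np.sort(rng.uniform(0, lT, n))]
        expected = placement.intensity * lT * np.exp(
            -2 * placement.intensity * placement.hardcore_radius
        )
        if expected < 1:
            import logging

            logging.getLogger(__name__).warning(
                "hardcore radius %.2f leaves < 1 expected spine", placement.hardcore_radius
            )
        kept: list[NetworkLocation] = []
        for c in cand:
            if all(net.distance(c, k) >= placement.hardcore_radius for k in kept):
                kept.append(c)
        locs = kept
    else:
        raise ValidationError(f"unknown placement mode {placement.mode!r}")
    spines = [make_spine(net, l, "mushroom", div=div, experiment=experiment) for l in locs]
    return SpinePattern(network=net, spines=spines, dendrite_id=dendrite_id)


# -------------------------------------------------------------- type sequences
def _dfs_segment_rank(net: LinearNetwork) -> dict[int, int]:
    children: dict[int, list[int]] = {}
    for si in range(net.n_segments):
        children.setdefault(net.seg_parent[si], []).append(si)
    root_idx = net.node_ids.index(net.root)
    rank, stack, k = {}, [root_idx], 0
    order_stack = []
    # DFS over segments
    seg_stack = list(reversed(children.get(root_idx, [])))
    while seg_stack:
        si = seg_stack.pop()
        rank[si] = k
        k += 1
        seg_stack.extend(reversed(children.get(net.seg_child[si], [])))
    return rank


def assign_types(
    pattern: SpinePattern, typespec: TypeSpec, rng: np.random.Generator
) -> SpinePattern:
    """Assign spine types i.i.d. or with same-type persistence ρ.

    The markov chain runs along the depth-first arc-length ordering of the
    spines: each spine copies the previous spine's type with probability ρ
    and otherwise draws from the base proportions, so long-run marginals
    equal the base proportions.
    """
    props = np.asarray(typespec.proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValidationError("type proportions must sum to 1")
    if pattern.n == 0:
        raise ValidationError("cannot assign types to an empty pattern")
    net = pattern.network
    rank = _dfs_segment_rank(net)
    order = sorted(
        range(pattern.n),
        key=lambda i: (
            rank[net.segment_index(pattern.spines[i].location.segment)],
            pattern.spines[i].location.offset,
        ),
    )
    types = [""] * pattern.n
    prev: int | None = None
    for i in order:
        if typespec.mode == "markov" and prev is not None and rng.random() < typespec.persistence:
            code = prev
        else:
            code = int(rng.choice(3, p=props))
        types[i] = TYPE_NAMES[code]
        prev = code
    new_spines = [
        make_spine(net, s.location, types[i], div=s.div, experiment=s.experiment)
        for i, s in enumerate(pattern.spines)
    ]
    return SpinePattern(
        network=net,
        spines=new_spines,
        window=pattern.window,
        dendrite_id=pattern.dendrite_id,
    )


# ------------------------------------------------------------- study fixtures
@dataclass
class StudySpec:
    """Design of a synthetic study: neurons per DIV per experiment, with
    densities rising with DIV and optional type persistence."""

    n_neurons_per_div: int = 2
    experiments: tuple[int, ...] = (1,)
    divs: tuple[int, ...] = (7, 14, 21)
    tree: TreeSpec = field(default_factory=TreeSpec)
    density_by_div: dict = field(default_factory=lambda: dict(DEFAULT_DENSITY_BY_DIV))
    placement_mode: str = "csr"
    type_spec: TypeSpec = field(default_factory=TypeSpec)
    seed: int = 0


def generate_study(spec: StudySpec) -> list[SpinePattern]:
    """Generate all dendrite patterns of a synthetic study (seeded)."""
    rng = np.random.default_rng(spec.seed)
    patterns = []
    for exp in spec.experiments:
        for div in spec.divs:
            for j in range(spec.n_neurons_per_div):
                net = generate_tree(spec.tree, rng)
                placement = PlacementSpec(
                    mode=spec.placement_mode, intensity=spec.density_by_div[div]
                )
                pat = place_spines(
                    net,
                    placement,
                    rng,
                    div=div,
                    experiment=exp,
                    dendrite_id=f"exp{exp}_div{div}_n{j}",
                )
                if pat.n == 0:
                    continue
                pat = assign_types(pat, spec.type_spec, rng)
                xs = net.coords[:, 0]
                ys = net.coords[:, 1]
                pad = 15.0
                pat.window = (
                    float(xs.min() - pad),
                    float(xs.max() + pad),
                    float(ys.min() - pad),
                    float(ys.max() + pad),
                )
                patterns.append(pat)
    return patterns


def make_study_fixture(out_dir, spec: StudySpec) -> dict:
    """Write SWC + spine CSV per dendrite plus a JSON manifest; returns the
    manifest.  Regenerating from the manifest's seed reproduces the files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patterns = generate_study(spec)
    entries = []
    for pat in patterns:
        swc = out / f"{pat.dendrite_id}.swc"
        csv = out / f"{pat.dendrite_id}.csv"
        write_annotations(pat, swc, csv)
        entries.append(
            dict(
                dendrite_id=pat.dendrite_id,
                swc=swc.name,
                spines=csv.name,
                n_spines=pat.n,
                div=pat.spines[0].div,
                experiment=pat.spines[0].experiment,
                window=pat.window,
            )
        )
    manifest = dict(
        spec={
            **asdict(spec),
            "tree": asdict(spec.tree),
            "type_spec": asdict(spec.type_spec),
        },
        seed=spec.seed,
        dendrites=entries,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
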