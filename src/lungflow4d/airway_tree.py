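"""Airway lumen segmentation and tree extraction.

The airway tree is segmented from the reference (end-expiratory) volume by
intensity flood fill from a tracheal seed, skeletonized to a centerline, and
converted into a rooted graph of segments.  An *endpoint* is the most distal
segment of the tree: a segment that has a parent segment but no daughter
segments.  Each endpoint supplies a region of lung tissue; the set of
endpoints therefore defines the granularity of the regional analysis and is
a resolution-dependent property of the segmentation.

Trees are stored as nodes (centerline points with a radius from the
distance transform) grouped into segments (branch-to-branch paths).  SWC
is the on-disk format (one node row: id, type, x, y, z, radius, parent).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize

from .errors import DegenerateTreeError, SeedError, StructuralError

__all__ = [
    "AirwayNode",
    "AirwaySegment",
    "AirwayTree",
    "flood_fill_segment",
    "skeletonize_to_graph",
    "find_endpoints",
    "read_swc",
    "write_swc",
]

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class AirwayNode:
    """A centerline point: position in micrometres and local airway radius."""

    id: int
    position: np.ndarray  # (3,) um
    radius: float  # um


@dataclass
class AirwaySegment:
    """A branch of the airway tree: an ordered proximal-to-distal node path."""

    id: int
    parent: int | None
    nodes: list[int] = field(default_factory=list)


class AirwayTree:
    """Rooted airway tree: nodes, segments, and the trachea as root.

    Invariants: exactly one root segment (``parent is None``); acyclic;
    every non-root segment has exactly one parent.  Endpoints are segments
    with a parent but no daughters, so a single-segment tree is degenerate
    (it has no endpoints).
    """

    def __init__(
        self,
        nodes: dict[int, AirwayNode],
        segments: dict[int, AirwaySegment],
        root: int,
    ) -> None:
        self.nodes = nodes
        self.segments = segments
        self.root = root
        self._children: dict[int, list[int]] = {sid: [] for sid in segments}
        n_roots = 0
        for seg in segments.values():
            if seg.parent is None:
                n_roots += 1
            else:
                if seg.parent not in segments:
                    raise StructuralError(f"segment {seg.id}: unknown parent {seg.parent}")
                self._children[seg.parent].append(seg.id)
        if n_roots != 1 or segments[root].parent is not None:
            raise StructuralError("tree must have exactly one root segment")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise StructuralError("cycle detected in airway tree")
            seen.add(sid)
            stack.extend(self._children[sid])
        if len(seen) != len(self.segments):
            raise StructuralError("tree contains segments unreachable from the root")

    # -- structure queries ------------------------------------------------

    def children(self, seg_id: int) -> list[int]:
        """Daughter segment ids, ordered by distal-node position."""
        kids = self._children[seg_id]
        return sorted(kids, key=lambda s: tuple(self.distal_node(s).position))

    def distal_node(self, seg_id: int) -> AirwayNode:
        return self.nodes[self.segments[seg_id].nodes[-1]]

    def proximal_node(self, seg_id: int) -> AirwayNode:
        return self.nodes[self.segments[seg_id].nodes[0]]

    def segment_length(self, seg_id: int) -> float:
        """Path length of a segment in micrometres."""
        pts = np.array([self.nodes[n].position for n in self.segments[seg_id].nodes])
        if len(pts) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def dfs_segments(self) -> list[int]:
        """Depth-first preorder of segment ids, daughters by position."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            sid = stack.pop()
            order.append(sid)
            stack.extend(reversed(self.children(sid)))
        return order

    @property
    def endpoint_ids(self) -> list[int]:
        return find_endpoints(self, strict=False)

    @property
    def is_degenerate(self) -> bool:
        return len(self.endpoint_ids) == 0

    def endpoint_positions(self) -> np.ndarray:
        """Distal-node positions of all endpoints, (E, 3) in um."""
        return np.array([self.distal_node(e).position for e in self.endpoint_ids])


def find_endpoints(tree: AirwayTree, strict: bool = True) -> list[int]:
    """Endpoint segment ids in deterministic depth-first order.

    An endpoint has a parent segment but no daughter segments.  For a
    degenerate single-segment tree the list is empty; with ``strict`` a
    :class:`DegenerateTreeError` is raised instead.
    """
    eps = [
        sid
        for sid in tree.dfs_segments()
        if tree.segments[sid].parent is not None and not tree._children[sid]
    ]
    if strict and not eps:
        raise DegenerateTreeError("tree has no endpoints")
    return eps


# ---------------------------------------------------------------------------
# segmentation


def flood_fill_segment(
    volume: np.ndarray,
    seed_point: tuple[int, int, int],
    intensity_window: tuple[float, float],
) -> np.ndarray:
    """26-connected flood fill of the intensity window containing the seed.

    Returns the binary lumen mask.  The seed intensity must lie inside the
    window; a component that touches the volume boundary triggers a leak
    warning (the fill may have escaped the airway).
    """
    lo, hi = intensity_window
    seed = tuple(int(s) for s in seed_point)
    val = float(volume[seed])
    if not lo <= val <= hi:
        raise SeedError(f"seed intensity {val} outside window [{lo}, {hi}]")
    window = (volume >= lo) & (volume <= hi)
    labels, _ = ndi.label(window, structure=_STRUCT26)
    mask = labels == labels[seed]
    if (
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    ):
        warnings.warn("flood-fill component touches the volume boundary (possible leak)")
    return mask


_NEIGHBOR_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) > (0, 0, 0)
    ]
)  # half of the 26-neighborhood; the graph is undirected


def skeletonize_to_graph(
    mask: np.ndarray,
    root_hint: tuple[int, int, int],
    voxel_spacing_um: float | tuple[float, float, float] = 1.0,
    prune_factor: float = 2.0,
) -> AirwayTree:
    """Skeletonize a binary lumen mask and convert it to a rooted tree.

    3D thinning produces a one-voxel centerline; its 26-connected voxel
    graph is rooted at the skeleton point nearest ``root_hint`` and
    compressed into branch segments.  Spur branches shorter than
    ``prune_factor`` times the local radius (distance-transform value at
    the branch origin) are removed.  Any cycle left by thinning is broken
    by a minimum-spanning-tree pass (logged).

    Node positions are in micrometres (index * spacing, grid-corner
    origin); radii come from the Euclidean distance transform of the mask.
    """
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.broadcast_to(np.asarray(voxel_spacing_um, dtype=float), (3,)).copy()
    skel = skeletonize(mask.astype(bool))
    coords = np.argwhere(skel)
    if len(coords) == 0:  # pathological tiny mask; fall back to mask voxels
        coords = np.argwhere(mask)
    index = {tuple(c): i for i, c in enumerate(coords)}

    G = nx.Graph()
    G.add_nodes_from(range(len(coords)))
    for i, c in enumerate(coords):
        for off in _NEIGHBOR_OFFSETS:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                G.add_edge(i, j, weight=float(np.linalg.norm(off * spacing)))

    root_idx = int(np.argmin(np.sum(((coords - np.asarray(root_hint)) * spacing) ** 2, axis=1)))
    comp = nx.node_connected_component(G, root_idx)
    if len(comp) < len(coords):
        log.warning("skeleton not connected: keeping root component (%d/%d voxels)",
                    len(comp), len(coords))
        G = G.subgraph(comp).copy()
    if G.number_of_edges() >= G.number_of_nodes():
        log.warning("cycles after thinning: breaking with minimum spanning tree")
        G = nx.minimum_spanning_tree(G, weight="weight")

    dist = ndi.distance_transform_edt(mask, sampling=spacing)
    radii = dist[tuple(coords.T)]
    positions = coords * spacing

    # directed tree of skeleton voxels
    parent: dict[int, int | None] = {root_idx: None}
    children: dict[int, list[int]] = {i: [] for i in G.nodes}
    for u, v in nx.bfs_edges(G, root_idx):
        parent[v] = u
        children[u].append(v)

    def branch_tips(node: int) -> list[list[int]]:
        """Walk from ``node``'s children, splitting the voxel tree into
        segment paths (each path starts at its branch voxel)."""
        paths = []
        for ch in children[node]:
            path = [node, ch]
            cur = ch
            while len(children[cur]) == 1:
                cur = children[cur][0]
                path.append(cur)
            paths.append(path)
        return paths

    # build segment tree recursively from the voxel tree
    seg_nodes: dict[int, list[int]] = {}
    seg_parent: dict[int, int | None] = {}
    counter = 0

    def build(start_voxel: int, parent_seg: int | None) -> None:
        nonlocal counter
        for path in branch_tips(start_voxel):
            sid = counter
            counter += 1
            seg_nodes[sid] = path
            seg_parent[sid] = parent_seg
            build(path[-1], sid)

    # the root segment starts at the root voxel itself
    root_path = [root_idx]
    cur = root_idx
    while len(children[cur]) == 1:
        cur = children[cur][0]
        root_path.append(cur)
    root_sid = counter
    counter += 1
    seg_nodes[root_sid] = root_path
    seg_parent[root_sid] = None
    build(root_path[-1], root_sid)

    def path_len(path: list[int]) -> float:
        pts = positions[path]
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()) if len(pts) > 1 else 0.0

    # iterative spur pruning + chain merging
    changed = True
    while changed:
        changed = False
        kids: dict[int, list[int]] = {s: [] for s in seg_nodes}
        for s, p in seg_parent.items():
            if p is not None:
                kids[p].append(s)
        # prune short leaf spurs, but only where a sibling remains
        for s in list(seg_nodes):
            p = seg_parent[s]
            if p is None or kids[s]:
                continue
            prune_len = prune_factor * float(radii[seg_nodes[s][0]])
            if path_len(seg_nodes[s]) < prune_len and len(kids[p]) > 1:
                del seg_nodes[s], seg_parent[s]
                changed = True
        if changed:
            continue
        # merge pass-through segments (single child) into their parent
        for s in list(seg_nodes):
            ch = kids.get(s, [])
            if len(ch) == 1 and ch[0] in seg_nodes:
                c = ch[0]
                seg_nodes[s] = seg_nodes[s] + seg_nodes[c][1:]
                for g in kids.get(c, []):
                    seg_parent[g] = s
                del seg_nodes[c], seg_parent[c]
                changed = True
                break

    used = sorted({v for path in seg_nodes.values() for v in path})
    nodes = {
        v: AirwayNode(id=v, position=positions[v].astype(float), radius=float(radii[v]))
        for v in used
    }
    segments = {
        s: AirwaySegment(id=s, parent=seg_parent[s], nodes=list(path))
        for s, path in seg_nodes.items()
    }
    tree = AirwayTree(nodes, segments, root=root_sid)
    if tree.is_degenerate:
        log.warning("skeleton produced a single-segment tree: no endpoints (degenerate)")
    return tree


# ---------------------------------------------------------------------------
# SWC I/O


def write_swc(tree: AirwayTree, path) -> None:
    """Write the tree as SWC (id, type, x, y, z, radius, parent)."""
    lines = ["# SWC airway tree", "# id type x y z radius parent"]
    written: dict[int, int] = {}
    swc_id = 0
    for sid in tree.dfs_segments():
        seg = tree.segments[sid]
        ntype = 1 if seg.parent is None else 2
        prev: int | None = None
        if seg.parent is not None:
            prev = written[tree.segments[seg.parent].nodes[-1]]
        for nid in seg.nodes:
            if nid in written:
                prev = written[nid]
                continue
            swc_id += 1
            written[nid] = swc_id
            node = tree.nodes[nid]
            p = -1 if prev is None else prev
            x, y, z = node.position
            lines.append(f"{swc_id} {ntype} {x:.3f} {y:.3f} {z:.3f} {node.radius:.3f} {p}")
            prev = swc_id
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_swc(path) -> AirwayTree:
    """Read an SWC file back into an :class:`AirwayTree`."""
    raw: dict[int, tuple[np.ndarray, float, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            raw[int(f[0])] = (np.array([float(f[2]), float(f[3]), float(f[4])]),
                              float(f[5]), int(f[6]))
    children: dict[int, list[int]] = {i: [] for i in raw}
    roots = []
    for nid, (_, _, p) in raw.items():
        if p == -1:
            roots.append(nid)
        else:
            children[p].append(nid)
    if len(roots) != 1:
        raise StructuralError(f"SWC must have exactly one root, found {len(roots)}")

    nodes = {nid: AirwayNode(id=nid, position=pos, radius=r)
             for nid, (pos, r, _) in raw.items()}
    seg_nodes: dict[int, list[int]] = {}
    seg_parent: dict[int, int | None] = {}
    counter = 0

    def walk(start: int, first: int | None, parent_seg: int | None) -> None:
        nonlocal counter
        path = [first, start] if first is not None else [start]
        cur = start
        while len(children[cur]) == 1:
            cur = children[cur][0]
            path.append(cur)
        sid = counter
        counter += 1
        seg_nodes[sid] = path
        seg_parent[sid] = parent_seg
        for ch in children[cur]:
            walk(ch, cur, sid)

    walk(roots[0], None, None)
    segments = {s: AirwaySegment(id=s, parent=seg_parent[s], nodes=p)
                for s, p in seg_nodes.items()}
    return AirwayTree(nodes, segments, root=0)
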