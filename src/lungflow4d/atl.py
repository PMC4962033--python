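"""Airway Tree Link: tissue-to-endpoint assignment and flow by continuity.

Each piece of lung tissue is supplied by the most distal segmentable
airway, so every masked grid point is assigned to the endpoint whose
distal node is nearest (Euclidean distance, ties to the smaller endpoint
id).  The volume change of an endpoint's tissue over a frame interval
gives its airflow; assuming negligible gas compressibility, continuity
makes the flow through any parent segment the sum of its daughters', so a
post-order traversal propagates endpoint flows up to the trachea.
Inspiratory flow (into tissue) is positive, and flows are timestamped at
frame-interval midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .airway_tree import AirwayTree, find_endpoints
from .errors import DegenerateTreeError, StructuralError
from .protocol import VentilationProtocol

__all__ = ["RegionAssignment", "FlowWaveform", "assign_tissue",
           "endpoint_flows", "propagate_flows"]


@dataclass
class RegionAssignment:
    """Mapping from masked grid points to supplying endpoints.

    ``labels[i]`` is the endpoint id of point ``i``; ``point_index`` holds
    each point's flat index into the displacement/expansion grid so maps
    can be sampled without re-deriving geometry.  ``endpoint_volumes`` is
    the supplied tissue volume per endpoint at the reference frame (uL).
    """

    endpoint_ids: list[int]
    labels: np.ndarray  # (N,) int endpoint id per point
    points_um: np.ndarray  # (N, 3)
    point_index: np.ndarray  # (N,) flat grid index
    cell_volume_ul: float
    endpoint_volumes: dict[int, float] = field(default_factory=dict)

    @property
    def total_volume(self) -> float:
        return float(sum(self.endpoint_volumes.values()))


@dataclass
class FlowWaveform:
    """Time-resolved airflow of one airway segment (uL/s, inspiratory
    positive), sampled at frame-interval midpoints."""

    segment_id: int
    times: np.ndarray  # (n_frames,) s
    flow: np.ndarray  # (n_frames,) uL/s
    missing: bool = False


def assign_tissue(
    points_um: np.ndarray,
    tree: AirwayTree,
    cell_volume_ul: float = 1.0,
    point_index: np.ndarray | None = None,
) -> RegionAssignment:
    """Nearest-endpoint assignment of masked grid points.

    ``points_um`` is (N, 3) in micrometres; each point goes to the
    endpoint whose distal node is nearest, ties broken toward the smaller
    endpoint id.  ``cell_volume_ul`` is the tissue volume represented by
    one grid cell, so per-endpoint supplied volumes are cell counts times
    that value.
    """
    endpoints = find_endpoints(tree)
    if not endpoints:
        raise DegenerateTreeError("cannot assign tissue: tree has no endpoints")
    eids = sorted(endpoints)
    targets = np.array([tree.distal_node(e).position for e in eids])
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if point_index is None:
        point_index = np.arange(len(pts))

    # chunked exact nearest search; argmin takes the first (= smallest id)
    # among exactly tied columns because eids are sorted ascending
    labels = np.empty(len(pts), dtype=int)
    chunk = 65536
    for s in range(0, len(pts), chunk):
        block = pts[s:s + chunk]
        d2 = ((block[:, None, :] - targets[None, :, :]) ** 2).sum(axis=2)
        labels[s:s + chunk] = np.argmin(d2, axis=1)
    labels = np.asarray(eids, dtype=int)[labels]

    volumes = {eid: float(np.count_nonzero(labels == eid) * cell_volume_ul)
               for eid in eids}
    return RegionAssignment(
        endpoint_ids=eids,
        labels=labels,
        points_um=pts,
        point_index=np.asarray(point_index),
        cell_volume_ul=float(cell_volume_ul),
        endpoint_volumes=volumes,
    )


def endpoint_flows(
    assignment: RegionAssignment,
    per_interval_delta_v: np.ndarray | dict[int, np.ndarray],
    protocol: VentilationProtocol,
) -> dict[int, FlowWaveform]:
    """Endpoint airflow waveforms from per-interval volume changes.

    ``per_interval_delta_v`` maps endpoint id to its n_frames volume
    changes (uL); flow at each interval midpoint is dV / dt with
    dt = period / n_frames.  Endpoints whose volume changes contain NaN
    are marked missing (zero flow, excluded from cohort statistics but
    still counted in supplied-volume totals).
    """
    times = protocol.midpoint_times()
    dt = protocol.dt
    out: dict[int, FlowWaveform] = {}
    for eid in assignment.endpoint_ids:
        dv = np.asarray(per_interval_delta_v[eid], dtype=float)
        if dv.shape != (protocol.n_frames,):
            raise ValueError(
                f"endpoint {eid}: expected {protocol.n_frames} interval volume changes"
            )
        if np.isnan(dv).any():
            out[eid] = FlowWaveform(eid, times.copy(), np.zeros_like(times),
                                    missing=True)
        else:
            out[eid] = FlowWaveform(eid, times.copy(), dv / dt)
    return out


def propagate_flows(
    tree: AirwayTree,
    flows: dict[int, FlowWaveform],
) -> dict[int, FlowWaveform]:
    """Flow in every tree segment by recursive summation (continuity).

    Endpoint flows are given; each internal segment's waveform is the sum
    of its daughters', computed post-order, so the root (trachea) carries
    the sum over all endpoints.  Endpoints missing a waveform are treated
    as zero flow with their ``missing`` flag preserved.
    """
    endpoints = set(find_endpoints(tree, strict=False))
    n = None
    for wf in flows.values():
        n = len(wf.flow)
        times = wf.times
        break
    if n is None:
        raise ValueError("no endpoint flows supplied")

    result: dict[int, FlowWaveform] = {}
    visiting: set[int] = set()

    def visit(sid: int) -> np.ndarray:
        if sid in visiting:
            raise StructuralError("cycle detected while propagating flows")
        if sid in result:
            return result[sid].flow
        visiting.add(sid)
        kids = tree.children(sid)
        if not kids:
            wf = flows.get(sid)
            if wf is None:
                if sid in endpoints:
                    wf = FlowWaveform(sid, times.copy(), np.zeros(n), missing=True)
                else:  # degenerate lone root
                    wf = FlowWaveform(sid, times.copy(), np.zeros(n), missing=True)
            result[sid] = wf
        else:
            total = np.zeros(n)
            for k in kids:
                total = total + visit(k)
            result[sid] = FlowWaveform(sid, times.copy(), total)
        visiting.discard(sid)
        return result[sid].flow

    visit(tree.root)
    # ensure every segment was reached (disconnected pieces are structural)
    for sid in tree.segments:
        if sid not in result:
            visit(sid)
    return result
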