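"""Synthetic 4D lung phantom with known mechanics and motion ground truth.

The phantom stands in for reconstructed 4D image data: a rooted binary
airway tree whose endpoints each feed a ball of speckle-textured "tissue",
driven by a single-compartment RC model of pressure-controlled ventilation.
Every downstream stage (PIV, expansion, segmentation, flow linking,
function metrics) can therefore be tested against analytic truth.

Mechanics.  Each endpoint compartment obeys

    dV/dt = (P_aw(t) - (V - V_rest)/C) / R

with a square airway-pressure wave between PIP and PEEP (pressures
referenced to PEEP, so ``V_rest`` is the static volume at PEEP).  The
periodic steady-state cycle has a closed form: piecewise exponentials with
time constant tau = R*C, matched across the inspiration/expiration valve
switches.  The generator draws tau per endpoint from a healthy normal
distribution; a configurable fraction of the rest volume is re-drawn from a
diseased (slower) distribution and a fraction of endpoints is fully
obstructed (zero flow, frozen at rest volume) — emulating patchy
muco-obstructive disease.

Geometry.  Compartments are disjoint balls (real supplied-tissue regions
are irregular; balls admit an exact analytic warp).  Frame ``f`` is
rendered by radially scaling each ball's reference speckle texture so its
volume matches the compartment volume V(t_f); the reference frame is peak
expiration (minimum total volume).  The airway lumen is rendered as dark
static tubes so intensity flood fill can recover the tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .airway_tree import AirwayNode, AirwaySegment, AirwayTree, find_endpoints
from .errors import ConfigurationError, DegenerateTreeError, ParameterError
from .protocol import VentilationProtocol

__all__ = [
    "DiseaseConfig",
    "Compartment",
    "CompartmentSim",
    "VolumeSeries",
    "PhantomGroundTruth",
    "generate_tree",
    "simulate_compartments",
    "render_volumes",
    "periodic_state",
    "compartment_volume",
    "compartment_flow",
]

# rendering intensity levels (arbitrary units); flood-fill window for the
# lumen is anything below BG - margin
LUMEN_VALUE = 10.0
BACKGROUND_VALUE = 60.0
TISSUE_LO = 100.0
TISSUE_HI = 200.0
TISSUE_MEAN = 150.0
TISSUE_SD = 25.0


@dataclass(frozen=True)
class DiseaseConfig:
    """Disease severity knobs for the phantom population.

    Time constants are drawn per endpoint: healthy endpoints from
    N(healthy_tau_mean, healthy_tau_sd), and endpoints supplying
    ``diseased_volume_fraction`` of the total rest volume from the diseased
    distribution.  ``blockage_fraction`` of endpoints (taken from the
    diseased subset first) are fully obstructed.  Defaults reproduce the
    healthy condition: tau ~ N(0.12 s, 0.022 s), no disease.
    """

    diseased_volume_fraction: float = 0.0
    healthy_tau_mean: float = 0.12
    healthy_tau_sd: float = 0.022
    diseased_tau_mean: float = 0.22
    diseased_tau_sd: float = 0.037
    blockage_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.diseased_volume_fraction, self.blockage_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for tau in (self.healthy_tau_mean, self.healthy_tau_sd,
                    self.diseased_tau_mean, self.diseased_tau_sd):
            if tau <= 0:
                raise ValueError("tau distribution parameters must be positive")

    @classmethod
    def healthy(cls, seed: int = 0) -> "DiseaseConfig":
        return cls(seed=seed)

    @classmethod
    def bimodal_diseased(cls, seed: int = 0,
                         diseased_volume_fraction: float = 0.5,
                         blockage_fraction: float = 0.05) -> "DiseaseConfig":
        """Muco-obstructive phenotype: a bimodal tau population with modes
        near 0.13 s and 0.22 s plus a small fraction of full obstructions."""
        return cls(
            diseased_volume_fraction=diseased_volume_fraction,
            healthy_tau_mean=0.13,
            healthy_tau_sd=0.038,
            diseased_tau_mean=0.22,
            diseased_tau_sd=0.037,
            blockage_fraction=blockage_fraction,
            seed=seed,
        )


@dataclass
class Compartment:
    """Single-compartment mechanics of one endpoint's supplied tissue."""

    endpoint_id: int
    R: float  # cmH2O*s/uL
    C: float  # uL/cmH2O
    obstructed: bool
    center: np.ndarray  # (3,) um, the endpoint's distal node
    rest_volume: float  # uL, static volume at PEEP

    def __post_init__(self) -> None:
        if self.R <= 0 or self.C <= 0:
            raise ParameterError("R and C must be positive")

    @property
    def tau(self) -> float:
        """RC time constant (s)."""
        return self.R * self.C


# ---------------------------------------------------------------------------
# tree generation


def generate_tree(
    n_generations: int,
    branch_angle: float = 1.05,
    length_ratio: float = 0.5,
    domain: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.0, 0.0, 0.0),
        (2560.0, 2560.0, 2560.0),
    ),
    seed: int = 0,
    jitter: float = 0.0,
    trachea_fraction: float = 0.18,
    trachea_radius: float = 80.0,
    radius_ratio: float = 0.75,
) -> AirwayTree:
    """Deterministic rooted binary airway tree inside ``domain`` (um).

    The trachea descends from the top of the domain; each generation
    bifurcates along alternating lateral axes (x then y).  The lateral
    offset of the k-th split along an axis is ``extent/4 * length_ratio**k``
    and the descent per generation is offset / tan(branch_angle), so the
    2**n endpoints land on a regular, well-separated grid.  ``jitter``
    (fraction of the local offset, seeded) perturbs daughter positions.

    Raises :class:`DegenerateTreeError` for ``n_generations == 0`` — a
    lone trachea has no segment with a parent, hence no endpoints.
    """
    if n_generations < 1:
        raise DegenerateTreeError("n_generations must be >= 1 to produce endpoints")
    lo = np.asarray(domain[0], dtype=float)
    hi = np.asarray(domain[1], dtype=float)
    extent = hi - lo
    if np.any(extent <= 0):
        raise ValueError("domain must have positive extent")
    rng = np.random.default_rng(seed)
    tan_a = math.tan(branch_angle)
    if tan_a <= 0:
        raise ValueError("branch_angle must lie in (0, pi/2)")

    nodes: dict[int, AirwayNode] = {}
    segments: dict[int, AirwaySegment] = {}
    node_counter = 0
    seg_counter = 0

    def add_node(pos: np.ndarray, radius: float) -> int:
        nonlocal node_counter
        nid = node_counter
        node_counter += 1
        nodes[nid] = AirwayNode(id=nid, position=pos.astype(float), radius=radius)
        return nid

    def add_segment(parent: int | None, node_ids: list[int]) -> int:
        nonlocal seg_counter
        sid = seg_counter
        seg_counter += 1
        segments[sid] = AirwaySegment(id=sid, parent=parent, nodes=node_ids)
        return sid

    cx, cy = lo[0] + extent[0] / 2.0, lo[1] + extent[1] / 2.0
    start = np.array([cx, cy, lo[2] + 0.04 * extent[2]])
    t_end = np.array([cx, cy, lo[2] + (0.04 + trachea_fraction) * extent[2]])
    root_prox = add_node(start, trachea_radius)
    root_dist = add_node(t_end, trachea_radius)
    root = add_segment(None, [root_prox, root_dist])

    def build(parent_seg: int, parent_node: int, gen: int) -> None:
        if gen > n_generations:
            return
        axis = (gen - 1) % 2  # x, y, x, y, ...
        k = (gen - 1) // 2  # number of earlier splits on this axis
        offset = extent[axis] / 4.0 * length_ratio**k
        descent = offset / tan_a
        radius = trachea_radius * radius_ratio**gen
        for sign in (1.0, -1.0):
            pos = nodes[parent_node].position.copy()
            pos[axis] += sign * offset
            pos[2] += descent
            if jitter > 0:
                pos += rng.normal(scale=jitter * offset, size=3)
            if np.any(pos < lo) or np.any(pos > hi):
                raise ConfigurationError(
                    f"generation {gen} node {pos} falls outside the domain; "
                    "enlarge the domain or reduce n_generations"
                )
            nid = add_node(pos, radius)
            sid = add_segment(parent_seg, [parent_node, nid])
            build(sid, nid, gen + 1)

    build(root, root_dist, 1)
    return AirwayTree(nodes, segments, root=root)


# ---------------------------------------------------------------------------
# compartment mechanics (closed-form periodic steady state)


def periodic_state(tau: float, protocol: VentilationProtocol) -> tuple[float, float]:
    """Periodic steady-state of the RC compartment under a square wave.

    Returns ``(x0, x_ei)``: the distension volume above rest at cycle start
    and at end inspiration, both as fractions of the full excursion
    ``C * (PIP - PEEP)``.
    """
    a = math.exp(-protocol.t_insp / tau)
    b = math.exp(-protocol.t_exp / tau)
    x_ei = (1.0 - a) / (1.0 - a * b)
    x0 = b * x_ei
    return x0, x_ei


def compartment_volume(comp: Compartment, protocol: VentilationProtocol, t) -> np.ndarray:
    """Absolute compartment volume V(t) in uL on the periodic cycle."""
    t = np.asarray(t, dtype=float) % protocol.period
    if comp.obstructed:
        return np.broadcast_to(comp.rest_volume, t.shape).copy()
    scale = comp.C * protocol.delta_p
    x0, x_ei = periodic_state(comp.tau, protocol)
    insp = 1.0 + (x0 - 1.0) * np.exp(-t / comp.tau)
    exp_ = x_ei * np.exp(-(t - protocol.t_insp) / comp.tau)
    x = np.where(t < protocol.t_insp, insp, exp_)
    return comp.rest_volume + scale * x


def compartment_flow(comp: Compartment, protocol: VentilationProtocol, t) -> np.ndarray:
    """Airflow dV/dt in uL/s (inspiratory positive) on the periodic cycle."""
    t = np.asarray(t, dtype=float) % protocol.period
    if comp.obstructed:
        return np.zeros_like(t)
    scale = comp.C * protocol.delta_p
    x0, x_ei = periodic_state(comp.tau, protocol)
    insp = (1.0 - x0) / comp.tau * np.exp(-t / comp.tau)
    exp_ = -x_ei / comp.tau * np.exp(-(t - protocol.t_insp) / comp.tau)
    return scale * np.where(t < protocol.t_insp, insp, exp_)


@dataclass
class CompartmentSim:
    """Compartment draws plus their sampled periodic waveforms.

    ``frame_volumes`` holds V(t_f) at the n_frames frame times (E, F);
    ``midpoint_flows`` holds the interval-average flow
    (V(t_{f+1}) - V(t_f)) / dt timestamped at the frame-interval midpoints
    (E, F) — the same quantity, at the same time stamps, that the imaging
    pipeline measures (a frame-rate-limited observation of dV/dt; the
    instantaneous closed form is available via :func:`compartment_flow`).
    """

    compartments: list[Compartment]
    protocol: VentilationProtocol
    frame_volumes: np.ndarray  # (E, F) uL
    midpoint_flows: np.ndarray  # (E, F) uL/s
    diseased: np.ndarray  # (E,) bool — tau drawn from the diseased mode
    taus: np.ndarray  # (E,) planted RC time constants

    @property
    def endpoint_ids(self) -> list[int]:
        return [c.endpoint_id for c in self.compartments]

    def total_frame_volumes(self) -> np.ndarray:
        return self.frame_volumes.sum(axis=0)


def _draw_positive_normal(rng, mean, sd, size, floor):
    vals = rng.normal(mean, sd, size=size)
    bad = vals <= floor
    while bad.any():
        vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = vals <= floor
    return vals


def simulate_compartments(
    tree: AirwayTree,
    protocol: VentilationProtocol,
    disease: DiseaseConfig,
    rest_volume_mean: float = 0.05,
    rest_volume_cv: float = 0.10,
    specific_compliance: float = 0.03,
    specific_compliance_cv: float = 0.12,
    tau_floor: float = 0.02,
) -> CompartmentSim:
    """Draw per-endpoint RC mechanics and sample their periodic waveforms.

    Each endpoint gets a rest volume (uL, mildly heterogeneous), a
    compliance ``C = specific_compliance * rest_volume`` (so the tidal
    excursion is a realistic fraction of resting volume; the CV mimics
    regional compliance variability), and a resistance ``R = tau / C``
    with tau drawn from the healthy or diseased distribution.  Endpoints
    are sorted into the diseased pool (a random subset supplying the
    configured fraction of total rest volume) before tau assignment;
    blocked endpoints are obstructed entirely (zero flow at every frame).
    """
    endpoints = find_endpoints(tree)
    E = len(endpoints)
    rng = np.random.default_rng(disease.seed)

    rest = _draw_positive_normal(
        rng, rest_volume_mean, rest_volume_cv * rest_volume_mean, E,
        floor=0.2 * rest_volume_mean,
    )
    c_spec = _draw_positive_normal(
        rng, specific_compliance, specific_compliance_cv * specific_compliance, E,
        floor=0.2 * specific_compliance,
    )

    # diseased subset: random order, accumulate until the volume fraction is met
    diseased = np.zeros(E, dtype=bool)
    if disease.diseased_volume_fraction > 0:
        order = rng.permutation(E)
        target = disease.diseased_volume_fraction * rest.sum()
        acc = 0.0
        for i in order:
            if acc >= target:
                break
            diseased[i] = True
            acc += rest[i]

    taus = np.where(
        diseased,
        _draw_positive_normal(rng, disease.diseased_tau_mean, disease.diseased_tau_sd,
                              E, tau_floor),
        _draw_positive_normal(rng, disease.healthy_tau_mean, disease.healthy_tau_sd,
                              E, tau_floor),
    )

    n_block = int(round(disease.blockage_fraction * E))
    blocked = np.zeros(E, dtype=bool)
    if n_block > 0:
        pool = np.flatnonzero(diseased)
        if len(pool) < n_block:
            extra = rng.permutation(np.flatnonzero(~diseased))[: n_block - len(pool)]
            pool = np.concatenate([pool, extra])
        blocked[rng.permutation(pool)[:n_block]] = True

    comps: list[Compartment] = []
    for i, eid in enumerate(endpoints):
        C = c_spec[i] * rest[i]
        comps.append(
            Compartment(
                endpoint_id=eid,
                R=taus[i] / C,
                C=C,
                obstructed=bool(blocked[i]),
                center=tree.distal_node(eid).position.copy(),
                rest_volume=float(rest[i]),
            )
        )

    ft = protocol.frame_times()
    frame_volumes = np.array([compartment_volume(c, protocol, ft) for c in comps])
    midpoint_flows = (np.roll(frame_volumes, -1, axis=1) - frame_volumes) / protocol.dt
    return CompartmentSim(comps, protocol, frame_volumes, midpoint_flows, diseased, taus)


# ---------------------------------------------------------------------------
# rendering


@dataclass
class VolumeSeries:
    """One respiratory cycle of reconstructed 3D volumes."""

    data: np.ndarray  # (F, X, Y, Z) float32
    voxel_spacing_um: float
    frame_times: np.ndarray  # (F,) s

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class PhantomGroundTruth:
    """Analytic truth accompanying a rendered phantom cycle."""

    tree: AirwayTree
    compartments: list[Compartment]
    centers_vox: np.ndarray  # (E, 3) ball centers in voxel coordinates
    radii_vox: np.ndarray  # (E,) reference ball radii in voxels
    scales: np.ndarray  # (E, F) linear scale factor per frame (lambda)
    frame_volumes: np.ndarray  # (F,) total lung volume, uL
    endpoint_frame_volumes: np.ndarray  # (E, F) uL
    endpoint_flows: np.ndarray  # (E, F) uL/s at interval midpoints
    label_volume: np.ndarray  # int endpoint-ownership labels at reference frame
    lung_mask: np.ndarray  # bool tissue mask at reference frame
    lumen_mask: np.ndarray  # bool rendered airway lumen
    reference_frame: int
    voxel_spacing_um: float

    @property
    def endpoint_ids(self) -> list[int]:
        return [c.endpoint_id for c in self.compartments]

    def trachea_flow(self) -> np.ndarray:
        """dV_total/dt at interval midpoints (uL/s)."""
        return self.endpoint_flows.sum(axis=0)

    def interval_expansion(self, f: int) -> np.ndarray:
        """Per-endpoint fractional volume change over interval f -> f+1."""
        F = self.scales.shape[1]
        return (self.endpoint_frame_volumes[:, (f + 1) % F]
                / self.endpoint_frame_volumes[:, f]) - 1.0

    def displacement_vox(self, points_vox: np.ndarray, f: int) -> np.ndarray:
        """Analytic displacement (voxels) of tissue points over f -> f+1.

        Points outside every compartment ball move by zero.
        """
        pts = np.atleast_2d(np.asarray(points_vox, dtype=float))
        F = self.scales.shape[1]
        out = np.zeros_like(pts)
        for e, c in enumerate(self.centers_vox):
            r = pts - c
            dist = np.linalg.norm(r, axis=1)
            inside = dist <= self.scales[e, f] * self.radii_vox[e]
            ratio = self.scales[e, (f + 1) % F] / self.scales[e, f]
            out[inside] = (ratio - 1.0) * r[inside]
        return out


def _rasterize_capsule(vol: np.ndarray, p: np.ndarray, q: np.ndarray,
                       radius: float, value: float) -> None:
    """Paint a cylinder with spherical caps from p to q (voxel coords)."""
    lo = np.maximum(np.floor(np.minimum(p, q) - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p, q) + radius + 2).astype(int),
                    np.array(vol.shape))
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    X = np.stack([g.astype(float) for g in grids], axis=-1)
    d = q - p
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.linalg.norm(X - p, axis=-1)
    else:
        t = np.clip(((X - p) @ d) / L2, 0.0, 1.0)
        proj = p + t[..., None] * d
        dist = np.linalg.norm(X - proj, axis=-1)
    sel = dist <= radius
    vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][sel] = value


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def render_volumes(
    tree: AirwayTree,
    compartments: CompartmentSim,
    grid_shape: tuple[int, int, int],
    voxel_spacing_um: float,
    texture_seed: int = 0,
    texture_correlation_vox: float = 3.0,
    linear_margin_vox: float = 3.0,
    falloff_vox: float = 4.0,
) -> tuple[VolumeSeries, PhantomGroundTruth]:
    """Render the 4D image cycle and its analytic ground truth.

    The whole grid carries band-limited speckle (parenchyma-like texture);
    each endpoint's supplied region is the ball of radius R0 around its
    compartment center at the reference frame (peak expiration, the
    minimum-total-volume frame).  Frame ``f`` warps the texture with a
    radial field that is a uniform dilation inside the ball — the local
    volume ratio equals V(t_f)/V(t_ref) exactly — and decays smoothly to
    zero over a shell of ``falloff_vox`` voxels, so tissue is continuous
    across the region boundary and no spurious moving intensity edge is
    created.  The airway lumen is painted as static dark tubes (endpoint
    tubes stop at the ball surface); lumen voxels are excluded from the
    lung mask.

    Raises :class:`ConfigurationError` if a ball (with its motion shell)
    leaves the grid or reaches into a neighboring ball at peak inflation:
    the ground-truth expansion would then be ambiguous.
    """
    if voxel_spacing_um <= 0:
        raise ValueError("voxel spacing must be positive")
    h = float(voxel_spacing_um)
    sim = compartments
    comps = sim.compartments
    E, F = sim.frame_volumes.shape

    ref = int(np.argmin(sim.total_frame_volumes()))
    v_ref = sim.frame_volumes[:, ref]
    # ball radius from reference volume: V[uL] * 1e9 um^3 = 4/3 pi (R_um)^3
    radii_um = np.cbrt(3.0 * v_ref * 1e9 / (4.0 * math.pi))
    radii_vox = radii_um / h
    scales = np.cbrt(sim.frame_volumes / v_ref[:, None])
    centers_vox = np.array([c.center for c in comps]) / h

    shape = tuple(int(s) for s in grid_shape)
    lam_max = scales.max(axis=1)
    r1 = radii_vox * lam_max + linear_margin_vox  # uniform-dilation zone
    r2 = r1 + falloff_vox  # motion vanishes beyond this
    for e in range(E):
        if np.any(centers_vox[e] - r2[e] < 0) or np.any(centers_vox[e] + r2[e] > np.array(shape)):
            raise ConfigurationError(
                f"compartment {comps[e].endpoint_id} motion shell leaves the grid"
            )
    for i in range(E):
        for j in range(i + 1, E):
            gap = np.linalg.norm(centers_vox[i] - centers_vox[j])
            if gap < max(r2[i] + lam_max[j] * radii_vox[j],
                         r2[j] + lam_max[i] * radii_vox[i]):
                raise ConfigurationError(
                    f"compartments {comps[i].endpoint_id} and "
                    f"{comps[j].endpoint_id} overlap at peak inflation"
                )

    # band-limited speckle reference texture
    rng = np.random.default_rng(texture_seed)
    noise = rng.standard_normal(shape)
    sigma = texture_correlation_vox / 2.5  # FWHM-ish ~ correlation length
    tex = ndi.gaussian_filter(noise, sigma)
    tex = TISSUE_MEAN + TISSUE_SD * tex / tex.std()
    tex = np.clip(tex, TISSUE_LO, TISSUE_HI)
    tex_spl = ndi.spline_filter(tex, order=3, output=np.float64)

    frames = np.repeat(tex.astype(np.float32)[None], F, axis=0)
    rad_grid = np.linspace(0.0, 1.05 * r2.max() + 2.0, 2048)
    for e in range(E):
        c = centers_vox[e]
        lo = np.maximum(np.floor(c - r2[e] - 1).astype(int), 0)
        hi = np.minimum(np.ceil(c + r2[e] + 2).astype(int), np.array(shape))
        grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                            indexing="ij")
        X = np.stack([g.astype(float) for g in grids], axis=-1)
        r = X - c
        dist = np.linalg.norm(r, axis=-1)
        sel = dist <= r2[e]
        if not sel.any():
            continue
        for f in range(F):
            lam = scales[e, f]
            if abs(lam - 1.0) < 1e-12:
                continue
            # forward radial map rho = r * m(r), m: lam inside, ->1 in shell
            m = 1.0 + (lam - 1.0) * (1.0 - _smoothstep((rad_grid - r1[e]) / falloff_vox))
            fwd = rad_grid * m
            src_r = np.interp(dist[sel], fwd, rad_grid)  # inverse map
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = np.where(dist[sel] > 0, src_r / dist[sel], 1.0 / lam)
            src = (c + r[sel] * ratio[:, None]).T
            vals = ndi.map_coordinates(tex_spl, src, order=3, prefilter=False,
                                       mode="nearest")
            block = frames[f, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            block[sel] = vals.astype(np.float32)

    # static airway lumen, painted over tissue in every frame; tubes of
    # endpoint segments stop at the ball surface so the supplied region
    # keeps its moving texture
    endpoint_ids = {c.endpoint_id for c in comps}
    ball_r_by_eid = {comps[e].endpoint_id: radii_vox[e] for e in range(E)}
    helper = np.zeros(shape, dtype=np.float32)
    for sid in tree.dfs_segments():
        seg = tree.segments[sid]
        for a, b in zip(seg.nodes[:-1], seg.nodes[1:]):
            p = tree.nodes[a].position / h
            q = tree.nodes[b].position / h
            if sid in endpoint_ids and b == seg.nodes[-1]:
                # trim the distal piece at the ball surface
                d = q - p
                L = float(np.linalg.norm(d))
                trim = ball_r_by_eid[sid]
                if L > trim:
                    q = p + d * (1.0 - trim / L)
                else:
                    continue
            rad = max(0.5 * (tree.nodes[a].radius + tree.nodes[b].radius) / h, 1.0)
            _rasterize_capsule(helper, p, q, rad, 1.0)
    lumen = helper > 0
    frames[:, lumen] = LUMEN_VALUE

    # ownership labels and lung mask at the reference frame
    label = np.full(shape, -1, dtype=np.int32)
    mask = np.zeros(shape, dtype=bool)
    for e in range(E):
        c = centers_vox[e]
        R = radii_vox[e]
        lo = np.maximum(np.floor(c - R - 1).astype(int), 0)
        hi = np.minimum(np.ceil(c + R + 2).astype(int), np.array(shape))
        grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
        X = np.stack([g.astype(float) for g in grids], axis=-1)
        sel = np.linalg.norm(X - c, axis=-1) <= R
        label[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][sel] = comps[e].endpoint_id
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][sel] = True
    mask &= ~lumen
    label[lumen] = -1

    series = VolumeSeries(
        data=frames,
        voxel_spacing_um=h,
        frame_times=sim.protocol.frame_times(),
    )
    truth = PhantomGroundTruth(
        tree=tree,
        compartments=comps,
        centers_vox=centers_vox,
        radii_vox=radii_vox,
        scales=scales,
        frame_volumes=sim.total_frame_volumes(),
        endpoint_frame_volumes=sim.frame_volumes,
        endpoint_flows=sim.midpoint_flows,
        label_volume=label,
        lung_mask=mask,
        lumen_mask=lumen,
        reference_frame=ref,
        voxel_spacing_um=h,
    )
    return series, truth
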