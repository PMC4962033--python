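"""End-to-end orchestration: phantom -> PIV -> expansion -> tree -> ATL -> metrics.

`run_phantom_subject` runs the full imaging pipeline on a rendered phantom
and returns every intermediate product, so tests, the CLI and the cohort
driver share one code path.  `simulate_endpoint_metrics` is the fast
mechanics-only variant (no imaging): it samples the compartment waveforms
directly and pushes them through the same flow/metric code, which is how
large cohorts are produced at realistic endpoint counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import atl, expansion as expn, metrics as met
from .airway_tree import AirwayTree, flood_fill_segment, skeletonize_to_graph
from .cohort import SubjectSummary, distribution_stats, lung_disease_index
from .phantom import (
    BACKGROUND_VALUE,
    TISSUE_LO,
    CompartmentSim,
    DiseaseConfig,
    PhantomGroundTruth,
    VolumeSeries,
    generate_tree,
    render_volumes,
    simulate_compartments,
)
from .piv3d import (DisplacementField, PivConfig, cross_correlate_windows,
                    smooth_displacements, validate_displacements)
from .protocol import VentilationProtocol

__all__ = [
    "PhantomRunConfig",
    "SubjectResult",
    "generate_phantom",
    "run_phantom_subject",
    "simulate_endpoint_metrics",
    "piv_all_pairs",
    "tissue_mask_from_frame",
]

log = logging.getLogger(__name__)

# midpoint between lumen/background and tissue intensities
TISSUE_THRESHOLD = 0.5 * (BACKGROUND_VALUE + TISSUE_LO)
LUMEN_WINDOW = (0.0, 50.0)


@dataclass(frozen=True)
class PhantomRunConfig:
    """Study conditions for one phantom subject."""

    protocol: VentilationProtocol = VentilationProtocol()
    disease: DiseaseConfig = DiseaseConfig()
    n_generations: int = 4
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_spacing_um: float = 20.0
    rest_volume_mean: float = 0.028  # uL -> ~9.5-voxel balls at 20 um
    domain_margin_vox: float = 6.0  # keeps motion shells inside the grid
    piv: PivConfig = PivConfig(window_size=10, window_spacing=4, search_radius=3)
    # sample displacement only this deep inside the lung mask: border
    # windows straddle the region boundary and dilute the measured motion
    piv_mask_erosion_vox: float = 3.0
    # exclusion radius around the static airway lumen (None: half window + 2)
    piv_lumen_halo_vox: float | None = None
    # "affine": one least-squares gradient fit per region (precise when
    # regional expansion is near-uniform); "pointwise": mean of the local
    # Jacobian expansion map
    regional_method: str = "affine"
    seed: int = 0


@dataclass
class SubjectResult:
    """Everything one phantom subject's pipeline run produced."""

    config: PhantomRunConfig
    true_tree: AirwayTree
    sim: CompartmentSim
    series: VolumeSeries
    truth: PhantomGroundTruth
    lung_mask: np.ndarray
    fields: list[DisplacementField]
    expansions: list[expn.ExpansionMap]
    lumen_mask: np.ndarray
    tree: AirwayTree  # measured (skeletonized) tree
    assignment: atl.RegionAssignment
    delta_v: dict[int, np.ndarray]  # per-endpoint interval volume changes
    flows: dict[int, atl.FlowWaveform]  # endpoint flows
    all_flows: dict[int, atl.FlowWaveform]  # every segment incl. trachea
    metrics: pd.DataFrame
    trachea_volume: met.VolumeWaveform
    global_tau: float
    global_tau_censored: bool

    def summary(self, subject_id: str, group: str,
                ldi: float | None = None) -> SubjectSummary:
        tau = self.metrics.loc[~self.metrics["missing"], "tau_exp"]
        st = distribution_stats(tau, t_exp=self.config.protocol.t_exp)
        return SubjectSummary(
            subject_id=subject_id,
            group=group,
            median_tau=st.median,
            sd_tau=st.sd,
            mean_tau=st.mean,
            global_tau=self.global_tau,
            ldi=float("nan") if ldi is None else ldi,
            total_volume=self.assignment.total_volume,
        )


def tissue_mask_from_frame(frame: np.ndarray) -> np.ndarray:
    """Lung tissue mask by intensity threshold on a single frame."""
    return frame > TISSUE_THRESHOLD


def piv_all_pairs(series: VolumeSeries, mask: np.ndarray, config: PivConfig,
                  validate: bool = True, smooth: bool = False) -> list[DisplacementField]:
    """Displacement fields for all n_frames cyclic pairs (f -> f+1, wrapped).

    The final pair correlates the last volume with the first so the whole
    respiratory cycle is covered.
    """
    F = series.n_frames
    fields = []
    for f in range(F):
        g = (f + 1) % F
        d = cross_correlate_windows(series.data[f], series.data[g], mask, config,
                                    frame_pair=(f, g))
        if validate:
            d = validate_displacements(d, config=config.validation)
        if smooth:
            d = smooth_displacements(d)
        fields.append(d)
    return fields


def _masked_grid(field: DisplacementField, mask: np.ndarray,
                 voxel_spacing_um: float):
    """Grid points (um), flat indices and per-cell volume for masked centers."""
    pts_vox = field.grid_points_vox().reshape(-1, 3)
    idx = np.arange(len(pts_vox))
    ivox = pts_vox.astype(int)
    inside = mask[ivox[:, 0], ivox[:, 1], ivox[:, 2]]
    cell_vol_ul = (field.spacing * voxel_spacing_um) ** 3 * 1e-9
    return pts_vox[inside] * voxel_spacing_um, idx[inside], cell_vol_ul


def generate_phantom(config: PhantomRunConfig):
    """Generate and render one phantom subject (tree, sim, series, truth)."""
    h = config.voxel_spacing_um
    m = config.domain_margin_vox * h
    domain = ((m, m, m), tuple(s * h - m for s in config.grid_shape))
    true_tree = generate_tree(config.n_generations, domain=domain, seed=config.seed)
    sim = simulate_compartments(true_tree, config.protocol, config.disease,
                                rest_volume_mean=config.rest_volume_mean)
    series, truth = render_volumes(true_tree, sim, config.grid_shape, h,
                                   texture_seed=config.seed + 1)
    return true_tree, sim, series, truth


def run_phantom_subject(config: PhantomRunConfig) -> SubjectResult:
    """Generate, image and analyse one phantom subject end to end."""
    h = config.voxel_spacing_um
    true_tree, sim, series, truth = generate_phantom(config)

    ref = truth.reference_frame
    lung_mask = truth.lung_mask

    # windows overlapping the static airway lumen would anchor the
    # correlation to zero motion; exclude their centers from measurement
    # (the tissue there stays assigned, it is just not sampled)
    from scipy.ndimage import distance_transform_edt

    halo = (config.piv.window_size // 2 + 2 if config.piv_lumen_halo_vox is None
            else config.piv_lumen_halo_vox)
    piv_mask = lung_mask & (distance_transform_edt(~truth.lumen_mask) >= halo)
    if config.piv_mask_erosion_vox > 0:
        piv_mask &= distance_transform_edt(lung_mask) > config.piv_mask_erosion_vox
    if not piv_mask.any():
        piv_mask = lung_mask

    fields = piv_all_pairs(series, piv_mask, config.piv)
    expansions = [expn.expansion_field(f, voxel_spacing_um=h, overlap_correction=True)
                  for f in fields]

    # airway tree from the reference (peak-expiration) frame
    root_vox = tuple(np.round(true_tree.proximal_node(true_tree.root).position / h).astype(int))
    lumen_mask = flood_fill_segment(series.data[ref], root_vox, LUMEN_WINDOW)
    tree = skeletonize_to_graph(lumen_mask, root_vox, voxel_spacing_um=h)

    points_um, point_index, cell_vol = _masked_grid(fields[0], lung_mask, h)
    assignment = atl.assign_tissue(points_um, tree, cell_vol, point_index)

    # supplied volumes at voxel resolution: grid-cell counts quantize the
    # region volume to a few percent, which scales every flow of that
    # endpoint; counting mask voxels per nearest endpoint is exact to the
    # rasterization
    vox_points = np.argwhere(lung_mask) * h
    vox_assign = atl.assign_tissue(vox_points, tree, h**3 * 1e-9)
    assignment.endpoint_volumes = vox_assign.endpoint_volumes

    # The expansion of interval f is relative to the tissue volume at frame
    # f, so region volumes are propagated multiplicatively around the cycle
    # starting from the reference (minimum-volume) frame; the reference
    # assignment volume is only the frame-0 state.
    delta_v: dict[int, np.ndarray] = {
        eid: np.empty(config.protocol.n_frames) for eid in assignment.endpoint_ids
    }
    current = dict(assignment.endpoint_volumes)
    for i in range(config.protocol.n_frames):
        if config.regional_method == "affine":
            dv, _missing = expn.regional_volume_change_affine(
                fields[i], assignment, current, voxel_spacing_um=h)
        else:
            dv, _missing = expn.regional_volume_change(expansions[i], assignment,
                                                       current)
        for eid, val in dv.items():
            delta_v[eid][i] = val
            if np.isfinite(val) and current[eid] > 0:
                current[eid] += val

    flows = atl.endpoint_flows(assignment, delta_v, config.protocol)
    all_flows = atl.propagate_flows(tree, flows)
    metrics = met.endpoint_metrics_table(flows, assignment, config.protocol)

    trachea_volume = met.volume_waveform(all_flows[tree.root], config.protocol)
    global_tau, censored = met.global_time_constant(trachea_volume, config.protocol)

    return SubjectResult(
        config=config,
        true_tree=true_tree,
        sim=sim,
        series=series,
        truth=truth,
        lung_mask=lung_mask,
        fields=fields,
        expansions=expansions,
        lumen_mask=lumen_mask,
        tree=tree,
        assignment=assignment,
        delta_v=delta_v,
        flows=flows,
        all_flows=all_flows,
        metrics=metrics,
        trachea_volume=trachea_volume,
        global_tau=global_tau,
        global_tau_censored=censored,
    )


def simulate_endpoint_metrics(
    n_endpoints: int,
    disease: DiseaseConfig,
    protocol: VentilationProtocol = VentilationProtocol(),
    seed: int | None = None,
    rest_volume_mean: float = 0.05,
) -> tuple[pd.DataFrame, CompartmentSim]:
    """Mechanics-only subject: endpoint metrics straight from compartment ODEs.

    Builds a large abstract tree (n_endpoints must be a power of two),
    samples the closed-form periodic waveforms at the standard 16-frame
    resolution and runs the identical flow/metric code the imaging
    pipeline uses.  The supplied tissue volume per endpoint is its
    compartment volume at the reference (minimum total volume) frame.
    """
    g = int(np.log2(n_endpoints))
    if 2**g != n_endpoints:
        raise ValueError("n_endpoints must be a power of two")
    if seed is not None:
        disease = DiseaseConfig(**{**disease.__dict__, "seed": seed})
    # large abstract domain: geometry is irrelevant here, only topology
    domain = ((0.0, 0.0, 0.0), (1e6, 1e6, 1e6))
    tree = generate_tree(g, domain=domain, seed=disease.seed)
    sim = simulate_compartments(tree, protocol, disease,
                                rest_volume_mean=rest_volume_mean)

    ref = int(np.argmin(sim.total_frame_volumes()))
    eids = sim.endpoint_ids
    order = np.argsort(eids)
    centers = np.array([c.center for c in sim.compartments])[order]
    v_ref = sim.frame_volumes[order, ref]

    assignment = atl.RegionAssignment(
        endpoint_ids=sorted(eids),
        labels=np.asarray(sorted(eids)),
        points_um=centers,
        point_index=np.arange(len(eids)),
        cell_volume_ul=float("nan"),
        endpoint_volumes={eid: float(v) for eid, v in zip(sorted(eids), v_ref)},
    )
    times = protocol.midpoint_times()
    flows = {
        eid: atl.FlowWaveform(eid, times.copy(), sim.midpoint_flows[i])
        for i, eid in enumerate(eids)
    }
    df = met.endpoint_metrics_table(flows, assignment, protocol)
    # attach the planted mechanics for validation studies
    planted = pd.DataFrame({
        "endpoint_id": eids,
        "planted_tau": sim.taus,
        "diseased": sim.diseased,
        "obstructed": [c.obstructed for c in sim.compartments],
    })
    df = df.merge(planted, on="endpoint_id")
    return df, sim
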