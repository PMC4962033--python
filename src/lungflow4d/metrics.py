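"""Per-segment pulmonary function measures.

Flow waveforms are integrated into volume waveforms (cumulative volume
above the end-expiratory baseline); from these come tidal volume (TV),
peak expiratory flow (PEF), and the expiratory time constant tau_exp — the
time after expiration onset for the expelled volume to reach 1 - 1/e
(~63%) of tidal volume, located by linear interpolation between volume
knots.  The exact 1 - 1/e threshold makes the estimator unbiased for
exponential emptying; the rounded literal 0.63 is available via
``threshold``.  Expiration onset is taken at the volume-waveform maximum
rather than the nominal valve time so that phase-lagged (diseased) regions
are measured from their own peak.  Normalized forms divide PEF by TV
(pef_norm, 1/s) and TV by the supplied tissue volume at end expiration
(tv_norm, dimensionless).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atl import FlowWaveform, RegionAssignment
from .protocol import VentilationProtocol

__all__ = [
    "VolumeWaveform",
    "EndpointMetrics",
    "volume_waveform",
    "tidal_volume",
    "peak_expiratory_flow",
    "expiratory_time_constant",
    "global_time_constant",
    "endpoint_metrics_table",
    "EXP_THRESHOLD",
]

EXP_THRESHOLD = 1.0 - 1.0 / math.e  # expelled fraction defining tau_exp


@dataclass
class VolumeWaveform:
    """Cumulative volume above end-expiratory baseline at knot times.

    ``volume[0]`` is 0 by construction after baseline shift; for periodic
    breathing ``volume[-1]`` returns to ~0 (cycle closure).
    """

    segment_id: int
    times: np.ndarray  # (n_frames + 1,) s
    volume: np.ndarray  # (n_frames + 1,) uL
    missing: bool = False


def volume_waveform(flow: FlowWaveform, protocol: VentilationProtocol) -> VolumeWaveform:
    """Integrate a midpoint-sampled flow waveform into volume knots.

    Rectangle integration of the n_frames midpoint flows over dt gives the
    volume at the n_frames + 1 knot times; the baseline is shifted so the
    minimum is zero.
    """
    if len(flow.flow) != protocol.n_frames:
        raise ValueError("flow waveform length must equal n_frames")
    v = np.concatenate([[0.0], np.cumsum(flow.flow) * protocol.dt])
    v -= v.min()
    return VolumeWaveform(
        segment_id=flow.segment_id,
        times=protocol.knot_times(),
        volume=v,
        missing=flow.missing,
    )


def tidal_volume(vol: VolumeWaveform) -> float:
    """max(V) - min(V) in uL; zero for a non-ventilated segment."""
    return float(vol.volume.max() - vol.volume.min())


def peak_expiratory_flow(flow: FlowWaveform, protocol: VentilationProtocol) -> tuple[float, bool]:
    """Largest expiratory (negative) flow magnitude in (t_insp, period].

    Returns ``(pef, flagged)``: pef is positive; when no expiratory flow
    occurs in the window (an obstructed region) pef is 0 and the flag set.
    """
    window = (flow.times > protocol.t_insp) & (flow.times <= protocol.period)
    f = flow.flow[window]
    neg = f[f < 0]
    if neg.size == 0:
        return 0.0, True
    return float(-neg.min()), False


def expiratory_time_constant(
    vol: VolumeWaveform,
    protocol: VentilationProtocol,
    threshold: float = EXP_THRESHOLD,
) -> tuple[float, bool]:
    """Time after expiration onset to expel ``threshold`` of tidal volume.

    Expiration onset is the volume-waveform maximum.  The crossing of the
    expelled-volume threshold is located by linear interpolation between
    knots.  If the threshold is never reached within the cycle the value
    is censored at t_exp and flagged.

    Returns ``(tau_exp, censored)``.
    """
    v = vol.volume
    tv = float(v.max() - v.min())
    if tv <= 0:
        return protocol.t_exp, True
    onset = int(np.argmax(v))
    target = v[onset] - threshold * tv
    t_onset = vol.times[onset]
    for k in range(onset, len(v) - 1):
        if v[k] > target >= v[k + 1]:
            frac = (v[k] - target) / (v[k] - v[k + 1])
            t_cross = vol.times[k] + frac * (vol.times[k + 1] - vol.times[k])
            return float(min(t_cross - t_onset, protocol.t_exp)), False
    return protocol.t_exp, True


def global_time_constant(
    trachea_vol: VolumeWaveform,
    protocol: VentilationProtocol,
    threshold: float = EXP_THRESHOLD,
) -> tuple[float, bool]:
    """tau_exp of the whole lung: the estimator applied to the trachea."""
    return expiratory_time_constant(trachea_vol, protocol, threshold)


@dataclass
class EndpointMetrics:
    """Function measures of one endpoint's supplied region."""

    endpoint_id: int
    tv: float  # uL
    pef: float  # uL/s
    tau_exp: float  # s
    v_ee: float  # uL supplied tissue volume at end expiration
    pef_norm: float  # 1/s
    tv_norm: float  # dimensionless
    missing: bool = False
    non_ventilated: bool = False
    tau_censored: bool = False


def endpoint_metrics_table(
    flows: dict[int, FlowWaveform],
    assignment: RegionAssignment,
    protocol: VentilationProtocol,
    threshold: float = EXP_THRESHOLD,
) -> pd.DataFrame:
    """One row of function measures per endpoint.

    Missing waveforms produce rows of NaNs with the ``missing`` flag;
    zero-TV endpoints are flagged ``non_ventilated`` and get NaN
    normalized values (their supplied volume still counts in totals).
    """
    rows = []
    for eid in assignment.endpoint_ids:
        wf = flows[eid]
        v_ee = assignment.endpoint_volumes.get(eid, float("nan"))
        if wf.missing:
            rows.append(EndpointMetrics(eid, float("nan"), float("nan"),
                                        float("nan"), v_ee, float("nan"),
                                        float("nan"), missing=True))
            continue
        vol = volume_waveform(wf, protocol)
        tv = tidal_volume(vol)
        pef, pef_flag = peak_expiratory_flow(wf, protocol)
        tau, censored = expiratory_time_constant(vol, protocol, threshold)
        if tv > 0 and v_ee > 0:
            pef_norm = pef / tv
            tv_norm = tv / v_ee
            nonvent = False
        else:
            pef_norm = float("nan")
            tv_norm = float("nan")
            nonvent = True
        rows.append(EndpointMetrics(eid, tv, pef, tau, v_ee, pef_norm, tv_norm,
                                    missing=False, non_ventilated=nonvent or pef_flag,
                                    tau_censored=censored))
    return pd.DataFrame([r.__dict__ for r in rows])
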