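"""Pressure-controlled ventilation protocol.

The ventilator drives the lung with a square pressure wave between PEEP and
PIP.  The default settings describe small-animal pressure-controlled
ventilation at 12/2 cmH2O and 133 breaths per minute: a 0.45 s cycle with
0.15 s inspiration and 0.30 s expiration, imaged at 16 frames per cycle.
Frame 0 is taken at the start of inspiration, i.e. at end expiration, which
is also the reference frame for segmentation and tissue assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VentilationProtocol"]


@dataclass(frozen=True)
class VentilationProtocol:
    """Square-wave pressure-controlled ventilation settings.

    Parameters
    ----------
    pip : float
        Peak inspiratory pressure (cmH2O).
    peep : float
        Positive end-expiratory pressure (cmH2O).
    period : float
        Duration of one respiratory cycle (s).
    t_insp : float
        Inspiration time (s); expiration occupies the remainder.
    n_frames : int
        Number of reconstructed volumes per cycle (>= 4).
    """

    pip: float = 12.0
    peep: float = 2.0
    period: float = 0.45
    t_insp: float = 0.15
    n_frames: int = 16

    def __post_init__(self) -> None:
        if not self.pip > self.peep:
            raise ValueError(f"PIP ({self.pip}) must exceed PEEP ({self.peep})")
        if not 0.0 < self.t_insp < self.period:
            raise ValueError("t_insp must lie strictly inside the cycle period")
        if self.n_frames < 4:
            raise ValueError("need at least 4 frames per cycle")

    @property
    def t_exp(self) -> float:
        """Expiration time (s); t_insp + t_exp = period."""
        return self.period - self.t_insp

    @property
    def delta_p(self) -> float:
        """Driving pressure PIP - PEEP (cmH2O)."""
        return self.pip - self.peep

    @property
    def dt(self) -> float:
        """Frame interval period / n_frames (s)."""
        return self.period / self.n_frames

    def frame_times(self) -> np.ndarray:
        """Times of the n_frames reconstructed volumes, starting at 0."""
        return np.arange(self.n_frames) * self.dt

    def midpoint_times(self) -> np.ndarray:
        """Midpoints of the n_frames frame intervals (flow timestamps)."""
        return (np.arange(self.n_frames) + 0.5) * self.dt

    def knot_times(self) -> np.ndarray:
        """n_frames + 1 knot times for integrated volume waveforms."""
        return np.arange(self.n_frames + 1) * self.dt

    def airway_pressure(self, t) -> np.ndarray:
        """Square-wave airway pressure at time(s) ``t`` (cmH2O)."""
        tc = np.asarray(t, dtype=float) % self.period
        return np.where(tc < self.t_insp, self.pip, self.peep)
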