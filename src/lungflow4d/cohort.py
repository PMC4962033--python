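"""Cohort-level analyses of regional lung function.

A polynomial reference model of normalized peak expiratory flow
(pef_norm = PEF/TV) as a function of normalized tidal volume
(tv_norm = TV/V_ee) is fitted to the pooled endpoints of the healthy
group.  The 99% band is interpreted as a pointwise *prediction* interval
for new endpoint observations (a mean-response interval would classify
nearly half of healthy endpoints as abnormal at large n); its lower limit
is the disease threshold.  The Lung Disease Index (LDI) is the percentage
of total supplied lung volume whose endpoints fall below that bound —
non-ventilated endpoints count as below (a fully blocked region is
maximally dysfunctional).

Phenotype structure is summarized per subject by the median and standard
deviation of the endpoint tau_exp distribution; subjects are clustered by
k-means (default k = 4) in that plane, and each subject's angle from the
cohort-mean point P is reported.  Group comparisons use unpaired
two-tailed t-tests (pooled variance by default, Welch optional) at the
0.05 significance level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "CohortModel",
    "SubjectSummary",
    "ClusterResult",
    "TauStats",
    "fit_reference",
    "lung_disease_index",
    "distribution_stats",
    "cluster_phenotypes",
    "compare_groups",
]

# absolute slack when classifying a point as below the bound, so that a
# noiseless fit does not flag machine-epsilon deviations
_BELOW_ATOL = 1e-8


@dataclass
class CohortModel:
    """Healthy-reference polynomial with a pointwise prediction band.

    ``coefficients`` are in numpy.polyval order (highest degree first).
    ``lower_bound`` evaluates fit - t_{alpha/2} * s * sqrt(1 + x0' (X'X)^-1 x0),
    the lower limit of the two-sided prediction interval at ``level``.
    tv_norm is clipped to the fitted support before evaluation:
    extrapolating the polynomial outside the healthy range is meaningless
    and can invert the classification.
    """

    degree: int
    coefficients: np.ndarray
    residual_scale: float
    level: float
    xtx_inv: np.ndarray
    df_resid: int
    n_healthy: int
    support: tuple[float, float]
    clip_to_support: bool = True

    def _design(self, x: np.ndarray) -> np.ndarray:
        return np.vander(np.asarray(x, dtype=float), self.degree + 1)

    def predict(self, tv_norm) -> np.ndarray:
        x = np.atleast_1d(np.asarray(tv_norm, dtype=float))
        if self.clip_to_support:
            x = np.clip(x, *self.support)
        return self._design(x) @ self.coefficients

    def lower_bound(self, tv_norm) -> np.ndarray:
        x = np.atleast_1d(np.asarray(tv_norm, dtype=float))
        if self.clip_to_support:
            x = np.clip(x, *self.support)
        X = self._design(x)
        fit = X @ self.coefficients
        leverage = np.einsum("ij,jk,ik->i", X, self.xtx_inv, X)
        se = self.residual_scale * np.sqrt(1.0 + leverage)
        tq = stats.t.ppf(1.0 - (1.0 - self.level) / 2.0, self.df_resid)
        return fit - tq * se

    def to_text(self, path) -> None:
        """Serialize as a structured text file."""
        with open(path, "w") as fh:
            fh.write(f"degree: {self.degree}\n")
            fh.write("coefficients: " + " ".join(repr(float(c)) for c in self.coefficients) + "\n")
            fh.write(f"residual_scale: {float(self.residual_scale)!r}\n")
            fh.write(f"level: {float(self.level)!r}\n")
            fh.write(f"df_resid: {self.df_resid}\n")
            fh.write(f"n_healthy: {self.n_healthy}\n")
            fh.write(f"support: {float(self.support[0])!r} {float(self.support[1])!r}\n")
            fh.write("xtx_inv: " + " ".join(repr(float(v)) for v in self.xtx_inv.ravel()) + "\n")

    @classmethod
    def from_text(cls, path) -> "CohortModel":
        vals: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                key, _, rest = line.partition(":")
                vals[key.strip()] = rest.strip()
        degree = int(vals["degree"])
        k = degree + 1
        return cls(
            degree=degree,
            coefficients=np.array([float(v) for v in vals["coefficients"].split()]),
            residual_scale=float(vals["residual_scale"]),
            level=float(vals["level"]),
            xtx_inv=np.array([float(v) for v in vals["xtx_inv"].split()]).reshape(k, k),
            df_resid=int(vals["df_resid"]),
            n_healthy=int(vals["n_healthy"]),
            support=tuple(float(v) for v in vals["support"].split()),  # type: ignore[arg-type]
        )


def fit_reference(
    healthy_metrics: pd.DataFrame,
    degree: int = 2,
    level: float = 0.99,
) -> CohortModel:
    """Least-squares polynomial of pef_norm on tv_norm over healthy endpoints.

    Rows with non-finite normalized metrics are dropped.  Requires at
    least ``degree + 2`` usable endpoints and a non-degenerate design
    (tv_norm must vary).
    """
    x = np.asarray(healthy_metrics["tv_norm"], dtype=float)
    y = np.asarray(healthy_metrics["pef_norm"], dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < degree + 2:
        raise ValueError(f"need at least {degree + 2} healthy endpoints, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all tv_norm values are equal")
    X = np.vander(x, degree + 1)
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < degree + 1:
        raise ValueError("degenerate design: polynomial basis is rank deficient")
    resid = y - X @ coef
    df = len(x) - (degree + 1)
    s = float(np.sqrt(resid @ resid / df))
    return CohortModel(
        degree=degree,
        coefficients=coef,
        residual_scale=s,
        level=level,
        xtx_inv=np.linalg.inv(X.T @ X),
        df_resid=df,
        n_healthy=len(x),
        support=(float(x.min()), float(x.max())),
    )


def lung_disease_index(metrics: pd.DataFrame, model: CohortModel) -> float:
    """LDI (%): supplied volume functioning below the healthy 99% bound.

    Volume-weighted: 100 * sum(V_ee below bound) / sum(V_ee over all
    endpoints).  Endpoints flagged missing or non-ventilated count as
    below the bound.  Raises if the total supplied volume is zero.
    """
    v_ee = np.asarray(metrics["v_ee"], dtype=float)
    total = np.nansum(v_ee)
    if not total > 0:
        raise ValueError("total supplied volume is zero; LDI undefined")
    flagged = np.zeros(len(metrics), dtype=bool)
    for col in ("missing", "non_ventilated"):
        if col in metrics:
            flagged |= np.asarray(metrics[col], dtype=bool)
    pef_norm = np.asarray(metrics["pef_norm"], dtype=float)
    tv_norm = np.asarray(metrics["tv_norm"], dtype=float)
    usable = np.isfinite(pef_norm) & np.isfinite(tv_norm) & ~flagged
    below = flagged.copy()
    if usable.any():
        bound = model.lower_bound(tv_norm[usable])
        below[usable] = pef_norm[usable] < bound - _BELOW_ATOL
    return float(100.0 * np.nansum(v_ee[below]) / total)


@dataclass
class TauStats:
    """Summary of an endpoint tau_exp distribution."""

    median: float
    sd: float
    mean: float
    bin_edges: np.ndarray
    counts: np.ndarray

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "count": self.counts,
        })


def distribution_stats(
    tau_values,
    bin_width: float = 0.02,
    t_exp: float = 0.30,
) -> TauStats:
    """Median, sample SD (n-1), mean and histogram of tau values.

    Bins are fixed on (0, t_exp] with the given width so histograms are
    comparable (and averageable) across subjects.  Requires >= 2 finite
    values.
    """
    tau = np.asarray(tau_values, dtype=float)
    tau = tau[np.isfinite(tau)]
    if len(tau) < 2:
        raise ValueError("need at least 2 finite tau values")
    n_bins = int(math.ceil(t_exp / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(tau, bins=edges)
    return TauStats(
        median=float(np.median(tau)),
        sd=float(np.std(tau, ddof=1)),
        mean=float(np.mean(tau)),
        bin_edges=edges,
        counts=counts,
    )


@dataclass
class SubjectSummary:
    """Per-subject aggregate of the regional analysis."""

    subject_id: str
    group: str  # "healthy" / "diseased"
    median_tau: float  # s
    sd_tau: float  # s
    mean_tau: float  # s
    global_tau: float  # s
    ldi: float  # %
    total_volume: float  # uL
    specific_airway_resistance: float | None = None  # external FOT, optional


@dataclass
class ClusterResult:
    """k-means phenotype clustering in the (median tau, sd tau) plane."""

    point_p: tuple[float, float]  # (mean of medians, mean of sds), s
    angles: np.ndarray  # (n,) radians in (-pi, pi] from P
    k: int
    labels: np.ndarray  # (n,) in 0..k-1
    centers: np.ndarray  # (k, 2)
    inertia: float
    seed: int


def cluster_phenotypes(
    summaries: list[SubjectSummary],
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 20,
) -> ClusterResult:
    """Cluster subjects by their tau distribution statistics.

    Point P is the cohort mean of (median tau, sd tau); each subject's
    angle from P is the four-quadrant arctangent.  Lloyd k-means with
    k-means++ seeding and ``n_restarts`` restarts (best inertia kept) runs
    on the raw (s, s) axes without standardization.
    """
    if k > len(summaries):
        raise ValueError(f"k = {k} exceeds the number of subjects ({len(summaries)})")
    pts = np.array([[s.median_tau, s.sd_tau] for s in summaries])
    p = pts.mean(axis=0)
    angles = np.arctan2(pts[:, 1] - p[1], pts[:, 0] - p[0])
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd").fit(pts)
    return ClusterResult(
        point_p=(float(p[0]), float(p[1])),
        angles=angles,
        k=k,
        labels=km.labels_.copy(),
        centers=km.cluster_centers_.copy(),
        inertia=float(km.inertia_),
        seed=seed,
    )


def compare_groups(
    values_a,
    values_b,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Unpaired two-tailed t-test; returns (t, df, p).

    Pooled variance by default (Welch optional).  Two groups with zero
    variance and equal means give t = 0, p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        df = len(a) + len(b) - 2
        if np.mean(a) == np.mean(b):
            return 0.0, float(df), 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    return float(res.statistic), df, float(res.pvalue)
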