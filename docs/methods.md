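# Methods

This note records the models, estimators, numerical choices and known
limitations behind `lungflow4d`, in the order the pipeline runs.

## Ventilation protocol and compartment mechanics

The driving pressure is an ideal square wave between PEEP and PIP
(defaults 2 and 12 cmH₂O; cycle 0.45 s with 0.15 s inspiration, i.e.
133 breaths/min, 16 frames per cycle). Pressure-controlled ventilation
does not fix the waveform shape; the square wave is the simplest shape
with the stated plateau pressures and gives closed-form mechanics.

Each airway endpoint feeds a single-compartment region obeying

    dV/dt = (P_aw(t) − (V − V_rest)/C) / R,

with V_rest the static volume at PEEP, compliance C, resistance R, and
time constant τ = RC. Under a square wave the periodic steady state is a
pair of matched exponentials with a closed form; the generator uses that
closed form directly (no warm-up integration), and the tests verify it
against a fine-step explicit integrator run to periodic convergence.
Frame 0 is the cycle start (end expiration), which is also the reference
frame for segmentation and tissue assignment (the minimum-volume frame).

Per-endpoint parameters (defaults, chosen once as realistic regional
variability for a ventilated mouse-scale lung):

| parameter | default | meaning |
| --- | --- | --- |
| rest volume | 0.028 µL mean, CV 0.10 | region size at phantom scale (≈9.5-voxel balls at 20 µm) |
| specific compliance | 0.03 cmH₂O⁻¹, CV 0.12 | C = c·V_rest; tidal excursion ≈20% of V_rest |
| healthy τ | N(0.12 s, 0.022 s) | homogeneous healthy population |
| diseased τ | N(0.22 s, 0.037 s) | slow mode of the bimodal diseased population |
| bimodal preset | modes 0.13/0.22 s, 50% volume | patchy muco-obstructive phenotype |

Disease is planted per endpoint: a random subset supplying the configured
fraction of total rest volume draws τ from the diseased distribution, and
a configurable fraction of endpoints (taken from the diseased pool first)
is fully obstructed — zero flow, volume frozen at rest. The parameter
heterogeneity (rest volume, specific compliance) matters beyond realism:
without a second source of variation every endpoint would lie on a
one-dimensional curve in the (tv_norm, pef_norm) plane and the healthy
prediction band would degenerate to zero width.

## Phantom rendering

Band-limited speckle (Gaussian random field, correlation length 3 voxels,
clipped to a 100–200 intensity band) fills the whole grid, emulating
parenchymal texture statistically. Each endpoint's supplied region is the
ball of radius R₀ around its distal node at the reference frame; frame f
warps the texture with a radial map that is a *uniform dilation* inside
the ball — so the local volume ratio equals V(t_f)/V(t_ref) exactly and
the analytic displacement/expansion ground truth is trivial — and decays
smoothly (smoothstep over 4 voxels, after a 3-voxel uniform margin) to
zero, keeping the tissue continuous with no spurious moving edge. The
radial map is inverted numerically on a fine radius grid for backward
resampling (cubic spline). The airway lumen is painted as static dark
tubes; endpoint tubes stop at the ball surface. Configuration errors are
raised if a motion shell leaves the grid or reaches a neighboring ball at
peak inflation, because ground truth would then be ambiguous.

Ball regions are a deliberate idealization: real supplied-tissue
territories are irregular and contiguous. Consequences: passing tests
demonstrate correct measurement of locally uniform regional expansion
with known topology; they do not probe irregular region boundaries,
sliding interfaces, image noise, or reconstruction artifacts.

The airway tree itself is a deterministic dyadic construction: lateral
offsets halve at each successive split along an axis (axes alternate),
descent per generation is offset/tan(branch angle), so 2ⁿ endpoints land
on a regular, well-separated grid. Optional seeded jitter perturbs
positions.

## 3D velocimetry

Displacement per cubic interrogation window is the peak of the
zero-normalized cross-correlation, computed as a zero-padded linear
correlation via FFT and divided by the per-lag overlap count
(w − |d|)³. The overlap normalization matters: the raw circular
correlation is damped by a triangular factor that sharpens the peak
symmetrically and shrinks the subpixel estimate by tens of percent.
Subpixel refinement is a separable three-point Gaussian fit (exact for
Gaussian-shaped peaks), with a parabolic fallback when a sample is
non-positive. Outliers are detected by the normalized-median test
(threshold 2.0, noise floor 0.1 voxel) over the 26-neighborhood and
replaced by the neighbor median. The defaults are 64³ windows at
16-voxel spacing; for the phantom the windows are scaled to the
compartment size (10³ at 4-voxel spacing) so a window sees locally
uniform motion, preserving the features-per-window count. Window centers
are masked to the lung, eroded 3 voxels from the region border, and kept
a half-window clear of the static lumen (which would otherwise anchor
the correlation to zero motion).

A known second-order bias of fixed-window correlation under deformation:
material with the largest displacement leaves the window pair's common
support, so the measured gradient is G − G²/2. The expansion stage can
invert this (G ← G + G²/2); the pipeline enables the correction, while
the bare `expansion_field` operation leaves it off so the pure Jacobian
definition holds exactly on analytic fields.

## Expansion and regional volume change

Pointwise expansion is det(I + ∇u) − 1 with central differences on the
window grid (one-sided at mask borders), positive for inflation; the
small-strain divergence is a config option. The exact determinant is the
default because it is exact for the phantom's warps and unbiased at
finite strain.

Regional ΔV per frame interval uses, by default, one least-squares affine
fit of the displacement field over each region's valid vectors
(u = Gx + b; ΔV = (det(I+G) − 1)·V). The pointwise alternative (mean
expansion × region volume) is retained as an option, but its regional
mean telescopes to a boundary difference and is noise-limited at tens of
windows per region. Two further accounting choices matter at tidal
amplitudes: (1) the expansion of interval f is relative to the region
volume *at frame f*, so region volumes are propagated multiplicatively
around the cycle from the reference frame (using the fixed reference
volume would bias mid-cycle flows low by the inflation ratio, ~15%);
(2) supplied region volumes are tallied at voxel resolution (nearest
endpoint per mask voxel), not window-grid resolution, to avoid a few
percent of quantization that would scale every flow of an endpoint.

## Airway tree and flow linking

The lumen is segmented by 26-connected intensity flood fill from a
tracheal seed (a vesselness pre-filter hook is left out; the phantom's
lumen contrast is controlled), skeletonized by 3D thinning, converted to
a voxel graph (26-connectivity, cycles broken by a minimum spanning
tree), rooted at the skeleton point nearest the seed, compressed into
branch segments, and pruned of leaf spurs shorter than twice the local
radius (distance-transform value). An endpoint is a segment with a
parent and no daughters; a single-segment tree is degenerate (no
endpoints). Endpoint granularity is resolution-dependent: what counts as
"most distal" depends on what the segmentation can resolve.

Tissue assignment is nearest-endpoint by Euclidean distance to the
endpoint's distal node, ties to the smaller endpoint id — simple,
deterministic, and verifiable by brute force; geodesic-within-lung
distance would be a refinement for real anatomy. Flows are ΔV/Δt at
interval midpoints (gas compressibility neglected, so air flow equals
tissue volume change), and internal segments get the post-order sum of
their daughters, making continuity exact at every bifurcation by
construction; the trachea waveform is the sum over all endpoints.

## Function metrics

Volume waveforms are rectangle integrals of the midpoint flows, shifted
so the minimum is zero; TV = max − min; PEF is the largest expiratory
(negative) flow magnitude in (t_insp, period], with the full expiration
window used. τ_exp is the time after expiration onset for the expelled
volume to reach 1 − 1/e of TV, located by linear interpolation between
knots. Choices: the threshold is the exact 1 − 1/e (≈63.21%) rather than
a literal 0.63, so the estimator is unbiased for exponential emptying
(0.63 is available via an argument); expiration onset is the waveform
maximum, not the valve time, to tolerate phase lag in diseased regions;
regions that never reach the threshold are censored at t_exp and
flagged.

A structural property worth knowing: because TV is the *within-cycle*
excursion, τ_exp saturates — with a 0.30 s expiration the estimator
cannot exceed ≈0.19 s, and a planted RC of 0.22 s reads ≈0.15 s. Rank
order is preserved (monotone mapping), so population statements about
slow regions survive, but absolute τ_exp of severely obstructed regions
is compressed. Population-distribution checks therefore run on the
planted τ draws, with the measured values compared against the
closed-form mapping.

## Cohort analyses

The healthy reference is a least-squares polynomial (default degree 2) of
pef_norm on tv_norm over all healthy endpoints. The 99% band is a
*pointwise prediction interval* for a new endpoint,
fit ± t₀.₉₉₅,df·s·√(1 + x₀ᵀ(XᵀX)⁻¹x₀): it classifies individual
endpoints, and a mean-response interval would flag nearly half of
healthy endpoints at large n. Evaluation clips tv_norm to the fitted
support — extrapolating a polynomial outside the healthy range is
meaningless and can invert the classification. LDI is volume-weighted:
100 × Σ V_ee(below bound) / Σ V_ee, with non-ventilated or missing
endpoints counted as below (a fully blocked region is maximally
dysfunctional). A 10⁻⁸ absolute slack avoids classifying machine-noise
deviations when the fit is exact. LDI detects endpoints *below* the
healthy band; disease expressed only as elevated τ with preserved PEF is
invisible to it until flow degrades, which is why "severe" disease in
the recovery studies means τ comparable to or exceeding the expiration
window (τ ≈ 0.35 s).

Subjects are summarized by the median and SD (n−1) of their endpoint
τ_exp distribution plus fixed-bin histograms on (0, t_exp] (width
0.02 s) so histograms average across subjects. Phenotype clustering is
Lloyd k-means (k-means++ seeding, 20 restarts, fixed seed, default
k = 4) on the raw (median, SD) plane in seconds — unstandardized, since
both axes share units; the per-subject angle is the four-quadrant
arctangent from the cohort-mean point P. Group comparisons are unpaired
two-tailed t-tests (pooled variance; Welch optional) at p < 0.05, with
no multiple-comparison correction applied.

## Problem sizes and determinism

The shipped study conditions: imaging runs use a 16-endpoint
(4-generation) tree in a 128³ grid at 20 µm voxels, 16 frames — one
subject renders and analyses in a few seconds; cohort analyses use
mechanics-level subjects with 256 endpoints (the imaging and mechanics
paths share the flow/metric code, so the cohort logic is exercised
identically). A single integer seed controls the tree, the mechanical
draws and the texture; reruns of the same configuration are bit-identical
(HDF5 written without timestamps; outputs stamped with the config hash
and seed).

## Known limitations

- Ball-shaped, disjoint supplied regions with locally uniform expansion;
  no irregular territories, no inter-region sliding.
- Noise-free images: no detector noise, reconstruction artifacts, or
  intensity drift; accuracy numbers are upper bounds in that respect.
- Single-pass correlation (no window deformation); displacement per
  interval must stay well under half a window.
- Nearest-endpoint (Euclidean) tissue assignment rather than
  supplied-territory or geodesic models.
- τ_exp saturation near the expiration duration, as described above.
- Obstructed regions are idealized as exactly zero flow rather than
  slow-leak compartments.
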