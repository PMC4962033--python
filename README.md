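# lungflow4d

Image-based **regional** pulmonary function testing. Clinical lung function
tests (spirometry, forced oscillation) return one number for the whole
lung, which hides patchy disease such as the muco-obstructive airway
disease of cystic fibrosis. `lungflow4d` instead measures lung function
*region by region* from 4D volumetric images of a breathing lung:

1. **4D velocimetry** — tissue displacement between successive 3D volumes
   is measured by windowed 3D cross-correlation (zero-normalized, spectral,
   three-point Gaussian subpixel fit, normalized-median outlier validation).
2. **Regional ventilation** — the local fractional volume change over a
   frame interval is det(I + ∇u) − 1, the exact Jacobian of the measured
   displacement field u.
3. **Airway tree linking** — the airway lumen is flood-filled from a
   tracheal seed, skeletonized into a rooted tree, and every piece of lung
   tissue is assigned to its nearest *endpoint* (the most distal segmented
   airway). Endpoint airflow is Q = ΔV/Δt; by continuity
   (negligible gas compressibility) the flow in any parent branch is the
   sum of its daughters', so flows propagate recursively up to the trachea.
4. **Function metrics** — per endpoint: tidal volume TV, peak expiratory
   flow PEF, and the expiratory time constant τ_exp, the time after
   expiration onset for the region to expel 1 − 1/e (≈63%) of its tidal
   volume. For a single-compartment region with resistance R and
   compliance C, τ_exp ≈ RC, so τ_exp rises with airway obstruction or
   loss of recoil.
5. **Cohort analysis** — a polynomial reference of PEF/TV against TV/V_ee
   over a healthy cohort with a pointwise 99% prediction band; the **Lung
   Disease Index (LDI)** is the percentage of total lung volume supplied
   by endpoints falling below the band's lower limit. Per-subject τ_exp
   distributions (median, SD, averaged histograms) feed k-means phenotype
   clustering in the (median τ, SD τ) plane with angles measured from the
   cohort-mean point P.

Because no deposited 4D lung data exist, the package ships a first-class
**synthetic phantom**: an airway tree whose endpoints drive
speckle-textured tissue regions by the single-compartment equation
dV/dt = (P_aw − (V − V_rest)/C)/R under square-wave pressure-controlled
ventilation (12/2 cmH₂O, 0.45 s cycle, 0.15 s inspiration, 16
frames/cycle). The rendered 4D images come with exact displacement,
expansion and flow ground truth, so every stage of the chain is testable
end to end.

## Worked example

```python
import pandas as pd
from lungflow4d import DiseaseConfig, fit_reference, lung_disease_index
from lungflow4d.pipeline import (PhantomRunConfig, run_phantom_subject,
                                 simulate_endpoint_metrics)

# image and analyse one healthy phantom subject (16 endpoints, 128^3)
res = run_phantom_subject(PhantomRunConfig(disease=DiseaseConfig.healthy(seed=1),
                                           seed=1))
print(f"endpoints recovered : {len(res.tree.endpoint_ids)}")
print(f"global tau_exp      : {res.global_tau:.3f} s")
print(res.metrics[["endpoint_id", "tv", "pef", "tau_exp", "pef_norm", "tv_norm"]]
      .head(4).round(4).to_string(index=False))

# healthy reference cohort and a severely diseased subject (mechanics level)
healthy = [simulate_endpoint_metrics(256, DiseaseConfig.healthy(seed=100 + s))[0]
           for s in range(6)]
model = fit_reference(pd.concat(healthy, ignore_index=True))
diseased, _ = simulate_endpoint_metrics(
    256, DiseaseConfig(diseased_volume_fraction=0.4,
                       diseased_tau_mean=0.35, diseased_tau_sd=0.02, seed=7))
print(f"LDI healthy subject : {lung_disease_index(healthy[0], model):.1f} %")
print(f"LDI diseased subject: {lung_disease_index(diseased, model):.1f} %")
```

prints

```
endpoints recovered : 16
global tau_exp      : 0.113 s
 endpoint_id     tv    pef  tau_exp  pef_norm  tv_norm
           4 0.0048 0.0328   0.1246    6.8206   0.1633
           5 0.0047 0.0312   0.1282    6.6462   0.1516
           7 0.0048 0.0331   0.1218    6.9407   0.1631
           8 0.0052 0.0402   0.1060    7.7429   0.2104
LDI healthy subject : 0.0 %
LDI diseased subject: 41.0 %
```

All 16 airway endpoints are recovered from the rendered images; the
global expiratory time constant (0.113 s) sits at the healthy value
implied by the planted RC population (mean 0.12 s; the within-cycle 63%
threshold reads a few ms low at 16-frame sampling). TV and PEF are in µL
and µL/s at phantom scale; pef_norm = PEF/TV (s⁻¹) and tv_norm = TV/V_ee
are the normalized coordinates of the cohort scatterplot. A subject whose
severely obstructed endpoints supply 40% of its lung volume is scored
LDI = 41%, while healthy subjects score ≈0%.

## Command line

```
lungflow4d run --config config.yaml      # full pipeline, all outputs
lungflow4d phantom / piv / segment / atl / cohort   # resumable stages
```

Volumes are NRRD plus a JSON manifest, trees are SWC, fields are HDF5,
tables are CSV; every output carries the config hash and seed, and reruns
are bit-identical.

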