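# flowres — resolution sensitivity of 4D-flow-MRI-derived hemodynamics

4D-flow MRI measures time-resolved, three-directional blood velocity per
voxel, and clinical pipelines derive geometry, inlet boundary conditions,
velocity metrics and wall shear stress (WSS) from it — all of which degrade
as the scan's spatial resolution coarsens.  `flowres` is a desk-scale
analysis of that degradation for researchers who combine 4D-flow MRI with
patient-specific CFD: it replaces the patient and the flow solver with an
analytic ground truth whose hemodynamics are known in closed form, pushes
that truth through a virtual scanner at the isotropic voxel sizes of a
four-scan protocol (4, 3, 2 and 1.5 mm), and measures exactly how much of
each quantity survives.

## The model

The ground truth is pulsatile laminar flow in a rigid straight tube of
radius R (default 12.575 mm, a mid-ascending-aortic calibre), driven by a
periodic volumetric waveform Q(t) with a sharp systolic peak.  The waveform
is decomposed into K = 8 complex harmonics Q_k; each harmonic contributes
the flow-driven Womersley profile

    u_k(r, t) = Re{ (Q_k / πR²) · [1 − J₀(i^{3/2} α_k r/R) / J₀(i^{3/2} α_k)]
                   / [1 − 2 J₁(i^{3/2} α_k) / (i^{3/2} α_k J₀(i^{3/2} α_k))] · e^{ikωt} }

with Womersley number α_k = R√(kω/ν), and the steady component is
Poiseuille flow.  This normalisation conserves flow exactly
(2π∫ u r dr = Q(t)), and the wall shear stress τ(t) = −μ ∂u/∂r|_{r=R} is
available in closed form — so every voxel-based estimate has an exact
reference.  Blood is Newtonian with ρ = 1060 kg/m³, μ = 3.5·10⁻³ Pa·s.

The virtual scanner samples this field with partial-volume averaging
(voxel velocity = lumen-fraction-diluted mean over sub-voxel quadrature
points), discrete cardiac frames (35 ms; 42 ms for the 1.5 mm scan, as in
the emulated protocol), and optional phase-contrast noise with
σ_v = √2·venc/(π·SNR) at venc = 150 cm/s.  Downstream modules mirror the
clinical pipeline: threshold segmentation of the magnitude image,
equivalent diameter 2√(A/π) of the inlet plane, per-frame degree-4
polynomial inlet-surface fits, voxel-sum flow rate, phase-windowed plane
velocity metrics (peak frame ± 1 for systole, low-flow frames for
diastole), and eight-sector WSS from near-wall velocity-gradient line fits
(μ·|slope|, sectors R, RA, A, LA, L, LP, P, RP every 45°).

Cross-resolution comparisons use the symmetric percent difference
|a−b| / ((a+b)/2) × 100, mean ± sample SD summaries, and an exact Wilcoxon
signed-rank test (zeros dropped, ties mid-ranked, two-sided p by full
enumeration of sign assignments for n ≤ 25).  The same statistics re-derive
every derived cell of the published four-resolution aortic comparison
tables from their printed value columns (`flowres.reference_tables`).

## Worked example

```python
import numpy as np
from flowres import *

vessel = VesselModel()                       # 25.15 mm straight tube
decomp = decompose(make_waveform(), 8)       # Q(t) -> 8 harmonics
field  = WomersleyField(decomp, vessel, BLOOD)

vox  = acquire(field, vessel, AcquisitionSettings(voxel_size=4.0), period=0.9)
mask = segment(vox, threshold=0.5)
q    = flow_rate(extract_inlet_samples(vox, mask, PlaneSpec(-0.0125)))
print(f"peak Q: {1e6*q.max():.1f} mL/s of {1e6*decomp.reconstruct(vox.frame_times).max():.1f} analytic")
```

prints `peak Q: 239.0 mL/s of 243.9 analytic` — the 4 mm scan already loses
2% of the peak flow to partial-volume dilution.  The full experiment,
`python analysis/07_resolution_sweep.py`, averages 10 seeded grid offsets
per voxel size and prints the recovery of each quantity against the
analytic truth:

```
quantity                          4.0      3.0      2.0      1.5  (mm)
peak_flow                       96.33    97.67    98.90    99.34
max_velocity (systole)          98.86    99.41    99.76    99.87
mean_velocity (systole)         94.45    96.18    97.44    98.51
max_velocity (diastole)         94.46    97.11    98.84    99.37
wss_P (systole)                  2.35     3.45     5.03     6.91
wss_P (diastole)                13.75    19.82    25.33    26.31
```

Every row is an underestimate that recovers monotonically as voxels
shrink; WSS — whose wall gradient lives in a boundary layer thinner than
any of the voxel sizes — is by far the most resolution-sensitive quantity,
the central conclusion of resolution-sensitivity studies of this kind.
The numbered scripts under `analysis/` walk the same pipeline stage by
stage (ground truth, virtual scans, geometry, inlet conditions,
velocity/WSS metrics, published-table statistics, the sweep) and write
their tables under `results/`.

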