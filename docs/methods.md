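# Methods

## Ground-truth flow

The reference hemodynamics are pulsatile laminar flow in a rigid straight
circular tube — the analytic stand-in for both the patient's ascending
aorta and a CFD solution.  The inflow waveform Q(t) is periodic (period
T = 0.9 s), built from a raised half-sine-squared systolic bump on a
constant diastolic baseline: peak flow 2.45·10⁻⁴ m³/s, systolic fraction
0.35 of the cycle, end-diastolic flow 10⁻⁵ m³/s, 128 samples per cycle.
The bump's two halves have zero slope at their junctions, so the waveform
is C¹ and periodic; the bump centre is snapped onto the sample grid so the
stored maximum equals the nominal peak exactly.  No flow-waveform values
are published for the emulated protocol, so this shape is a stand-in
chosen to reproduce the qualitative features (sharp systolic peak, long
low-flow diastole); no quantitative result depends on its exact form.

A truncated Fourier series (K = 8 harmonics, coefficients from the FFT of
the uniform samples) represents the waveform to 0.27% RMS of peak flow.
Each harmonic drives the flow-normalised Womersley solution; the steady
term is Poiseuille flow.  With this normalisation the cross-section
integral of the velocity profile reproduces the truncated series exactly
(validated against Gauss–Legendre quadrature to ~10⁻¹⁵ relative), the
no-slip condition holds to machine precision, and the wall shear stress

    τ(t) = −μ ∂u/∂r|_{r=R}
         = 4μQ₀/(πR³) − μ Σ_k Re{ (Q_k/πR²)(Λ_k/R) J₁(Λ_k)/(J₀(Λ_k) D_k) e^{ikωt} },
    Λ_k = i^{3/2} α_k,  D_k = 1 − 2J₁(Λ_k)/(Λ_k J₀(Λ_k)),

follows in closed form (validated against a second-order one-sided finite
difference of the profile at the wall, h = 10⁻⁶ m, to better than 10⁻⁶ of
the cycle's peak stress).  Complex-argument Bessel functions come from
`scipy.special.jv`, accurate far beyond the α ≤ 52 range used here
(α₁ ≈ 18.3 at the default radius; α_k grows as √k).

Defaults: tube radius 12.575 mm (the 25.15 mm mid-ascending-aortic
diameter of the emulated patient), length 50 mm, axis +y, blood with
ρ = 1060 kg/m³ and μ = 3.5·10⁻³ Pa·s.  The resulting peak systolic
centreline velocity is ≈ 0.62 m/s and peak wall shear stress ≈ 2.9 Pa —
physiological aortic scales.

For bulk evaluation the field caches complex radial mode shapes on a
4096-point radius grid; a time sample is then one phase sum plus a linear
interpolation (≤ 10⁻⁶ m/s error against direct Bessel evaluation, and the
cache can be disabled).

## Virtual scanner

Acquisition samples the continuous field on an isotropic voxel grid
covering the vessel's bounding box plus a one-voxel margin, optionally
shifted by a sub-voxel grid offset.  Partial volume is modelled by
fixed-grid subsampling: 4³ quadrature points per voxel; the magnitude
channel stores the lumen point fraction.  The voxel velocity is the mean
of the field over the voxel's lumen-interior points scaled by that lumen
fraction — equivalently, the mean of the zero-extended field over the
whole voxel.  This *signal dilution* reflects how phase-contrast velocity
estimates mix static-tissue signal (at zero velocity) into rim voxels, and
it is what makes coarse scans underestimate flow, velocity and wall shear
stress; without it, rim voxels keep their undiluted interior mean and the
voxel-sum flow rate *over*estimates the truth at coarse resolution.  The
undiluted variant remains available (`signal_dilution=False`) for oracle
tests (on a linear field an undiluted voxel value equals the field at the
lumen-subsample centroid).

Frames are instantaneous samples at frame centres (j + ½)Δt, with
n = ⌊T/Δt⌋ frames per cycle; there is no view-sharing or multi-beat
averaging model — beat averaging is treated as already folded into the
noise-free field.  The emulated protocol uses Δt = 35 ms at 4/3/2 mm and
42 ms at 1.5 mm, venc = 150 cm/s.  Velocity noise, when enabled, is
zero-mean Gaussian per component with σ_v = √2·venc/(π·SNR) applied to
lumen voxels only; the protocol's SNR is unreported, so SNR is a free
parameter (default 30, i.e. σ_v ≈ 0.0225 m/s) and the study's trend
experiments run noise-free.  Velocity aliasing is not modelled: the venc
(1.5 m/s) exceeds every velocity in the emulated regime.

## Segmentation and geometry

The lumen mask is a plain threshold on the partial-volume magnitude.  The
default threshold 0.25 accepts rim voxels with a quarter coverage and
reproduces the dilation of coarse scans (the published diameter-table
trend); 0.5 is asymptotically unbiased and is used wherever geometry
should not confound a velocity comparison (all sweep defaults).  Plane
measurements count lumen voxels in the half-open voxel slice containing
the plane coordinate: area = count · h², equivalent diameter d = 2√(A/π)
(the published tables do not state their diameter convention; the
equivalent-circle definition is adopted throughout).

## Inlet conditions and flow rate

Inlet samples are the through-plane (axial) velocities at lumen voxel
centres of the inlet slice.  The inlet surface is fitted per frame by
ordinary least squares over the bivariate monomials x^a z^b, a+b ≤ 4, in
centred/scaled coordinates, with minimum-norm resolution of rank-deficient
systems (logged) and a hard no-slip clamp outside the sample radius plus
half a voxel; time evaluation interpolates linearly (cyclically) between
frames.  The source protocol names neither its fit family nor degree;
degree 4 balances the coarse scan's ~30 inlet samples against
expressiveness, and an `InsufficientSamplesError` signals frames with
fewer samples than basis terms — the coarse-resolution failure mode.
Volumetric flow rate is the voxel-sum Riemann integral Σ v·h² (the most
literal voxel-data estimate); a fit-based disc integral is provided as a
documented alternative and differs by the fit's interpolation error.

## Phase windows and plane metrics

The systolic window is the peak-flow frame and its two cyclic neighbours;
the diastolic window runs from the first post-peak frame below 0.2 × peak
flow to the end of the cycle (the windowing of the emulated study marks
diastole only graphically; 0.2 is the package's choice).  Ties on the peak
break to the earliest frame.  Plane metrics average per-voxel speed over
the window frames first, then take the maximum and mean over the slice
(magnitude-then-average; component-averaging first would differ for
oscillating diastolic flow and is intentionally not the default).  The
analytic reference applies the identical reduction to |u(r, t)| on a dense
radius grid with area weighting.

## Sector wall shear stress

WSS is estimated on eight rays at 45° spacing in the analysis plane
(R at +x, A at −z; order R, RA, A, LA, L, LP, P, RP), each value taken at
the ray angle, not sector-averaged.  Along each ray the through-plane
velocity is sampled at three wall-inward positions (spacing = voxel size
for voxel data via trilinear interpolation, R/200 for continuous fields),
a straight line is fitted, and WSS = μ·|slope|, phase-averaged over the
window.  The wall position comes from the vessel model.  On the analytic
field this estimator recovers the Poiseuille closed form 2μU_max/R within
1 − 2Δ/R (≈ 1% at the dense spacing); on voxel data it inherits both the
coarse sampling of the gradient and the partial-volume dilution of
near-wall velocities, which is why WSS is the most resolution-sensitive
quantity in the sweep (systolic recovery of only a few percent even at
1.5 mm — the systolic boundary layer, δ ≈ R/α ≈ 0.7 mm, is thinner than
every voxel size tested).

## Comparison statistics

Percent differences use the pair mean as base, |a−b|/((a+b)/2)·100 — the
only base consistent with all sixteen printed difference cells of the
published tables (relative-to-reference bases reproduce none of them).
Summaries are mean ± sample SD (n−1 denominator; the population SD does
not reproduce the printed 0.05758).  The Wilcoxon signed-rank test drops
zero differences, mid-ranks ties, and computes the exact two-sided
p-value for n ≤ 25 by dynamic programming over the doubled ranks —
numerically identical to enumerating all 2ⁿ sign assignments, which the
test suite does independently — with a tie- and continuity-corrected
normal approximation above n = 25.  p is reported as 2·min(P(W ≤ w),
P(W ≥ w)), capped at 1.

## Sweep design

The sweep runs acquire → segment → inlet extraction/fit → flow rate →
phase windows → plane metrics → sector WSS per (voxel size, grid offset),
with the analytic field evaluated identically as the reference method, and
aggregates means over offsets, percent differences and cross-resolution
summaries.  Grid offsets are drawn once per offset index from the run seed
and shared across voxel sizes, pairing the comparisons; every stochastic
path is seeded and two runs with the same configuration produce
byte-identical CSV output.

The trend experiments (and `scripts/acceptance.py`) use 10 grid offsets,
noise-free acquisition, threshold 0.5, and hold the frame interval at
35 ms for *all* voxel sizes: the emulated protocol's coarser Δt at 1.5 mm
shifts the diastolic window and confounds the spatial trend (exactly the
temporal-resolution caveat the source protocol acknowledges), so the
spatial studies remove that variable by design.  The mixed-Δt protocol
remains the package default for emulation runs.  The geometry-dilation
experiment uses threshold 0.25 and a single systolic frame, since the
magnitude channel is frame-independent.

## What the synthetic data does and does not show

The generator reproduces the resolution-dependent mechanisms —
partial-volume dilution, sub-voxel gradient loss, segmentation dilation,
frame discretisation, venc-scaled noise — in an axisymmetric straight
tube.  It does not reproduce patient anatomy (curvature, branches,
secondary flows), turbulence, wall motion, beat-to-beat variability, or
k-space/gating artefacts.  Passing trends therefore demonstrate that the
pipeline recovers the direction and monotonicity of resolution effects,
not the patient-specific magnitudes of any in-vivo study; the published
tables' derived columns are reproduced exactly because they are pure
functions of the printed inputs.

## Numerical choices and degenerate inputs

Radial profile cache 4096 points (linear interpolation); quadrature 4³
points per voxel; waveform decomposition rejects harmonic counts beyond
the Nyquist limit of its sampling; `pct_diff` requires a + b > 0; empty
plane slices, under-determined fit frames and rays with too few lumen
samples raise typed errors (`EmptyRegionError`, `InsufficientSamplesError`,
`DegenerateRayError`) rather than returning silent zeros; an all-zero
Wilcoxon difference vector yields a logged degenerate result with p = 1.
Problem sizes throughout (10–20 offsets, ≤ 8262 lumen voxels at 1.5 mm,
K = 8 harmonics) keep the full analysis and test suite in the
single-minute range on one CPU while leaving every trend statistically
unambiguous.
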