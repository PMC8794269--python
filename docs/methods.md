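# Methods

## Scope and model assumptions

The package estimates wall shear stress (WSS) at the zebrafish
atrioventricular canal (AVC) from 2D + time imaging, under two rheological
treatments of blood, and implements the formula-defined fluorescence
quantifications used alongside such measurements.  Common assumptions:

* Flow is quasi-steady and laminar at embryonic-heart scales (Re « 1); the
  instantaneous velocity profile is parabolic across the lumen.
* Blood plasma is Newtonian with constant dynamic viscosity
  (default 1.5 mPa·s); no shear thinning.
* Shear stress is always τ = μ γ̇, checked as an invariant on every trace.
* Geometry is planar: wall contours are 2D polylines, the canal
  cross-section a 2D polygon.  3D effects enter only through the
  maximum-inscribed-circle radius (a conservative, i.e. maximal, shear
  parameterisation) and through disk summation when volumes are built from
  slice polygons.

### Two-phase estimator (`wss.near_wall_shear`)

For a velocity sample at distance `d` from the wall, γ̇ = |v_t|/d with `v_t`
the component tangential to the wall at the nearest wall point.  Design
choices where the procedure is genuinely open:

* **Tangential projection** (default) versus raw speed: shear is defined by
  the tangential velocity gradient; normal motion mostly reflects wall
  movement.  A `projection="magnitude"` switch restores the speed-based
  variant.
* **Wall-relative velocity** (default on): the local wall velocity
  (displacement of the same normalized arc-length position between frames)
  is subtracted, so a contracting wall is not read as flow.  Switchable off.
* **Near-wall cutoff**: default 0.15 × the local inscribed radius.  The
  linear profile is the first-order Taylor expansion of the parabola at the
  wall; at distance d the estimate is biased low by a factor
  (1 − d/2R), so d < 0.15 R keeps the Taylor error below ~8% and the stated
  15% tolerance has margin for velocity-sampling error.
* **Per-frame statistic**: maximum over qualifying particles (the analyses
  this supports report maximal WSS); the per-frame mean is emitted
  alongside.  Frames with no qualifying particle carry NaN, never zero.

### One-phase estimator (`wss.flow_rate_from_volume`, `wss.parabolic_wall_shear`)

Q = −dV/dt by second-order central differences (second-order one-sided
stencils at the ends; exact for affine volume traces).  No spline fitting —
the finite-difference error bound ((ωΔt)²/6 for a sinusoid) is provable and
small at ≥ 100 samples per cycle.  Wall shear is 4|Q|/(πr³) with `r` the
maximum inscribed circle radius of the cross-section polygon, found by grid
search at a caller-stated resolution plus Nelder–Mead refinement of the
distance-to-boundary objective (radius guaranteed within resolution/2, in
practice ~1e-6).  Unit bookkeeping: Q in nl/s and r in μm give
γ̇[s⁻¹] = 4·10⁶ Q/(πr³); τ[Pa] = 10⁻³ μ[mPa·s] γ̇.

### Trace post-processing (`wss.postprocess_trace`, `wss.compare_traces`)

Traces are treated as periodic over one cardiac cycle.  Smoothing is a
centred moving mean over 2h+1 frames (default h = 2) with periodic boundary,
which conserves the trace mean exactly; alignment circularly shifts the
trace so a caller-identified event (e.g. widest lumen) lands at a stated
time.  Aggregates (max, 95th percentile) are recomputed on the smoothed
series.  Comparisons report ratios of maxima and 95th percentiles with
zero-denominator guards; no significance claims.

## Free-form registration (`tracking`)

Displacements live on a regular control grid (default 5.6 μm) and are the
coefficients of a separable cubic B-spline, so the zero field is exactly the
identity and constant coefficients give an exactly constant field (partition
of unity).  Registration minimises mean squared intensity difference with
L-BFGS-B and an analytic gradient (adjoint of the B-spline interpolation),
over a 3-level pyramid (factors 4, 2, 1; Gaussian smoothing before
decimation; the control grid lives in full-resolution coordinates at all
levels).  Iteration caps (40/40/60) and the relative-objective tolerance
(1e-7) are package choices; the optimizer's monotone line search plus a
final fallback guarantee the solution objective never exceeds the
initialization's.  No smoothness penalty beyond grid coarseness by default
(an optional first-difference weight is exposed).  Track linking is
nearest-neighbour between warped centroids and next-frame detections within
a gating radius (default 2 × grid spacing); gating failures terminate tracks
rather than guessing.  Minimum particle area 4 px² rejects single-pixel
noise.

## Dot-density statistic (`rnascope`)

The four formulas are implemented literally: background = I/A of a dot-free
region; mean per-dot intensity = (ΣI_i − background·ΣA_i)/n over n isolated
reference dots (the protocol's 20 generalised to any n ≥ 1, with n
recorded); region count = (I_ROI − background·A_ROI)/Ī_dot; density =
count/area.  Negative counts pass through unmodified — they are the honest
output of a difference of noisy sums near zero.  Pixel membership uses
pixel-centre containment with half-open boundary ties (left/top edges in),
making counts additive over tilings.  Three z-slices (mid-valve plus
neighbours) are pooled by summing intensities and areas before applying the
formula; per-slice results are also available so an averaging convention can
be recovered.  Reference-dot selection is caller-supplied; the statistic
never depends on automated spot detection.

## Ratio quantifications (`ratiometry`)

Intensities along caller-annotated membrane segments are sampled at 1-px
arc-length spacing with bilinear interpolation (deterministic and
resolution-independent).  The interface ratio averages a per-interface
statistic (mean or max) within each label set before dividing, making it
invariant to global intensity rescaling.  The polarity ratio-of-ratios sums
per-slice channel means over slices before forming ratios (per-slice values
are emitted too) and is invariant to independent rescaling of either
channel.  The one-sample test against the theoretical value 1 is the
Wilcoxon signed-rank test — the coherent one-sample analogue of a rank test
against a constant — exact for n ≤ 25 with no ties or zero differences
(verified against exhaustive 2ⁿ sign enumeration in the tests), normal
approximation otherwise; n ≥ 5 is required, and an all-at-null sample is
reported as degenerate with p = 1.

## Synthetic data: what it emulates, and what it does not

`synthetic` generates every fixture with known ground truth:

* **Tube movies**: a straight 2D tube of (possibly time-varying) radius
  R(t), parabolic axial flow v(r,t) = 2Q/(πR²)(1 − r²/R²), tracers advected
  with the fluid velocity at their centre (midpoint sub-stepping), a
  consistent ventricular volume trace with −dV/dt = Q(t), and the analytic
  wall shear 4Q/(πR³) emitted per frame.  Default flow is
  Q(t) = Q₀ cos(2πt/period) — oscillatory with zero net drift, so tracers
  stay in view; tracers that do leave re-enter at the other end under a new
  track id (count conserved).  Rendering: Gaussian blobs for tracers, a
  Gaussian-profile ridge per wall, additive Gaussian noise of constant
  variance.  Coordinates are pixel-centred, origin top-left, x right,
  y down, with a single μm-per-pixel calibration.
* **Volume traces**: V(t) = V₀ + A sin(2πt/period + phase) with the
  closed-form Q(t) returned as ground truth.
* **Spot images**: uniform background plus Gaussian dots placed fully inside
  their ROI (3σ margin) and isolated (4σ minimum separation, bounded
  retries then error).  The ledger records each dot's analytic integrated
  intensity a·2πσ² and effective area π(3σ)².  Defaults (background 50,
  amplitude 80, σ = 2 px, noise SD 8 — i.e. peak SNR 10, typical of
  confocal smFISH) were fixed once as realistic study conditions.
* **Polarity images**: a row of rectangular cells with apical (top), basal
  (bottom) and lateral membranes drawn as Gaussian-profile lines,
  max-composited so crossing membranes do not double up; annotation
  segments are shrunk 2σ from corners so samples avoid junctions.

Not emulated: photorealistic cardiac texture, 3D geometry, red-blood-cell
deformation and crowding, motion blur, detector noise statistics
(imaging-noise characteristics of spinning-disk data are not public, so
fixture noise levels are free parameters).  Passing tests therefore
demonstrate correctness of the estimators under their stated assumptions,
not robustness to every artefact of real movies.

## Default problem sizes

The cross-validation scenario uses R = 25 μm, Q₀ = 1 nl/s, a 0.5 s cycle at
100 frames per cycle for 2 cycles, and 150 tracers — enough near-wall
samples that the two-phase per-frame maximum is dominated by cells within a
few percent of the radius of the wall.  Registration checks run on 256²
textured images (Gaussian-filtered white noise, correlation length ~3 px).
Dot-recovery statistics aggregate 50 seeded fixtures.  These sizes are the
package's reference conditions; all are parameters.

## Known limitations

* The two-phase estimator is biased low by ~d/(2R) per sample; reported
  maxima inherit the bias of the closest sampled cell.
* The Corcione correlation is extrapolated when φ < 1e-4 or d_p outside
  25–200 nm; the package warns rather than fails because the plasma
  d_p/d_f ratio itself sits at the edge of the fitted regime.  The measured
  viscosity of a diluted nanoemulsion and the correlation's prediction are
  reported through separate pathways and are not reconciled.
* Track identity across frames is plumbing (nearest neighbour with gating),
  not a claim about how any particular study maintained identities.
* No Navier–Stokes or fluid–structure interaction; the parabolic and
  linear-profile models are the whole hydrodynamic content.
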