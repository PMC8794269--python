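# valveflow

Quantitative tools for studying how blood flow shapes the developing
zebrafish heart valve: wall-shear-stress (WSS) estimation from beating-heart
imaging under two blood-rheology regimes, an effective-viscosity model for
plasma and injected lipid nanoemulsions, and formula-defined fluorescence
quantifications (smFISH dot densities, junction and apical/basal polarity
intensity ratios).  Because the underlying microscopy movies of such studies
are rarely deposited, the package ships first-class synthetic-data
generators with analytic ground truth, and every estimator is validated
against that ground truth.

It is aimed at developmental-biology and cardiovascular-mechanobiology labs
that need reproducible, scriptable versions of these measurements instead of
one-off image-tool macros.

## The models

**Two-phase (wild type, red blood cells present).**  Tracked blood cells
passing near the atrioventricular canal (AVC) wall are point samples of
fluid velocity.  Assuming a linear velocity profile between the cell and the
wall, the shear rate at the wall is

    γ̇ = |v_t| / d,        τ = μ γ̇,

with `v_t` the wall-tangential velocity component, `d` the cell-to-wall
distance and `μ` the plasma viscosity.  Cell motion comes from pairwise
free-form image registration (cubic B-spline control grid, 5.6 μm spacing,
mean-square intensity metric, warm-started with half the previous frame's
deformation) followed by intensity-threshold segmentation.

**One-phase (*gata1* mutants, no red blood cells).**  Flow is the rate of
ventricular volume change, `Q = −dV/dt`, and the wall shear rate follows a
parabolic (Poiseuille) profile across the maximum inscribed circle of the
canal cross-section:

    γ̇_wall = 4 Q / (π r³),

a conservative (maximal) estimate.  Traces are smoothed with a ±2-frame
periodic envelope; maxima and 95th percentiles summarise the cycle.

**Effective viscosity.**  Plasma (μ_f = 1.5 mPa·s, M = 100 kDa,
ρ = 997 kg/m³) laden with nanoparticles of diameter `d_p` at volume fraction
`φ` follows the Corcione nanofluid correlation

    μ_eff / μ_f = 1 / (1 − 34.87 (d_p/d_f)^−0.3 φ^1.03),
    d_f = 0.1 (6M / (N π ρ_f0))^(1/3),

with `N` Avogadro's number.  An injection calculator converts a bolus
(e.g. 4.6 nl into 60 nl of blood, a 1:13 dilution) into `φ`.

**Fluorescence statistics.**  smFISH dot counts use an intensity budget:
`count = (I_ROI − background·A_ROI) / Ī_dot`, with the background from a
dot-free region and `Ī_dot` from ~20 isolated reference dots; counts near
zero may legitimately be negative.  Junction ratios divide across-interface
averages of per-interface mean (or max) intensity between two labeled cell
populations.  Polarity is the ratio-of-ratios
`(apical green/red) / (basal green/red)`; departures from the theoretical
value 1 are tested with a one-sample Wilcoxon signed-rank test.

## Worked example

```python
import numpy as np
import valveflow as vf

# a pulsatile tube (R = 25 μm, Q(t) = 1 nl/s · cos(2πt/0.5 s)) with tracers
sc = vf.synthetic.TubeFlowScenario(radius_fn=25.0, peak_flow=1.0,
                                   period=0.5, frame_interval=0.005,
                                   n_frames=200, tracer_count=150,
                                   tracer_radius=1.0, seed=1)
movie = vf.synthetic.generate_tube_movie(sc, render=False)
true_max = movie.ground_truth["wall_shear_rate_s"].max()

two = vf.wss.near_wall_shear(movie.tracks, movie.wall, viscosity=1.5,
                             near_wall_cutoff=0.15 * 25.0)
t, q = vf.wss.flow_rate_from_volume(movie.volume_trace)
_, r = vf.wss.max_inscribed_circle(movie.wall.cross_sections[0], 0.5)
one = vf.wss.parabolic_wall_shear(t, q, r, viscosity=1.5)

print(f"analytic  max γ̇ = {true_max:.2f} 1/s")
print(f"two-phase max γ̇ = {two.max_rate:.2f} 1/s")
print(f"one-phase max γ̇ = {one.max_rate:.2f} 1/s")
```

prints

```
analytic  max γ̇ = 81.49 1/s
two-phase max γ̇ = 79.73 1/s
one-phase max γ̇ = 81.67 1/s
```

The analytic wall shear rate of the scenario is 4Q/(πR³) ≈ 81.5 s⁻¹ at peak
flow.  The near-wall linear-profile estimate sits ~2% below it (the linear
profile is the first-order Taylor limit of the parabola, so it approaches
the true value from below as tracked cells get closer to the wall), while
the volume-trace route reproduces it to ~0.2%.  At μ = 1.5 mPa·s the peak
one-phase wall shear stress is `1.5e-3 × 81.7 ≈ 0.12 Pa`.

The viscosity side:

```python
from valveflow.viscosity import (PLASMA, NanofluidSpec,
                                 equivalent_molecule_diameter,
                                 injection_volume_fraction,
                                 effective_viscosity)
d_f = equivalent_molecule_diameter(PLASMA)        # 6.826e-10 m
phi, dilution = injection_volume_fraction(0.05, 4.6, 60.0)
mu = effective_viscosity(NanofluidSpec(PLASMA, d_p=95e-9, phi=phi))
print(d_f, dilution, phi, mu)
# 6.826349022002333e-10  13.043478260869566  0.00356...  1.5366... mPa·s
```

A command-line interface mirrors the library
(`valveflow simulate|track|wss|dots|junctions|polarity|viscosity|demo`);
`valveflow demo --seed 0` runs the full synthetic pipeline and prints a
machine-readable report of every estimate against its ground truth.

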