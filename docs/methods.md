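# Methods

## Transport model

Diffusion of α-factor between the two agarose compartments is treated as
one-dimensional along the gradient axis: both compartments are assumed
transversely uniform, which matches the two readouts (microscopy
positions in a row orthogonal to the boundary, and transversely averaged
scan profiles). The domain `[0, l]` is closed (zero-flux walls at both
ends); the source initially occupies `[0, h]` at concentration C₀.
Defaults h = 5 mm, l = 10 mm, C₀ = 10 μM.

The solution is the method-of-images erf series truncated at ±N image
pairs, with N = 12 by default. N acts as a floor: when the diffusion
length √(Dt) grows comparable to the domain (t beyond ~2 days), the
number of terms is raised automatically to `ceil((6√(Dt) + l)/l)` so the
series stays converged at any time; for t ≤ 48 h the default 12 terms
reproduce doubling-N values to better than 10⁻⁹ C₀. The t = 0 case is
evaluated analytically as the exact step (C₀ inside, C₀/2 on the
boundary, 0 beyond) to avoid the 0/0 in the erf arguments. Series
values whose magnitude falls below 10⁻¹² C₀ are clamped to zero so
fields are nonnegative by construction.

### Diffusivity

The free-solution diffusivity is computed by Stokes–Einstein with the
hydrodynamic radius of the sphere carrying the peptide's anhydrous
molecular volume: M = 1700 Da, partial specific volume 0.73 cm³/g gives
r ≈ 0.79 nm, and at 30 °C (η = 7.97·10⁻⁴ Pa·s) D₀ ≈ 3.53·10⁻⁴ mm²/s.
This is a documented, physically grounded default — order-of-magnitude
consistent with measured peptide diffusivities — and the config accepts
a direct `d0_mm2_s` override for users with a measured value.

Obstruction by the agarose network uses the Amsden scaling form
`D/D0 = exp(−π((r_s + r_f)/(k_s φ^(−1/2) + 2 r_f))²)`. Defaults are
fiber radius 1.9 nm, scaling constant 1.0 nm, and polymer volume
fraction 0.0064 for 1% (w/v) agarose (1 g per 100 mL at a polymer
density near 1.6 g/cm³). These are literature-scale values, all
exposed in the config; at the defaults the correction factor is 0.918,
so the conclusions are insensitive to their exact values (the factor is
bounded in (0, 1] and enters multiplicatively).

### Secreting-cell source

A compartment of pheromone-secreting cells is modeled as a constant
volumetric source of strength q = per_od_rate · OD₆₀₀ on `[0, h]`. By
Duhamel's principle its concentration is `q ∫₀ᵗ u(x, s) ds` with u the
unit-C₀ step solution, evaluated by composite Simpson quadrature after
the substitution s = t·w² (257 nodes; the substitution clusters nodes
near s = 0 where u varies fastest, and the integral agrees with a
quadrupled-node evaluation to ~10⁻¹¹ relative). No secretion rate is
measurable from the printed record, so the per-OD rate is calibrated to
the one quantitative equivalence the experiments support: an OD 0.75
secreting compartment reproduces the 10 μM synthetic source's boundary
concentration at 6 h. Since the relation is linear the calibration is a
ratio of two boundary values.

### Finite-difference oracle

An independent Crank–Nicolson solver (vertex grid, mirror-node Neumann
boundaries, which conserve the trapezoid mass of the semi-discrete
system exactly) validates both the series and the secretion solution.
Four half-step backward-Euler startup steps damp the odd–even mode a
discontinuous initial profile would otherwise excite. At dx = 0.05 mm,
dt = 1 s the solver agrees with the series to < 10⁻³ C₀ in sup norm at
10 min, 1 h and 6 h. An explicit Euler mode exists for reference and
rejects steps violating r = D·dt/dx² ≤ 1/2.

## Response model

The pathway output is assumed proportional to a saturating function of
extracellular pheromone, modeled as a Hill curve (EC₅₀ = 10 nM — the
wild-type minimal shmoo-inducing concentration; the hypersensitive
protease-deletion value of 4 nM is available as an alternative
threshold; n = 2; shmoo ceiling 0.9). The three-class morphology split
makes the shmoo probability the Hill response, while among non-shmoo
cells the elongated fraction rises from a 5% basal value toward a 0.5
ceiling with a lower midpoint (5 nM), capturing the partial-response
band that extends beyond the shmoo zone. The probabilities sum to one
by construction and are monotone in concentration.

Promoter activity rises first-order with τ = 5 min to a ceiling F
calibrated so that the fold-change at 20 min under saturation is exactly
100 (F = 1 + 99/(1 − e⁻⁴) ≈ 101.85). Reporter fluorescence follows the
two-stage linear kinetics dP/dt = production·fold − k_m·P,
dF/dt = k_m·P with k_m = ln 2 / maturation half-time. The maturation
half-time defaults to 100 min, a typical red-fluorescent-protein scale;
an EGFP-like 25 min is a config choice. The integrator is fixed-step
classical RK4 at 0.1 min (non-stiff at these constants; halving the
step changes the 6-h fluorescence by < 0.1%); a half-time below a tenth
of the step switches to the exact instantaneous-maturation limit
(P ≡ 0, dF/dt = production·fold) rather than integrating a stiff decay.

**Detection.** "Detectable" fluorescence is operationalized as the
induced:basal ratio reaching a factor (default 3) — with an optional
constant autofluorescence floor added to both signals. The bare ratio
crosses any factor within a minute or two, because the induced pool
outpaces a near-zero basal pool from the start; that is a property of
the ratio criterion, not of the biology. The timescale comparison
therefore pins the floor at the basal trace's end-of-run level, making
detection an absolute requirement (the induced signal must rise clear of
the ambient background of uninduced cells), which is how a scanner or
eye judges distinctness. Under the defaults this puts reporter
detectability at ≈ 1.1 h for saturating pheromone — well inside the
observed few-hour scale and, at every distance in the reporter
compartment, far later than gradient arrival: the response is
reporter-limited, not diffusion-limited.

## Phenotype classification

Segmentation chain: Gaussian smoothing (σ = 1 px) → Otsu threshold
(objects brighter than background) → hole filling → distance-transform
watershed for touching cells → area filter [100, 5000] px² →
border-touching removal. Watershed markers are distance-transform
maxima at least half their component's maximum — this splits genuinely
touching cells of similar size while leaving a shmoo's protrusion lobe
(whose distance peak is ≈ 0.45 of the body's) attached to its body.

Eccentricity comes from the region's central second moments
(E = √(1 − λ_min/λ_max)); degenerate collinear regions clamp to 0.999.
Classification uses half-open bands: circular E < 0.60, elongated
0.60 ≤ E < 0.85, shmoo E ≥ 0.85. These cut points were chosen jointly
with the generator's canonical shapes (see below); they are config
values, since eccentricity alone cannot distinguish a pear-shaped
protrusion from a long ellipse in every case — a documented limitation
shared by any single-feature classifier.

Per-cell fluorescence is the mean over the cell's interior (mask eroded
by 3 px) so point-spread-diluted edge pixels do not bias the estimate
downward; cells too small to survive the erosion fall back to the full
mask.

The acquisition plan places fields of view in a row orthogonal to the
boundary at 0.3 mm spacing. Sixteen positions is the default (spanning
4.65 mm less one half-field); an eleven-position preset exists, since
both layouts appear in the experimental record. The first field is
centered 0.15 mm from the boundary — the plan gives spacing but no
origin offset, so half a spacing is adopted as the natural
field-of-view-center convention.

## Scan profiles

A scan is reduced to its profile by averaging the ROI transversely per
pixel column, distances measured from the boundary edge inward.
Normalization is `(raw − background)/(reference − background)` with the
background from a configured cell-free ROI and the reference from the
constitutive-fluorescence compartment, whose own profile then peaks at
exactly 1.0. Extent and peak queries run after a 3-sample median filter
for single-pixel robustness; the detection threshold defaults to 5% of
the constitutive reference, conservative relative to the generator's
noise floor. Scan resolution defaults to 0.1 mm/px.

## Synthetic data

The generator emulates the study conditions: 16 positions × 0.3 mm, a
10 μM source diffusing for 6 h to set per-position concentrations,
60 cells per 600 × 600 px field (0.5 μm/px), additive Gaussian noise
(σ = 4 on a 20/120 background/foreground scale), Gaussian PSF σ = 1 px,
90% viability, and 5 × 5 mm scans at 0.1 mm/px with a 1000-unit dynamic
range over a 100-unit background (noise σ = 5). Cell shapes are
co-calibrated with the classifier: discs for circular cells,
area-preserving ellipses with axis ratios drawn from [1.5, 1.8]
(E ≈ 0.75–0.84) for elongated cells, and a ratio-1.6 body fused with a
0.45 r polar lobe centered 1.25 major-semi-axes out (E ≈ 0.87–0.90 over
all orientations) for shmoos, so every rendered cell's noise-free
geometry classifies to its generating class. Per-cell fluorescence
carries 10% lognormal scatter around the position's reporter level.
Placement is rejection sampling with per-cell footprints, so rendered
cells never touch; the instrument-faithful higher magnification
(≈ 0.128 μm/px at 100×) is available by config but the coarser default
keeps the test suite fast.

What the generator does *not* emulate: bright-field optics (halos,
defocus), Poisson shot noise, cell growth or budding during incubation,
touching/overlapping cells at high density, and any mechanism producing
the sub-boundary fluorescence peak seen in real scans — an optional,
clearly-labeled edge-attenuation term `(1 − a·e^(−d/w))` can impose such
a peak on synthetic scans, but it is disabled by default and no
mechanistic claim is attached to it. Passing tests therefore validate
the pipeline's internal consistency and its statistical behavior under
the stated noise model, not its performance on real micrographs.

## Problem sizes and determinism

The validation suite uses a 0.05 mm / 1 s Crank–Nicolson grid (201
points), 16-position microscopy suites of ~500 cells, and 50 × 50 px
scans — all chosen so each stage completes in seconds on one CPU while
leaving comfortable margins to its tolerance. Every random draw flows
from one integer seed through `numpy.random.SeedSequence`; identical
configs and seeds give byte-identical images, tables and output files.

## Known limitations

- The transport model is 1-D and ignores α-factor degradation, Bar1
  protease activity (the modeled strains lack it), receptor-mediated
  depletion and convection.
- The true α-factor diffusivity in the original experiments is not
  printed in the available record; the Stokes–Einstein default is a
  stand-in, and conclusions drawn at millimeter/hour scales are robust
  to its ~tens-of-percent uncertainty.
- The dose–response and promoter forms are minimal monotone models
  consistent with the qualitative record, not fitted curves; their
  parameters are config values.
- Eccentricity-only classification confuses long ellipses with shmoos
  near the 0.85 boundary; the generator avoids that band by
  construction, real data need not.
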