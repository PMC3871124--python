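# pherosim

Spatio-temporal modeling and image analysis for a two-compartment yeast
pheromone signaling system.

## The problem

Whole-cell biosensors can be built from two communicating yeast
populations: sensor cells that secrete the mating pheromone α-factor
(~1.7 kDa) in response to an analyte, and reporter cells of mating type
**a** that answer the pheromone with mating-projection ("shmoo")
formation and expression of a fluorescent protein from the
pheromone-inducible *FIG1* promoter. When the two populations are
immobilized in adjacent agarose compartments, the usable compartment
size and the response time are set by two competing processes: diffusion
of α-factor across the compartment boundary, and expression plus
chromophore maturation of the reporter protein. `pherosim` models both
and provides the image-analysis pipeline that reads the response out of
microscopy fields and fluorescence scans, together with a synthetic-data
generator so the entire pipeline runs and validates without external
data.

## The model

**Transport.** One-dimensional diffusion along the gradient axis in a
closed domain `[0, l]` (reflecting walls), with the source initially
filling `[0, h]` at concentration C₀. The method of images gives the erf
series

```
C(x,t) = (C0/2) Σₙ [ erf((h + 2nl − x)/(2√(Dt))) + erf((h − 2nl + x)/(2√(Dt))) ]
```

summed over n ∈ [−N, N]. The free-solution diffusivity D₀ comes from
Stokes–Einstein (M = 1700 Da, 30 °C: D₀ ≈ 3.5·10⁻⁴ mm²/s) and is reduced
by the Amsden obstruction factor for 1% agarose,
`D/D0 = exp(−π((r_s + r_f)/(k_s φ^(−1/2) + 2 r_f))²)` (≈ 0.92).
A compartment of secreting cells is modeled, by linearity, as the time
integral of the unit step solution scaled by a per-OD₆₀₀ secretion rate,
calibrated so an OD 0.75 secreting compartment matches the 10 μM
synthetic-pheromone source at the boundary after 6 h.

**Response.** Shmoo probability is a Hill function of local
concentration (EC₅₀ = 10 nM, n = 2), with an elongated intermediate
class; the *FIG1* promoter rises first-order (τ = 5 min) to a ceiling
calibrated to give exactly 100-fold at 20 min under saturation; the
fluorescent protein matures with a 100-min half-time via a two-stage
linear ODE.

**Readout.** Cells are segmented from bright-field-like images
(Gaussian smoothing, Otsu, watershed splitting), classified as
circular / elongated / shmoo by the eccentricity E of the moment-fit
ellipse (cuts at 0.60 and 0.85), and aggregated into phenotype profiles
versus distance from the boundary. Compartment scans are reduced to 1-D
relative-intensity profiles normalized to a constitutive reference.

## Worked example

```python
from pherosim import (Geometry, default_transport_params,
                      step_source_concentration, induction_extent,
                      timescale_report, DoseResponseParams, ReporterParams)

geom = Geometry()                                 # h = 5 mm, l = 10 mm
tp = default_transport_params(c0_initial=10.0)    # 10 uM step source

c = step_source_concentration(9.0, 6 * 3600, geom, tp)
print(f"C at 4 mm after 6 h: {c:.2f} uM")
print(f"extent above 10 nM: {induction_extent(6 * 3600, 0.01, geom, tp):.1f} mm")
print(timescale_report(1.0, geom, tp, ReporterParams(), DoseResponseParams()))
```

prints

```
C at 4 mm after 6 h: 1.97 uM
extent above 10 nM: 5.0 mm
TimescaleReport(distance_mm=1.0, t_diffusion_h=0.04491041472656784,
                t_reporter_h=1.12, reporter_limited=True)
```

Four millimeters beyond the boundary the modeled concentration (1.97 μM)
is still far above the 10 nM induction threshold, so after six hours the
whole 5 mm reporter compartment can be induced — diffusion is not what
limits the response. The timescale report makes that explicit at 1 mm:
the gradient arrives within minutes (0.045 h) while the reporter needs
over an hour to become distinct against background, so the response is
reporter-limited.

The same analyses are available from the command line:

```
pherosim --outdir out simulate-diffusion
pherosim --outdir out synth           # synthetic microscopy + ground truth
pherosim --outdir out classify --images out/synth
pherosim --outdir out timescales
pherosim --outdir out reproduce      # run every headline experiment
```

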