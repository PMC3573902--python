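# dielgrow

Synchronous quantification of **leaf expansion** and **root elongation**
from grey-value time-lapse image stacks, with day/night (diel) growth
statistics — for plant physiologists measuring how organs partition their
growth between day and night and how root-zone treatments shift it.

Plants grow rhythmically: leaves of many dicot seedlings expand up to
three times faster at night than in the day, while root tips elongate at
a nearly constant rate unless the root environment changes. Measuring
both organs on the *same* plant at minute-scale resolution requires
nothing more than a camera, but turning image stacks into growth rates
requires sub-pixel motion analysis. This package implements that
analysis, together with a synthetic scene generator that renders leaf and
root time-lapses with exactly known growth, so every stage of the
pipeline is verifiable without laboratory data.

## What it computes

**Leaf relative growth rate (RGR).** Dense velocity fields are estimated
by structure-tensor optical flow (total least squares on the brightness
constancy constraint `g_x u + g_y v + g_t = 0`; velocity from the
smallest-eigenvalue eigenvector of the spatiotemporal second-moment
matrix, with confidence gating and aperture-problem rejection). The RGR
of a tracked area of interest (AOI) is computed two independent ways per
≈15-min window and reported side by side:

    RGR = ⟨∂u/∂x + ∂v/∂y⟩        (mean divergence of the velocity field)
    RGR = (ln A₁ − ln A₀) / t     (areas of the flow-advected AOI polygon)

both in h⁻¹. Agreement of the two estimators is the pipeline's built-in
self-check.

**Root tip velocity.** The root is segmented (auto-detected polarity),
skeletonised, and the tip located as the skeleton endpoint geodesically
farthest from a fixed anchor in the mature region; a capsule-model fit to
the grey values of the tip cap refines the position to a few hundredths
of a pixel. Anchor stability is verified by patch cross-correlation.
Velocities are reported per 5-min window in mm h⁻¹, as along-path
displacement (with the straight-line value alongside).

**Diel statistics.** Series are partitioned against a light schedule
(light-on inclusive, half-open), averaged per (day, period) cell,
normalised so nocturnal + diurnal = 100% per day, and summarised across
replicate plants with standard errors (s.d./√n across plants).

**Synthetic scenes.** `synthetic_data` renders textured leaves under
prescribed RGR profiles and elongating roots under prescribed velocity
profiles, plus three root-zone treatment presets (control ≈ 0.6 mm h⁻¹,
root cooling ≈ 0.3 mm h⁻¹, root illumination ≈ 0.4 mm h⁻¹ with a morning
trough; the leaf profile — nocturnal ≈ 3× diurnal with a transient
light-on dip — is identical across presets). Ground truth (rates, tip
positions, AOI polygons, displacement fields) is exported for direct
comparison.

## Worked example

Render the control preset for two hours around lights-off, analyse both
organs, and summarise:

```bash
dielgrow simulate --preset control --out sim --seed 19 \
    --duration-h 2.0 --start-clock 19.0
dielgrow analyze-root --stack sim/root.tif --out results
dielgrow analyze-leaf --stack sim/leaf.tif --out results
dielgrow summarize --series results/root_velocity.csv \
    --treatment control --out results
```

`results/root_velocity.csv` then holds one row per 5-min window:

```
window_start_clock,window_end_clock,velocity_mm_h,...
19,19.083333,0.59833813,...
19.083333,19.166667,0.60077422,...
```

— the tip moves at ≈ 0.6 mm h⁻¹, the preset's configured control
velocity. `results/diel_summary.csv` aggregates the windows by period:

```
treatment,day,period,mean,sem,n,share_pct
control,1,diurnal,0.59989311,,1,49.997767
control,1,nocturnal,0.59994671,,1,50.002233
```

Root growth splits almost exactly 50:50 between the light and dark
period (the control root grows at a constant rate; `sem` is empty because
a single simulated plant has no replicate scatter). The same library
calls are available in Python via `dielgrow.make_root_stack`,
`dielgrow.tip_velocity_series`, `dielgrow.rgr_series`,
`dielgrow.summarize_replicates`, etc.

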