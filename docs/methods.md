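# Methods

This note documents the models and procedures implemented in `lampcall`,
the defaults they ship with, and what the synthetic fixtures do and do not
establish about real data.

## Hue as the readout

Colorimetric LAMP dyes move between two endpoint colors; the hue channel of
the HSB color space separates the endpoints better than any single RGB
channel, so hue is the sole calling statistic. The conversion is the
standard hexcone hue `H ∈ [0°, 360°)` rescaled to 8 bits,
`h = round(H · 255/360)`, giving the 0–255 circular scale common in 8-bit
imaging. Achromatic pixels (r = g = b), where hue is undefined, map to 0 by
convention so the conversion is total.

Hue is circular: 255 adjoins 0 at red. Phenol red's pink (hue 220) to
yellow (hue 40) transition crosses that wrap, so naive subtraction would
report −180 for what is physically a +76 shift. All arithmetic therefore
goes through the signed minimal circular difference
(`hue_delta_signed`, range (−128, +128], ties at 128 resolved positive),
and every per-well series is unwrapped onto an unbounded real scale before
means, standard deviations or smoothing are computed. This is what makes
"hue rises for PR, falls for HNB" well defined: the dye profile's
`direction` is the sign of the minimal circular path from its negative to
its positive hue (+1 for PR, −1 for HNB).

### Built-in dye profiles

| dye | negative color | hue | positive color | hue | direction | k_sd |
|-----|----------------|-----|----------------|-----|-----------|------|
| PR  | (255, 0, 210) pink | 220 | (255, 240, 0) yellow | 40 | +1 | 3 |
| HNB | (180, 0, 255) violet | 200 | (0, 60, 255) blue | 160 | −1 | 3 |

The endpoint RGB constants were solved analytically so the 8-bit conversion
hits the canonical hue endpoints exactly (e.g. for a hue-sector color
(255, 0, m), `h = 255 − m/6`, so m = 210 gives 220). The threshold
multiplier `k_sd` is 3 or 5 depending on dye chemistry conventions; both
built-ins ship with 3 and the value is overridable per profile and per run
(`--k`). Saturation and brightness are computed nowhere; only hue is used.

## Extraction

Each well's readout is the hue of the **mean RGB color** over its ROI disc,
not the mean of per-pixel hues: a circular mean is ill-defined for pixel
distributions straddling the red wrap, exactly where PR sits. On
near-uniform discs the two agree to within ~2 hue units (verified against
a circular-mean oracle in the tests); mean-RGB is stable everywhere.
Pixels are weighted uniformly inside the disc.

## Plate geometry

The camera and plate are rigidly mounted, so wells are a parametric 12×8
grid (rows A–H, columns 1–12, row-major A1-first ordering, which fixes the
CSV column order), not blob detections. `standard_layout` centers the grid
with a fractional margin (default 5%) and sets the ROI disc radius to 0.20
of the smaller pitch — small enough that a disc fits inside the centroid
search window and avoids tube-wall edge pixels, configurable where the
visible liquid area differs. `refine_rois` absorbs registration drift by
moving each center to the contrast centroid (|luminance − window median|)
within a ±pitch/4 window, iterated to convergence with total displacement
clamped to pitch/4; flat windows keep the nominal center and log a warning.
Iteration (rather than one pass) removes the bias a window-clipped disc
would cause and makes refinement idempotent.

## Calling

Per well: unwrap the raw hues, smooth with the trailing 3-point moving
average (partial windows at the first two frames), compute baseline mean μ
and *sample* SD σ from the **raw unwrapped** values in the baseline window,
and call positive at the first frame strictly after the window where

```
direction · (smoothed[t] − μ) > max(k·σ, δ_min)
```

Choices worth stating:

- **Baseline window 0–2 min** by default; a 3–4 min window and a delayed
  first-report time are available via configuration, since both conventions
  appear in practice.
- **Baseline from raw values, calls on smoothed values.** The threshold
  reflects genuine early-run noise; the smoothed curve is what a display
  plots and what crossing times are read from.
- **`δ_min` = 2 hue units** guards the degenerate σ = 0 baseline (a
  noise-free or heavily quantized series) from calling 1-unit flicker
  positive. With 8-bit-quantized hues and disc averaging, baseline σ is
  routinely near zero, so this floor is the operative threshold in clean
  data.
- **Strict inequality**: a value exactly at the threshold is negative.
- **Latching**: once crossed, a call is never rescinded; the per-frame call
  map is therefore non-decreasing, which is what a live array display
  shows.
- Empty wells are processed like samples (they image as flat background and
  call negative); a run configuration may mark wells ignored.

Streaming and batch processing are the same computation: the trailing
average depends only on past frames and baseline statistics freeze when the
window closes, so feeding frames one at a time (`RunProcessor.feed`) and
processing the complete list give bit-identical CSVs.

## Run-folder dialect

`params.txt` (key=value, echoing every run parameter and the layout),
`Image_1` … `Image_N` (JPEG or PNG; N = total/interval + 1 because the
t = 0 frame is captured — the baseline needs it), `raw_hue.csv` and
`averaged_hue.csv` (header `time_min,A1,…,H12`, values printed with 2
decimals so write→read→write is byte-identical), and `calls.csv`
(`well,status,crossing_time_min,threshold`). Raw CSV values are 8-bit hues
in [0, 255]; the averaged CSV stores the smoothed series on the unwrapped
scale (it may exceed 255 after a wrap-crossing transition). The calls CSV
is always recomputable from the raw CSV alone. Unknown params keys are
accepted with a warning.

## Synthetic runs

The generator produces what the analysis assumes and nothing more:

- **Trajectory**: per channel, `c(t) = negative + s(t)·(positive −
  negative)` with logistic `s(t) = 1/(1 + exp(−(t − t_amp)/τ))` for
  positives and `s ≡ 0` for negatives. The transition lives in RGB space,
  so PR's hue path traverses the red wrap naturally. τ defaults to 0.5 min
  — amplification-driven color flips are sharp (10–90% in ~2.2 min) — which
  also keeps threshold crossings within ~2 frames of the midpoint `t_amp`.
  Default transition midpoints fall uniformly in 30–75% of the run.
- **Noise**: independent Gaussian per channel (default sd 1.5 intensity
  units) applied both to well colors over time and to pixels at render
  time; everything is seeded and byte-reproducible.
- **Illumination**: a multiplicative linear gradient plus vignette.
  Being achromatic, it barely moves hue (< 3 units at the corners for
  default strengths) — which is itself a property of reading hue rather
  than intensity.
- **Rendering**: colored ROI discs on a matte off-white background.

What passing the synthetic suites does **not** show about real data: no
condensation, bubbles, tube-wall reflections or mix-in-cap failures are
modeled; lighting is stationary; endpoint colors are the profile constants
rather than reaction-dependent; and non-specific amplification — a true
color change without target — is indistinguishable from a positive by
design, in synthetic and real data alike.

## Thermal simulator

Three lumped compartments with first-order coupling: heated air chamber
(heater input, rate 20 °C/min, against loss to ambient, τ = 5 min), metal
plate (lag toward `ambient + (1 − k)(chamber − ambient)` with
`k = offset/(setpoint − ambient)`, τ = 6 min), and in-tube liquid (lag
toward the plate, τ = 10 s). The controller is bang-bang with a ±¼ °C
hysteresis band by default; with the band set to zero the heater modulates
and holds the setpoint exactly, which is the configuration whose steady
states match the closed-form fixed points to < 1e-6 °C. Folding plate heat
loss into the steady-state offset keeps the system linear (closed-form
fixed points, exact Euler fixed points) and gives the right two limits: at
setpoint the plate sits at `setpoint − offset` (77 → 68 °C by default),
with the heater off everything decays to ambient.

Defaults were calibrated to the qualitative behavior of a convectively
heated instrument: the plate passes 65 °C near 20 min, settles within
0.5 °C of its asymptote inside a 45-min pre-heat, an inserted tube reaches
65 °C within 30 s, and the settled tube band stays within ±1 °C. An
`open_port_coupling` coefficient shortens the effective plate time constant,
encoding the observation that unfilled sample ports vent hot air through
the plate. Explicit Euler with a `dt ≤ τ/20` guard is used throughout —
adequate for first-order dynamics. No spatial gradients, fan dynamics or
per-well temperature differences are modeled; simulator outputs are design
documentation and property-test substrate, not instrument predictions.

## Mock-study scoring

A sample is **correct** only when every probed marker (defaults: Vb/HBB
blood, Se/SEMG1 semen, Sa/HTN3 saliva, Vf/CYP2B7P vaginal fluid) matches
its expectation; per-marker false-positive/false-negative tallies are
reported alongside. Only probed markers are compared, and the marker set is
configurable (e.g. to add a menstrual-blood marker). The bundled 12-sample
table scores 6/12 concordant under this rule, with all semen errors being
false negatives and most other errors cross-reactive false positives.

## Problem sizes used in the test suite

Rendered-pipeline sweeps use 240×160–360×240 px plates and 6–15-minute
runs (96 wells throughout); the 50-seed recovery suite runs at noise sd 2,
the 200-replicate specificity check at the default sd 1.5 on the
trajectory→hue path. The exhaustive hue checks enumerate all 256³ RGB
triples and all 256² hue pairs. These sizes make every stochastic claim
exactly reproducible from fixed seeds.

## Known limitations

- Hue quantization to integers before baselining means σ is often an
  underestimate of the pre-quantization noise; the `δ_min` floor, not
  `k·σ`, is then the operative threshold.
- `refine_rois` assumes drift ≤ pitch/4 and a loaded plate; it cannot
  recover rotation or scale changes.
- The JPEG run-folder convention is supported but lossy; generated
  ground-truth fixtures default to PNG.
- Crossing time depends on the threshold height as well as the kinetics, so
  it is a relative, not absolute, measure of amplification onset.
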