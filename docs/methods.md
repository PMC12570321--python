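# Methods

## The measurement model

Ratiometric pH imaging estimates organelle pH from the ratio of a
pH-sensitive to a pH-independent fluorescence channel. Because both dyes
ride on the same dextran, probe amount, optical path and focus drop out
of the ratio; what remains is the probe's protonation response, modeled
throughout as a 4-parameter logistic in pH:

    S(pH) = bottom + (top − bottom) / (1 + 10^(slope·(pH − pKa)))

`slope > 0` means acid-bright (the ApHID convention: brighter with
acidity), `slope < 0` base-bright (fluorescein, Oregon Green). pKa is
the inflection — the fitted log IC50 of the titration. Fits are plain
least squares (Levenberg–Marquardt) on the individual replicate points,
not replicate means, so reported standard errors reflect well-to-well
scatter. Initialization is deterministic: bottom/top from the data
extremes, pKa from the point nearest mid-signal, slope sign from the
rank correlation of signal with pH. A fitted curve with `bottom > top`
is re-canonicalized by swapping asymptotes and negating the slope (the
two parameterizations describe the same curve). Convergence is the
optimizer's relative-change criterion at 1e-12 with a 10,000-evaluation
cap; non-convergence is reported, never silently accepted.

The default acid-bright probe model is `(bottom, top, pKa, slope) =
(0.02, 1.00, 5.4, 2.0)`. pKa 5.4 is the probe class this pipeline
targets; bottom and slope were solved jointly so that S(4.0)/S(6.0) ≈
12.8, the ~13-fold dynamic range such probes show between pH 4 and 6.
A Hill-type slope of 2 is what that fold-change forces once pKa is
fixed at 5.4 — a slope of 1 cannot produce a 13-fold change over a
2-unit window centered 0.6 units off the midpoint.

## Calibration

Two constructions map measured ratios to pH.

*Full*: fit the logistic directly to fixed-cell ratios measured across a
buffer series (pH 4.0–6.0 in 0.5 steps, membrane-permeant equilibrators
assumed to have equilibrated the compartments to buffer pH). Its valid
pH range is the span of the input buffers.

*Anchored*: measure the fixed-cell ratio at pH 5.0 only, then scale a
solution ratio titration of the same probe pair through that anchor:
generated ratio at pH p = anchor · R_sol(p)/R_sol(5.0), evaluated on a
0.1-pH grid over 3.5–7.4 and refit. Scaling a logistic by a positive
constant scales only bottom and top, so when the solution input is
already a fitted curve the scaling is applied analytically — the refit
of exactly-scaled points converges to the same parameters, and the
analytic route makes the anchor-passing invariant exact rather than
optimizer-limited. The anchored shortcut is valid exactly when the
cellular response equals the solution response up to scale; the package
tests that equivalence on simulation rather than assuming it.

Inversion is closed-form: pH = pKa + (1/slope)·log10((top−r)/(r−bottom)).
Ratios within a guard band of either asymptote (default 1% of
top−bottom) are returned as non-interpolatable flags carrying the side;
with the default probe this makes roughly pH < 4.4 and > 6.4
unreportable, which is a statement about the probe's usable window, not
a defect. Interpolations landing outside the calibration's pH range are
returned but flagged extrapolated. Flags are data, not exceptions.

## Image pipeline

Per plane and channel, the 5th-percentile pixel value is subtracted and
negatives are clipped; subtracted values are logged. Per-field mode sum-
projects the corrected stack, thresholds the pH-independent channel
(Otsu by default — the threshold actually used is always recorded, since
fixed thresholds are the least reproducible part of published pipelines)
and takes Σ(pH-dep)/Σ(pH-indep) over the mask. Per-object mode runs
plane by plane: one pooled threshold is computed from the whole
corrected reference stack (per-plane Otsu misbehaves on organelle-free
planes, where it splits the background histogram), connected components
are flooded from brightest pixel down, and two local maxima become
separate objects when the saddle between them is ≤ 50% of the lower
peak. The 50%-separation convention of common morphometry software
admits two readings — a valley-depth (saddle) criterion and a literal
peak-height-ratio criterion; the saddle reading matches the intent of
separating adjacent Gaussian-shaped puncta and is the default, with
the peak-ratio reading available as `split_rule="peak_ratio"`.
The flooding implementation computes saddles exactly (it is the minimax
saddle of descending-order union-find), and the test suite checks it
against an independent brute-force threshold-enumeration oracle.

Object morphometry uses area (pixel count · pixel_size²) and outer
radius (max centroid-to-pixel distance). Filters default to 10–1500
area units and 0–1000 radius units. On real microscope data these are
calibrated units (µm², µm) derived from the pixel size; for the default
synthetic grid (0.2 µm/px) the pipeline uses pixel units, where a
10 px² minimum discards single-pixel noise exactly as the filter
intends — at 0.2 µm/px a 10 µm² minimum would discard every real-sized
organelle, so the unit system is an explicit config choice, never
implicit. Objects spanning several planes are not merged or
deduplicated in 3-D; quantification is strictly per plane.

Ratio images threshold on the reference channel, smooth both channels
with a 7×7 Gaussian (σ = 7/6 px, kernel truncated to exactly 7×7), clip
the pixel ratio to a display range and map it through a fixed 256-entry
blue→green→red LUT (v1); blue is the least acidic end. Photobleach
series normalize per-cycle integrated field intensity to cycle 1
(F/F₀); "fraction lost" is 1 − final F/F₀. Nuclei counting estimates
local background by grey opening with a footprint 1.5× the maximum
nucleus width, thresholds the excess, and counts components whose
equivalent diameter falls in the configured 5–30 µm window.

## Synthetic data: what it emulates, and what it does not

Each simulated field renders punctate organelles as isotropic 3-D
Gaussians (σ = radius/2) rather than hard spheres: sub-resolution
puncta look Gaussian after the PSF anyway, and the choice keeps every
integral closed-form for oracle tests. The pH-independent channel
carries each organelle's load (lognormal, µ=9.9, σ=0.4 in log-space —
median ≈ 2×10⁴ a.u. integrated, peak SNR ≈ 50 at the default noise);
the pH-dependent channel shares the geometry with amplitude multiplied
by S(pH)/reference_response, so load cancels exactly in the noiseless
ratio — the invariant the channel-construction tests pin down.

Defaults, chosen once as ordinary confocal conditions and then left
alone: 5 planes of 256×256 at 0.2 µm/px and 1.5 µm z-spacing; 50
organelles per field with radius N(0.5, 0.1) µm and true pH N(5.1, 0.2)
truncated to [3.0, 7.5]; background 100 a.u. with a 20 a.u. linear
flat-field gradient (~20% nonuniformity, typical of a confocal field of
view, and enough for the percentile correction to have something to
remove); lateral PSF σ 0.2 µm and axial PSF σ 0.6 µm (confocal axial
resolution is ~3× worse than lateral; an isotropic PSF would make
organelles centered between planes vanish entirely); Poisson noise at 1
photon per a.u. and Gaussian read noise σ 5. Values are clipped to the
unsigned 16-bit range in memory and rounded to uint16 only at TIFF
write time, with clipped-pixel counts logged. All randomness flows from
one seeded generator; the noise stream is derived from the seed
independently of the geometry draws so a treated (pH-shifted) field
re-renders with identical geometry and noise.

What the generator does *not* emulate — and therefore what passing
tests do not establish about real data: no cell bodies or structured
autofluorescence, no spectral bleed-through between channels, no focus
drift or stage motion, no diffraction PSF beyond a Gaussian, no
organelle motion between channels, and no probe-delivery biology
(recovery results say the *quantification* is faithful given the image
model, not that dextran loading is unbiased).

Two consequences of the model worth knowing. First, with 1.5 µm plane
spacing and ~0.65 µm effective axial σ, organelles centered between
planes are dim in both adjacent planes; per-plane detection typically
recovers ~20 of 50 organelles per field — realistic z-undersampling,
not a bug, and ratios of detected objects are unbiased because load
cancels. Second, the per-field ratio is load-weighted and sits on a
convex region of the response curve, so the field-level pH carries a
small (~+0.05) alkaline bias relative to the unweighted true mean pH at
these conditions, with field-to-field scatter of ~0.03; the per-object
median is free of this bias (median |error| ~0.01) and is the readout
used for shift detection. At the defaults, a simulated +0.4 pH
methylamine-like alkalinization is detected as ~+0.38.

## Numerical and degenerate-input choices

Truncated-normal pH draws use rejection sampling (exact truncation).
Fits reject constant signals and grids with fewer than 4 distinct pH
values as degenerate input. Empty masks propagate as flagged undefined
field results, not exceptions. An organelle count of zero yields a
valid background-only field. Segmentation ties (equal-valued pixels)
break deterministically by pixel index in the descending flood, so
outputs are bit-reproducible. Blank subtraction matches buffers to the
nearest blank pH within 0.05 and errors, listing the offending pH
values, when no blank is close enough. CSV floats are written at 9
significant digits; every results file carries a JSON sidecar with the
parameters, thresholds, seeds and package version that produced it.

## Known limitations

* The anchored calibration inherits any real divergence between
  cellular and solution responses (e.g. protein-induced quenching);
  only the equal-response case is verifiable here.
* Per-plane object records double-count organelles that are bright in
  two planes; downstream statistics treating records as independent
  organelles will overweight in-focus compartments.
* The field-level pH estimator's load-weighting bias (above) is
  inherent to the ratio-of-sums definition, not removable by
  calibration at a single anchor pH.
* Nuclei counting assumes roughly convex nuclei sparse enough for grey
  opening to see background between them; confluent monolayers will
  undercount.
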