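# Methods

This note documents the models, parameter choices and numerical devices
behind `ferncover`, and what the synthetic-data validation does and does not
establish about real imagery.

## Experimental design

The replacement series holds total density fixed at 20 spores per well and
varies composition: monocultures (20:0), asymmetric mixtures (15:5, counted
once per ordered species pair, since "15 of X with 5 of Y" and the reverse
are different treatments) and symmetric mixtures (10:10, unordered). Three
species therefore give 3 + 6 + 3 = 12 combinations, exactly filling a 3×4
well plate. Across plates the layout satisfies a Latin-rectangle-style
constraint — no combination repeats a well position — built by randomized
greedy matching with restarts; this is feasible up to 12 plates and any
satisfying layout is accepted (the constraint, not a particular layout, is
the contract). The number of plate-boundary edges a well touches (0, 1 or 2)
is carried along as a nuisance covariate for edge effects; on a 3×4 plate
the distribution is exactly {2: 4, 1: 6, 0: 2}.

Spores are placed by rejection sampling, uniform in the central half of the
11-mm well radius, with a minimum pairwise spacing of 0.8 mm (default; the
half-radius rule avoids the agar meniscus, and the spacing default gives
"random but even" scatter while leaving room for 20 gametophytes at week 5).

## Growth model (invented, calibrated to qualitative patterns)

No quantitative growth-curve parameters exist for this system, so the
generator uses a discrete logistic recursion with two competition channels
(see `synthgen.py`): a density-based interference factor
`g_i = exp(-θ·L_i)` acting on the growth rate from the start (`L_i` = mean
competition weight over the 19 neighbours; this is what makes composition
matter by week 5, when areas are still far below carrying capacity), and
area-based logistic saturation `1 − C_s/K_s` that caps growth by week 10.

Defaults (per week, mm²): growth rates r = 1.7/1.9/2.2, germination areas
a₀ = 0.004/0.0055/0.007 and carrying capacities K = 120/160/220 for species
A/B/F; θ = 0.4; competition matrix rows α[A] = (1, 1.2, 1.6),
α[B] = (0.8, 1, 1.3), α[F] = (0.5, 0.7, 1). These were chosen once so that
the simulation reproduces the qualitative regularities of the study system —
monoculture cover ranking F > B > A, the strongest competitor overyielding
when sown rare, the weakest underyielding under competition, and week-4–10
well totals in the 0.3–210 mm² range — and are *not* fits to any measured
growth curve. A perpendicularity factor (1.0 through week 5, declining
linearly to 0.7 at week 10) models upright growth reducing the area visible
from above; it is shared across species within a week, encoding the
assumption that wells are comparable within an observation date.

## Rendering and the synthetic scene

Gametophytes are drawn as star-convex polygons (three random radial
harmonics) smoothed by morphological closing, then trimmed or grown
pixel-by-pixel so each ground-truth mask contains exactly its target pixel
count — measurement error in round-trip tests is therefore attributable to
the classification step alone. Masks are disjoint (contested pixels go to
the earlier-drawn blob).

Coloration is sampled in HSV inside species-specific green-yellow hue bands
(A 70–80°, B 78–88°, F 86–96°), with saturation co-varied against hue so
that, *after* the standard +10° yellow-band shift, every tissue pixel
carries a green-channel excess of ≈ 42.3 ± 3 8-bit counts. That constant is
deliberate: the default classification threshold (`min_excess` 20) then sits
exactly midway between tissue and the hue-shifted agar background (≈ −2.3),
which makes mean-pooled boundary blocks at 2× downsampling unbiased coin
flips rather than a systematic over- or under-count. Residual round-trip
error is therefore a boundary-variance effect that shrinks with raster
scale: ≈ 1% at 900 px/mm² and < 0.5% at the study scale of 2190 px/mm² for
whole-well totals.

What the synthetic scene does **not** emulate: uneven illumination, optical
distortion, agar meniscus shading, algal contamination (a speckle rate
exists but defaults to 0 — the default scene guarantees zero background
false positives by construction), gametophyte translucency and shade
variation, and real lobed morphology beyond star-convexity. Passing
round-trip tests therefore validates the *computational* chain (shift →
classify → calibrate → attribute), not the robustness of any particular
threshold on real photographs; thresholds must be re-calibrated per imaging
setup, as the workflow itself prescribes.

## Measurement chain

Hue shifting uses the 0–360° hexagon convention on the standard HSV
transform; only pixels with hue inside the band (default \[30°, 90°\]) and
nonzero saturation are touched, and untouched pixels are copied verbatim. A
cosine falloff at the band edges is available but off by default (the hard
window is the plainest reading of a named hue range).

"Processing speed = 2" is implemented as 2× linear block-mean downsampling
before classification — the one interpretation that changes the number of
pixels analyzed — so counts are in downsampled pixels and the calibration
squares must be processed at the same factor. The JPEG processing dialect
(quality 95) is applied before classification when enabled; chroma
subsampling is disabled because color thresholding immediately follows.
Calibration divides the mean red-pixel count of reference squares by their
known area (ten 100-mm² squares at study scale give the constant
2190 px/mm²); rendered squares are laid out aligned to the pooling grid so
the calibration round-trip is exact to the pixel.

The classifier itself (target channel ≥ each other channel + `min_excess`,
and ≥ `min_value`) is this package's own re-implementation of
channel-dominance green/red detection; the upstream tools' exact rules are
not published, and no attempt is made to guess their thresholds.

## Attribution

Species identity at week 5 comes from the sowing-image pair: spots present
in both images are the first-sown species, spots only in the second image
the second. Spot detection thresholds luminance at 50 counts below the image
median (the agar dominates the frame, making the median a robust background
level) and keeps components of ≥ 3 px; matching is nearest-neighbour within
0.4 mm. The tolerance radius is this package's device — how identification
survived spore drift in the original workflow is not documented — and any
unmatched first-image spot flags the well for exclusion rather than being
guessed. Deletion replaces one species' pixels with the background color;
in pipeline mode the deletion masks are the ground-truth masks (emulating
careful manual deletion), and user-supplied masks can be substituted for
real data. The subtraction rule conserves pixels exactly by construction;
an altered count exceeding the total signals mismatched settings between
the two measurement passes and is an error, never silently clipped.

## Statistics

**Ratios.** Theoretical area = well total × n_species/20 (the explicit
formula; monoculture ratios are then exactly 1). A documented alternative —
predicting each species' expected cover from the mean per-spore area of its
monoculture wells — is available as `method="monoculture-mean"`; the two
readings conflict in the source material and the explicit formula is primary
here. Standardization divides each species' ratios by the species' mean
over *mixture* wells only; the mixture mean is exactly 1 afterwards, and
monoculture rows are divided by the same constant. Wells that lost spores
at sowing are removed before modeling (the generator's default loss pattern,
17 spores across 5 of 120 wells, reproduces the "approximately 4%"
exclusion rate).

**Gamma GLMM.** Cover is strictly positive with variance growing with the
mean, hence a gamma family with log link and a per-plate random intercept.
No installed Python library fits this model, so it is fitted here by maximum
marginal likelihood: the likelihood factorizes over plates, each plate's
integral over its scalar intercept is strictly log-concave, and adaptive
Gauss–Hermite quadrature (15 nodes around the per-plate posterior mode,
found by Newton) evaluates it to near machine precision. Fixed effects, the
log shape and the log random-intercept SD are optimized by L-BFGS-B with box
bounds (log ν ∈ \[−3, 9\], log σ ∈ \[−8, 3\]) that keep the quadrature
conditioned; `fix_sigma=0` collapses the model to a plain gamma GLM (the
estimates then agree with `statsmodels` GLM to < 1e-6). On a shared fixture
the fit matches `glmmTMB` (Laplace ML) to 3–4 decimals in coefficients,
random-effect SD and log-likelihood. Model sequences are compared by
sequential (type-I) likelihood-ratio tests: terms enter in the declared
order, each χ² is twice the log-likelihood gain over the previous model and
its df the number of added columns, with interactions entered last. Warm
starts from the previous model are used, with a cold-start retry whenever a
nested fit fails to reach its predecessor's likelihood. Null simulations
(120 wells, 10 plates) put the 5% rejection rate of the 2-df species term at
its nominal level, and a log-scale effect of 0.5 is recovered with |bias|
well under 0.1.

**Week-5 LMM.** Standardized ratios are analyzed per species, mixtures
only (monoculture ratios are identically 1 and would be circular), with the
categorical spore count {5, 10, 15} as predictor — competitor identities
are pooled within a count — and the plate as random intercept, via
`statsmodels` `MixedLM` refitted by ML for valid likelihood ratios.
Pairwise contrasts on the estimated marginal means (groups weighted
equally) are adjusted by the studentized-range (Tukey) method with
residual-based degrees of freedom n − k − 1; with two groups this reduces
exactly to the unadjusted t-test, as it should.

**Method comparison.** The pixel chain can be compared against a
polygon-outline oracle (marching-squares contours of each connected
component, shoelace area), mirroring how a manual-outline tool would
measure the same wells; `compare_measurers` reports the per-well ratio of
estimates and its min/mean/max.

## Numerical and scale choices

Test fixtures render at 900 px/mm² and validation of the deletion
round-trip at the study scale of 2190 px/mm²; these sizes make the 2%
round-trip tolerances a ≥ 3σ margin over the boundary-block variance while
keeping the suite quick. The null-calibration simulation uses 500
replicates, effect recovery 200, the LMM size/power checks 200, and the
qualitative-pattern check 40 seeds. Degenerate inputs are handled
explicitly: zero-saturation pixels are never hue-shifted, empty masks are
identities, a zero-red reference image is an error, all-deficient well
tables warn and return empty, and non-positive responses are rejected by
the GLMM rather than transformed.

## Known limitations

The growth and appearance models are stand-ins: their defaults encode the
intended qualitative biology, not measured parameters, so quantitative
outputs of the simulation (χ² values, ratio magnitudes) are
seed-and-parameter-dependent and should not be read as predictions for any
real data set. The GLMM assumes a single scalar random intercept; crossed
or nested random effects are out of scope. Attribution is only defined
through week 5 — once gametophytes physically overlap, deletion
differencing no longer isolates species areas — and multi-shade density
weighting of green pixels is deliberately not implemented.
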