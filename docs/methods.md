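# Methods

## Image model and pipeline

The pipeline assumes grayscale photomicrographs of dark vessels on a bright
background, with a user-supplied calibration in µm per pixel. All
intensities are normalized by the dtype maximum (255 or 65535) rather than
the per-image maximum, so absolute contrast remains comparable between
treatment and control images; RGB input is collapsed to Rec.709 luminance.

**Anisotropic diffusion.** The explicit Perona–Malik scheme on the
4-neighbourhood with exponential conductance `g(∇) = exp(−(∇/κ)²)` and
reflective (zero-flux) boundaries. Defaults: 10 iterations, κ = 0.1 on the
[0, 1] intensity scale, time step 0.25 (the stability limit of the 2-D
explicit scheme; larger steps oscillate). κ sits well below the
vessel/background contrast of typical CAM images (≈ 0.5) and well above
sensor noise (≈ 0.02), so noise diffuses away while vessel edges are
essentially frozen. Zero-flux borders make the update conservative: the
image mean is preserved to floating-point accuracy, and the scheme obeys the
discrete maximum principle.

**Despeckle.** A fixed 3×3 median with reflective borders — the canonical
despeckle. The window is deliberately not configurable so results are
bit-comparable across runs. Note one side effect relevant to dense
capillary beds: a 1-pixel background gap between two vessels has a majority
of vessel pixels in its window and is bridged. At adequate sampling
(capillary diameter ≳ 10 px) such gaps are rare; see "Sampling" below.

**Bernsen segmentation.** Per pixel, over a disk of radius `r` px:
`T = (max + min)/2`; the pixel is vessel if the window contrast
`max − min` reaches `contrast_min` **and** the intensity lies below `T`
(an `invert` flag handles bright-on-dark material). Low-contrast windows
are background: the mid-range is meaningless in flat regions and would
binarize pure noise — the conservative choice, since over-sensitive
segmentation is the known failure mode of this assay. Library defaults are
`r = 15 px`, `contrast_min = 0.06` (about 3× the default sensor noise).
**Choosing `r`:** the window must extend past the half-width of the widest
vessel present; a window that fits entirely inside a vessel sees zero
contrast and hollows the vessel out. The batch-pipeline default is
`r = 25 px` at 1 µm/px, matching the ~40 µm feeder vessels of the synthetic
scenes. Foreground is encoded as label 1 (the "black pixels" of the
original assay vocabulary).

**Thin-capillary isolation.** Vessels wider than `d_max` (default 15 µm)
are removed by building a "wide" copy — morphological opening with a disk
of radius `⌈(d_max/2)/pixel size⌉` px — and subtracting it from the mask.
The ceiling errs toward removing borderline vessels. During erosion,
out-of-frame pixels count as foreground so that vessels crossing the field
of view are removed in full instead of leaving end caps at the border.
Two systematic effects follow from the operator itself: (i) the dilation
that rebuilds wide vessels overshoots by up to one disk radius *along*
attached capillaries, shadowing their first few pixels at each junction;
(ii) where two capillaries overlap or run flush, their union is locally
wider than `d_max` and is (correctly, by the rule) removed. Together these
bias the measured thin area low by roughly 5–15% on dense synthetic beds;
the bias is shared by treatment and control images and largely cancels in
%-of-control comparisons.

**Skeleton analysis.** Zhang–Suen thinning; each skeleton pixel is
classified by its 8-neighbour count — fewer than two: endpoint, exactly
two: mid-vessel, more than two: junction. The three classes partition the
skeleton exactly. 8-connectivity is required for diagonal skeleton steps to
read as continuous vessels; a consequence is that a single anatomical
bifurcation can rasterize to two or more adjacent junction pixels (and a
perfect 4-arm cross to five), so the package additionally reports
*junction clusters* (8-connected components of junction pixels), which is
the quantity comparable to a count of branch points. Branch segments are
the 8-connected components remaining after junction pixels are deleted;
mean branch length assigns one pixel size per non-junction skeleton pixel
(diagonal steps are not √2-weighted — a declared simplification).
"Fraction of endpoints/junctions/mid" are the class counts divided by
total skeleton pixels. All per-image metrics can be normalized as percent
of the control-group mean.

## Dose–response and synergy

The four-parameter logistic `r(d) = bottom + (top − bottom)/(1 + (d/IC50)^h)`
is fitted by least squares on the log-dose axis with the IC50 parameterized
as `log10 IC50` (this makes the fit scale-equivariant: scaling all doses by
c scales the fitted IC50 by c). Initialisation from the data (top = max,
bottom = min, IC50 = geometric-mean dose, h = 1) with a deterministic
three-point multi-start on the IC50 guess (×0.3, ×1, ×3); the lowest
residual sum of squares wins. The fit is canonicalised to `bottom ≤ top`,
the slope sign then encoding direction, and a flag marks IC50 estimates
falling outside the tested dose range. Constant responses raise a
"no transition detected" error; at least four distinct doses are required.

Inhibition is defined as `100 · (1 − treated/mean(control))`, mapping both
assay polarities (remaining vascular area in vivo, wound closure in vitro)
onto one scale where larger means stronger inhibition. The literature on
this assay states the synergy criterion once per polarity — "above 50%"
for inhibition values and "below 50%" for remaining-area values — which are
the same rule; the single internal convention avoids sign errors.

In the fixed-ratio design each drug is dosed at a fraction of its own IC50
with the fractions summing to one, so the mixture always totals one
IC50-equivalent. Loewe additivity therefore predicts 50% inhibition at
every ratio — `additive_null` returns the constant 50 and exists as an
explicit function to make the null auditable. Verdicts use a margin rule:
observed − 50 beyond ±`tolerance_pct` (default 5 points) is called
synergistic/antagonistic, otherwise additive. The margin substitutes for
replicate-level t-tests when only per-ratio means are available, and is
exposed on the API and CLI.

## Synthetic data generator

**What it emulates.** Dark vessels of two calibres on a bright background:
root (feeder) vessels of 40 µm entering the field from its edges, halving
in width at each bifurcation down to a 10 µm capillary floor, so the 15 µm
cutoff falls between generations. Branches grow as seeded random walks
(20 µm steps, 0.12 rad/step heading jitter, 15% per-step bifurcation
probability up to depth 4) and end at the field boundary or after 300 µm
without branching — blind-ended sprouts, as in a growing capillary bed.
Rendering paints each segment as a capsule of its width into a
600 × 900 µm field, then applies a linear left-to-right illumination ramp
(amplitude 0.1 about a 0.8 background), multiplicative vessel darkening
(0.6), additive Gaussian sensor noise (σ = 0.02) and salt speckle
(density 0.002) — the illumination and impulse-noise artefacts the
segmentation and despeckle stages are designed to absorb. All stages are
bit-reproducible for a fixed seed.

**Ground truth.** The renderer returns the exact vessel raster, the
thin-vessel raster and the list of branch points. The thin raster is
*occlusion-aware*: capillary pixels lying underneath a feeder vessel are
not visible in the image and are excluded, since no image-based method
could measure them.

**Sampling.** The default 1 µm/px resolves the 10 µm capillary floor at
~10 px per diameter. Coarser sampling (≥ 2 µm/px here) aliases
inter-capillary gaps to single pixels, which the median despeckle bridges;
the merged blobs then exceed the diameter cutoff and are removed, biasing
the thin-area readout. Pixel sizes larger than the capillary width trigger
an explicit warning.

**What it does not emulate.** No biophysics (no VEGF gradients, no drug
mechanism), no anastomosis into closed loops, no vessel texture or
red-channel colour information, no out-of-focus blur, and edges are hard
(no partial-volume anti-aliasing). Passing round-trip tests therefore
demonstrates correctness of the measurement chain on geometrically
realistic scenes, not performance on real photomicrographs.

## Numerical choices and degenerate inputs

- Diffusion step capped at 0.25 (explicit-scheme stability); clamping to
  [0, 1] only acts on last-ulp drift.
- Bernsen, median and min/max filters use reflective borders throughout,
  matching their brute-force test oracles exactly.
- The diameter filter rejects cutoffs below one pixel (the disk would be
  empty); empty masks pass through every morphometric operation and yield
  zero-valued statistics rather than errors.
- Skeleton statistics on an empty skeleton return zeros with
  `mean_branch_length_um = 0`.
- Control normalization refuses empty control groups and zero control
  means.
- Problem sizes in the test suite (600 × 900 px renders for round-trip
  checks, 300 × 300 µm fields for the 100-seed sweep, 200 seeded
  simulations for noisy IC50 recovery) were chosen as the smallest scenes
  that still exercise both vessel calibres and dense branching.

## Known limitations

- The thin-area readout carries the junction-shadow bias described above;
  absolute areas are systematically a few percent low, while
  %-of-control contrasts are much less affected.
- Branch lengths ignore the √2 weight of diagonal steps and so
  underestimate the length of oblique vessels by up to ~30%; comparisons
  between groups with similar orientation statistics are unaffected.
- The synergy margin rule is not a significance test; with replicate-level
  data a t-test against 50% is the stronger analysis.
- Bernsen's window radius must be chosen against the widest vessel in the
  scene; there is no automatic scale selection.
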