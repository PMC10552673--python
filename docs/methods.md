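# Methods

## What is quantified

Dystrophic skeletal muscle shows four histopathological hallmarks that
this package quantifies from stained cross-sections:

1. **Membrane damage** — fibers that have taken up a membrane-impermeant
   dye (Evans Blue Dye) are counted and expressed as a percentage of all
   fibers (`ebd` assay).
2. **Regeneration** — fibers re-expressing embryonic myosin heavy chain
   (eMyHC) are counted, expressed as a percentage of all fibers, and
   their per-fiber pixel areas reported for a size distribution
   (`emyhc` assay).
3. **Inflammation** — CD68+ macrophages aggregate in necrotic regions
   and cannot be counted individually, so the fraction of the image area
   they cover is reported (`cd68` assay).
4. **Fibrosis** — collagen in a Picrosirius-red brightfield stain,
   likewise reported as percent of image area (`collagen` assay).

All sizes and diameters are in pixels; no physical pixel pitch is
assumed, so µm² conversion is left to the user. All intensities are
processed in floating point on [0, 1]. Percent-area denominators are the
**full image frame**, not a tissue mask — a tissue-restricted denominator
would change the numbers and is deliberately not applied.

## Thresholding

Two global threshold selectors are implemented.

**Robust background** (`mean + N·SD`): sort all intensities, discard the
dimmest `trim_low` and brightest `trim_high` fractions (5% each by
default — the upper trim is what removes the foreground), then take
mean μ and *population* standard deviation σ of the retained pixels and
return μ + Nσ. N defaults to 2; raising it makes the threshold more
stringent. The trim counts are `floor(fraction · n)` per side. Population
rather than sample SD is a documented reproducibility choice; with 90%
of pixels retained the difference is negligible.

**Minimum cross-entropy** (Li's criterion family): candidate thresholds
are the 256 left bin edges k/256 of a 256-bin histogram of [0, 1]. For
each candidate t, pixels split into background (x < t) and foreground
(x ≥ t) with class means μ₀, μ₁, and

    η(t) = − Σ_bg x·log μ₀ − Σ_fg x·log μ₁

is minimised by exhaustive search (ties → smallest t; candidates with an
empty class are skipped; an all-equal image returns its own value). The
search is exhaustive rather than iterative because 256 evaluations are
cheap and exactness makes the selector testable against a brute-force
re-derivation. Note the objective is flat across an empty gap between
two intensity modes: any threshold in the gap induces the same
partition, and this implementation returns the gap's left edge.

**Bounds.** Both selectors clamp their result to
`[lower_bound, upper_bound]`. This is the first knob to adjust when
automatic selection fails on an atypical image (e.g. a frame dominated
by foreground, where a background-plus-2σ estimate exceeds every pixel).
The shipped per-assay defaults place the bounds between the relevant
stain levels:

- fiber passes (inverted laminin, and the squared dye-masking image):
  [0.5, 0.7] — between the dark wall/masked level (≈0.35) and bright
  interiors (≈0.93);
- eMyHC marker pass: [0.3, 0.6];
- CD68: [0.4, 0.9] and collagen: [0.575, 0.9] — the lower bound sits at
  the half-maximum midpoint between background and marker levels, so a
  symmetric optical blur moves the recovered boundary onto the true
  object edge and the measured area is unbiased to first order.

Foreground is closed on the bright side (pixel ≥ t is foreground). An
optional Gaussian blur (`pre_apply_sigma`, default off) may smooth the
image before the threshold is *applied*, never before it is selected.

## Object identification

`identify_primary_objects` runs: threshold → fill holes → declump →
size-filter → (optional) drop border-touching objects → relabel 1..k.

Declumping is shape-based: Euclidean distance transform of the
foreground, Gaussian-smoothed with `smoothing_sigma`, local maxima at
least `min_seed_distance` apart as watershed seeds (found per connected
component, so every component keeps at least one seed), watershed of the
negated smoothed distance map within the foreground. Ridge pixels are
assigned to basins, so foreground area is conserved, and declumping can
only split components, never merge them. Over-segmentation is corrected
by raising `smoothing_sigma` (and seed spacing); under-segmentation by
lowering them. `"auto"` resolves sigma to `min_diameter/4` and seed
distance to `min_diameter/2` — sensible for compact objects near
`min_diameter`, but the fiber-pass defaults override them (σ = 8,
spacing 40) because muscle fibers span 30–80 px and are already
separated by their laminin walls: within-fiber distance-map maxima must
be suppressed while the wall network, not the watershed, provides the
separation. Size filtering uses the area-equivalent diameter
2·√(area/π), inclusive on both ends. Border-touching objects are counted
by default (edge-clipped fibers are real fibers). Hole filling precedes
declumping so the distance transform reflects whole-fiber geometry; it
is disabled in the collagen defaults because the collagen network
encircles fibers and filling would swallow them.

## The four pipelines

**ebd.** Damaged fibers have ill-defined borders and resist direct
segmentation, so the pipeline counts their complement: (1) invert the
image; (2) combine the dye and laminin channels into one grayscale
(equal-weight mean, so the result stays in [0, 1]); (3) square the
pixels — after inversion, dye-positive interiors and walls sit mid-gray
and squaring pushes them toward black while dye-negative interiors stay
near 1, masking the positives out; (4) identify the remaining
(dye-negative) fibers; (5) identify *all* fibers on the inverted laminin
channel with the same parameters, so the subtraction compares like with
like; (6) dye-positive count = total − dye-negative, floored at 0 with a
recorded warning if the two passes disagree (the counts come from
independent segmentations and can cross); percentage over the total.
The squaring exponent is configurable (default 2); larger masks harder.

**emyhc.** Total fibers from the inverted laminin channel; positives
segmented directly on the un-inverted marker channel (regenerating
fibers are bright, well-defined objects); their areas are the reported
size list.

**cd68 / collagen.** Marker plane (collagen: inverted green plane of the
brightfield image, where collagen is darkest) → minimum-cross-entropy
identification → binary mask → foreground / total pixels. Counts are
deliberately not reported. Declumping is off (object identity is
irrelevant to area) and the collagen diameter filter's finite maximum
(400 px default) rejects frame-scale artifacts such as a uniformly
thresholded blank frame, while a ~10%-coverage collagen network
(equivalent diameter ≈ 365 px at 512²) passes. The CD68 maximum is
effectively unbounded because merged aggregates are legitimately large.

Channel roles are explicit configuration because staining conventions
differ between assays (dye assay: laminin green / dye red; eMyHC and
CD68: laminin red / marker green). Pipelines contain no randomness:
identical input and configuration give byte-identical CSV output.

## Synthetic scenes

The generator emulates the geometry the pipelines exploit, with exact
ground truth:

- **Fibers**: Voronoi regions of lattice points jittered by ±0.35 of the
  lattice spacing — polygonal, size-varying packing like a real
  cross-section. Interiors are the regions eroded by `boundary_width`
  (default 3 px) from the inter-region boundary (never from the frame
  edge); the complement is the laminin wall network, rendered at 0.8
  over 0.05 interiors.
- **Markers**: ⌈fraction·n⌉ fibers are flagged positive (optionally
  biased toward the smallest quartile, mirroring the observation that
  regenerating fibers are small); their interiors render at 0.7–0.9 over
  a 0.02 background. Macrophage aggregates are unions of three jittered
  disks per aggregate. Collagen grows ring by ring from the wall-core
  line, restricted to the interstitium, until the target coverage is met
  to ±0.5% of the frame (the last ring is subsampled).
- **Imaging**: per-channel Gaussian blur (default σ 1) then additive
  Gaussian noise (default σ 0.01), clipped to [0, 1].

Everything derives from one explicit seed (separate streams for
geometry and rendering); no global random state is touched.

Default conditions used by the tests and the acceptance script: 512×512
frames; 100 fibers (≈58 px mean diameter) for the dye and CD68 assays;
50 fibers at 14% positive for eMyHC; 16 aggregates of radius 13
(≈3.2–3.6% coverage) for CD68; 40 fibers with 10% collagen (denser
packings leave less than 10% interstitium, which would make that target
unreachable by construction).

**What the scenes do not model** — and hence what passing tests do not
show about real micrographs: broken or weak laminin walls (the case
declumping exists for), tissue folds and tears, out-of-focus regions,
uneven illumination, autofluorescence background, nuclei, and real
pixel-size calibration. Recovery on these scenes demonstrates the
pipeline logic is correct, not that the default thresholds transfer to
any particular microscope; the bounds-tuning workflow exists precisely
because real datasets need per-dataset adjustment.

## Numerical and degenerate-input choices

- 8-connectivity everywhere for component labeling and watershed.
- An image that thresholds to empty foreground is a valid zero-object
  result, not an error; a blank frame whose inversion is all-bright
  yields one frame-sized object that the diameter filter removes.
- Count subtraction clamps at zero with an explicit warning rather than
  reporting a negative count.
- The t-test helper is the classical equal-variance Student form; with
  zero pooled variance it returns t = 0, p = 1 for equal means and
  t = ±∞, p = 0 otherwise.
- CSV numeric fields are written in plain decimal (no exponent
  notation); TIFF output is 16-bit (round-trip error ≤ 1/65535), PNG
  output 8-bit.

## Known limitations

- Robust-background thresholding assumes background-dominated images;
  on fully tessellated tissue the clamp bounds do the work. This mirrors
  practice (bounds tuning) but means the defaults are calibrated to the
  synthetic stain levels.
- The watershed seed spacing that keeps large irregular fibers whole
  (40 px) will under-split genuinely touching objects closer than that;
  tune per dataset.
- No secondary-object propagation, intensity-based declumping,
  per-object intensity statistics, or whole-slide formats.
- Aggregation across images/animals (per-image vs pooled percentages) is
  left to the user; the package reports per-image values only.
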