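# Methods

This note documents the algorithms, parameter defaults and numerical
choices in `colonygrid`, and what the synthetic-data generator does and does
not emulate.

## Image model and geometric processing

Plate scans are treated as 8-bit grayscale rasters (recommended ≥300 dpi).
Color inputs are averaged to gray on load. Rows are addressed 1-based
top-to-bottom, columns 1-based left-to-right; position A1 = (1, 1) is the
image's top-left grid position.

**Multi-plate splitting.** Composite scans must have an essentially black
background between plates (gray ≤ 20/255). Plates are found as bright
connected regions larger than 1/8 of a tile of the declared arrangement and
returned in reading order; any other detected count is an error, because a
mis-split would silently shift every downstream plate identity.

**Rotation estimation.** Colony centroids come from the same thresholding
and connected-component analysis used for measurement. Nine 3×3 squares of
adjacent centroids, anchored on the colony nearest each of nine symmetric
patch positions, provide six angle measurements each (two diagonals, ideal
45°/135°; two vertical and two horizontal outer edges, ideal 90°/0°; the
middle row/column add no independent orientation information). Each
measured angle is mapped to its nearest ideal modulo 180° and the signed
deviations are averaged per square and then across squares. Squares whose
nine points do not form a consistent grid block (spacing spread > 50%, or
any deviation > 12°) are skipped; fewer than 3 usable squares is an
alignment error. Rotation correction uses bilinear interpolation about the
image center, background filled with the modal border gray; corrections
beyond ±15° are refused as gross misorientation. On synthetic plates the
estimator recovers rotations of ±0.5–5° to within ~0.15°; the residual
floor comes from centroid quantization over a 2-pitch baseline.

**Pitch estimation.** Column/row foreground-sum profiles are
autocorrelated; the pitch is the dominant local maximum at lag ≥ ~¾ of the
colony width. Colony width is the mean run length of the profile above one
quarter of its maximum — for a disc the column-sum profile is a semicircle,
whose quarter-maximum width (≈1.94 r) tracks the true diameter much better
than the half-maximum width (≈1.73 r).

**Fine cropping.** A band one pitch thick spanning the central ¾ of the
perpendicular extent steps outward from the image center (step = one pitch)
until it contains no colony-scale foreground; the border is the outermost
foreground pixel inside the walked region, padded outward by half the
inter-colony gap so the crop partitions into centered cells. Bands clip at
the image boundary and a band fully outside is trivially empty, which makes
an already fine-cropped image a fixed point of the operation. Cropping is
growth-based: a completely empty outer row is not part of the crop; such
plates then fail grid validation and are routed to the error folder for
manual repair, which mirrors how un-croppable plates are handled generally.

**Grid validation.** Thin separator lines are drawn between expected rows
and columns; a line with more than 10% foreground pixels fails, and the
plate fails if more than 5% of lines fail. Both tolerances are package
choices (the underlying criterion is only "no significant overlap").

**Partitioning.** The fine crop is divided into rows×cols cells; integer
remainders are absorbed by the last rows/columns (one extra pixel each), so
the boxes tile the image exactly and deterministically.

**Directory workflow.** Files are copied, never destructively moved,
through the stage folders; `run_status.json` records per-image provenance.
On a re-run, images present in `fine_crops` but not yet measured (e.g.
manually repaired crops) are measured into a new, suffixed log file so
individual plates can be reprocessed without touching the rest.

## Measurement modes

**Thresholding** uses the isodata (iterative intermeans) algorithm — the
historical default of macro-driven image analysis — with polarity
auto-detected so colonies (the minority class) are foreground. A constant
image yields an empty mask and a warning.

**Particles** are 8-connected components; border-touching particles are
kept (edge cells legitimately abut the crop). Circularity is
4π·area/perimeter² with the Crofton perimeter estimate, clamped to [0, 1]:
near 1 for discs, near 0 for thin lines. The marching-squares perimeter
would systematically underestimate thin artifacts and misclassify them as
circular.

**Anomalies** are particles that are simultaneously non-circular
(circularity < 0.7) and unusually sized (> 1 SD from the plate's mean
particle area). Both defaults are exposed. Detection is non-interactive:
anomalies are reported with centroids, and an exclusion list fed back into
Standard mode deletes the named particles before assignment — a scriptable
replacement for interactive erasing.

**Standard mode** assigns each cell the largest-area particle whose
centroid lies inside it; empty cells score 0. The QC statistic is
|total − assigned| / total where *assigned* counts cells that received a
particle and *total* counts particles after any listed exclusions (deviation
is measured against the particle count, the more stable denominator); the
plate passes at ≤ 25%. Fragmented growth inflates *total* and fails QC by
design — those plates belong in Summation mode.

**Summation mode** sums all particle areas per cell and deliberately does
no artifact handling.

**Background-Subtracted mode** estimates each cell's background as the
median gray over four k×k corner patches (k = max(3, cell_side/10); the
corner size is a package choice) and reports the mean of
max(pixel − background, 0) over **all** cell pixels. Averaging over all
pixels (zeros included) rather than only positive residuals makes sparse
growth score low, which is the behavior that separates density differences;
`positive_only_mean=True` switches to the other reading. Because the
background is per cell, the score is exactly invariant to constant offsets
and insensitive to smooth plate-wide gradients.

## Normalization, exclusion, statistics

**Normalization** divides each value by its plate's median (default; robust
to blank positions), by the median of designated control positions (when
most strains are expected to respond), or not at all. The median of an even
count is the mean of the two middle values — this convention reaches the
designated-control divisor directly. A zero divisor is an error naming the
plate.

**Low-growth flag:** normalized value below 25% of the plate median.

**Global exclusion** removes un-inoculated plate sections. A colony is
excluded iff it is itself below the low-growth threshold **and** (≥ 6 of
its 8 Moore neighbors are below the threshold **or** ≥ 2 neighbors are
already excluded), iterated to a fixed point. The defaults 6 and 2 are the
empirically optimized values of the original heuristic. The self-low
condition is what keeps the recursion anchored to dead regions: without it
the excluded-neighbor rule propagates across healthy cells without bound.
At plate borders the neighbor thresholds scale proportionally
(⌈p·k/8⌉ of k existing neighbors). The rule is monotone, so the fixed
point is unique and order-independent (asserted against a brute-force
sweep oracle in the tests).

**Replicate exclusion** runs only on quad-replicate (2×2 per strain)
layouts and refuses others with a warning. A colony is excluded when it
deviates from its block's median by more than 45% of that median. The
historical description of this band ("within 45% … excluded") inverts the
selection and would discard concordant replicates; the deviation reading
implemented here matches the rule's purpose (discarding outlier replicates)
and the literal reading remains available behind
`literal_within_band=True`.

**Ratios.** Per strain and plate pair: growth_ratio = experimental mean /
control mean over non-excluded replicates; log_ratio = log(control/
experimental), natural log by default (`log_base` only rescales z-scores;
p-values are base-invariant). A strain dead on the experimental plate gets
a +∞ log-ratio sentinel; strains with no surviving replicate on a side are
flagged rather than tested.

**Tests.**

* *Normal-distribution method:* the screen-wide set of finite log ratios is
  fit by its mean and population SD (ddof = 0 — the z-scores describe the
  realized screen distribution; sample SD is available via
  `population_sd=False`); p = 2·Φ̄(|z|). Non-finite ratios (dead strains)
  are excluded from the fit. Because p is a monotone function of the
  strain's rank in the screen distribution, Bonferroni correction is
  refused for this method.
* *Welch's t:* long-hand t and Welch–Satterthwaite df, two-tailed p from
  the t distribution. Zero variance on both sides degenerates to p = 1
  (equal means) or a p = 0 sentinel with a warning.
* *Mann–Whitney U:* midrank U statistic; exact two-sided
  p = min(1, 2·min(tail probabilities)) by enumeration of all group
  assignments while the pooled sample is ≤ 20 (with ties, the enumeration
  runs over the observed value vector, so midranks are honored); beyond 20,
  the normal approximation with tie-corrected variance.

**Bonferroni** multiplies by m = the number of strains with a computed
p-value in the run, clamped at 1.

**Histogram bin width** minimizes the Shimazaki–Shinomoto cost
C(Δ) = (2·k̄ − v)/Δ² (k̄, v = mean and biased variance of per-bin counts,
N = ⌈range/Δ⌉ bins anchored at the minimum) over 64 log-spaced candidate
widths between range/200 and range/2; ties resolve to the smallest width.

**Classification.** Hits are strains with growth ratio ≤ 0.5, suppressors
≥ 2.0, both boundaries inclusive; the three output files carry an ISO-8601
date prefix and `-all` / `-positive-hits` / `-suppressors` suffixes.

**Plate pairing:** the condition labeled `control` (configurable) is the
comparer for every other condition with the same plate id; unpaired plates
are an error listing the orphans.

## Visualization

Cartoons are pure functions of (normalized values, masks, threshold):
re-rendering is byte-identical. Circle radius is proportional to the
normalized value, capped at 2 plate-median units so giants do not overlap
neighbors; fill interpolates light gray → black on [0, 1] and black → blue
on [1, 2]. Highlight precedence on single plates: excluded (red) >
low-growth (yellow). On comparisons: excluded (green) > dead-on-both
(orange) > significant (red, p or Bonferroni-adjusted p below the
threshold, following the run's correction setting). Raising the threshold
never removes a red highlight. The hover statistics of an interactive
viewer are replaced by a legend TSV written next to each SVG.

## Synthetic data

`generate_plate` renders anti-aliased discs at a fixed pitch with chosen
contrast (agar 60, colonies 180 by default), Gaussian pixel noise, additive
linear gradients, rotation, and line/blob artifacts; ground truth records
each colony's rendered footprint (pixels with coverage ≥ ½), its expected
background-subtracted density, and the grid layout box (tight colony extent
plus half a gap per side — the target of a correct fine crop). Three
deposition styles exercise the three measurement modes: `pinned` (one hard
disc), `fragmented` (the footprint split into equal fragments on a jittered
ring inside the cell; blunt-pin plates use a wider pitch — 36 px with
10 px colonies and 4 fragments by default in the tests — because disjoint
fragments geometrically cannot fit a 24 px pitch, and larger fragments keep
the thresholding rim small relative to their area) and `spotted`
(equal-footprint discs whose gray level encodes density).

`generate_screen` assembles control/experimental screens as multi-plate
composites on black backgrounds with a key file and a truth table of
planted experimental/control ratios. Colony areas vary log-normally with a
5% CV around their nominal value (pinning variability); planted effects
multiply the nominal area. The default base radius (6 px at 24 px pitch)
leaves headroom below the overlap limit so suppressors up to ~3× area can
express without clipping. `simulate_null_ratios` provides numbers-only
null screens (both sides drawn from the same lognormal) for statistical
calibration at sizes where rendering images would be pointless.

What the generator does **not** emulate: agar texture and specular
reflections, optical point-spread, plate-edge shadows and meniscus effects,
barcode labels, colony morphology (color/texture) and spatial growth
covariance beyond the planted effects. Passing tests therefore demonstrate
the correctness of the geometry, measurement, exclusion and statistics
logic under controlled conditions — not scanner-specific robustness, which
the error-folder workflow exists to absorb in practice.

## Problem sizes and determinism

The test suite and the acceptance script run on 384-position plates at
24–36 px pitch (images of roughly 400×600 px), 50-plate crop batches,
100 random exclusion grids and 2 000-strain null screens; these sizes give
stable statistics while keeping a full run in well under a minute on one
CPU. All randomness flows from explicit seeds (`numpy.random.default_rng`);
identical seeds give byte-identical images, screens and SVG output.

## Known limitations

* Round (Petri-dish) plate detection, perspective correction and
  barcode/OCR identification are out of scope; scans must be flatbed-style
  with the grid roughly axis-aligned (±15°).
* The normal-distribution method assumes the screen-wide log-ratio
  distribution is approximately normal; heavy planting of true effects
  inflates its variance estimate and makes the method conservative.
* The Mann–Whitney exact branch enumerates up to C(20, 10) ≈ 1.8·10⁵
  assignments per strain; at exactly 20 pooled samples it is noticeably
  slower than the approximation it hands over to.
* Designated-control normalization requires at least one flagged control
  per plate and fails loudly otherwise; there is no imputation of excluded
  values and no FDR control beyond Bonferroni.
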