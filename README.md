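# colonygrid

Quantification, review, statistics and visualization of colony-growth data
from high-throughput screens on gridded agar plates (synthetic-lethal / SDL
screens, yeast two-hybrid arrays, chemical-genetic screens — any experiment
whose readout is the growth of colonies pinned in a 384- or 1536-position
grid and compared between a control and an experimental condition).

The package covers the whole path from scanner output to hit list:

1. **Geometric processing** (`colonygrid.gridproc`) — split multi-plate
   scans (plates tiled on a black scanner mask) into per-plate images,
   estimate and correct plate rotation from 3×3 squares of colony centroids,
   fine-crop each plate so its borders coincide with the colony grid,
   validate the grid and partition it into one cell per colony. A directory
   workflow moves images through `original_scans → rough_crops →
   fine_crops → measurements_passed` stage folders, with failures routed to
   `fine_crop_errors` / `measurement_errors` for manual repair and re-run.
2. **Measurement** (`colonygrid.measure`) — three modes matched to how the
   cells were deposited:
   * *Standard* (robot-pinned): threshold, find connected particles, assign
     each cell the area of the largest particle whose centroid it contains;
     artifact detection (circularity < 0.7 **and** area > 1 SD from the
     plate mean) and a quality-control check (cells assigned vs. particles
     found must agree within 25%).
   * *Summation* (blunt-pin transfers): sum of all particle areas per cell.
   * *Background-Subtracted* (liquid-spotted): per cell, subtract the
     median gray of the four corner patches and report the mean positive
     residual — captures density differences and is invariant to lighting
     gradients across the plate.
3. **Review and statistics** (`colonygrid.review`) — plate-median (or
   designated-control) normalization; low-growth flagging (< 25% of the
   plate median); two exclusion heuristics (a recursive neighborhood rule
   that blanks un-inoculated plate sections, and a 2×2-replicate outlier
   rule); per-strain growth ratios r = experimental/control and log ratios
   log(control/experimental); p-values by one of three user-selected tests:

   * **normal** — z = (x − μ)/σ of each strain's log ratio within the
     screen-wide distribution, p = 2·Φ̄(|z|) (rank-based, inherently
     multiplicity-corrected);
   * **Welch t** — t = (m₁−m₂)/√(s₁²/n₁ + s₂²/n₂) with Welch–Satterthwaite
     degrees of freedom, between replicate sets;
   * **Mann–Whitney U** — exact two-sided p by enumeration up to 20 pooled
     samples, normal approximation (tie-corrected) beyond;

   optional Bonferroni correction (for the latter two), Shimazaki–Shinomoto
   histogram bin widths for distribution inspection, and three
   classification files: all strains, positive hits (r ≤ 0.5), suppressors
   (r ≥ 2.0).
4. **Visualization** (`colonygrid.visualize`) — deterministic SVG plate
   cartoons (circle size and gray→black→blue color encode normalized
   growth; yellow = low growth, red = excluded) and side-by-side
   control/experimental comparisons with significance highlighting and a
   machine-readable legend.
5. **Synthetic plates** (`colonygrid.synthplate`) — a ground-truthed
   generator of plate images (pinned / fragmented / liquid-spotted
   deposition, rotation, noise, gradients, scratch artifacts) and full
   screens with planted hits and suppressors, so the entire pipeline is
   testable without real scans.

## Worked example

`examples/03_review_statistics.py` simulates a screen with 20 planted
growth defects at a 0.3 area ratio, pushes the images through cropping,
Standard-mode measurement and the review pipeline, and prints:

```
strains tested: 384
positions excluded by heuristics: 0
strains in positive-hits file (ratio <= 0.5): 20
planted hits recovered: 20 of 20
  b1_01_s0182: ratio 0.24, z +4.69, p 2.71e-06
  b1_01_s0011: ratio 0.26, z +4.37, p 1.25e-05
  b1_01_s0049: ratio 0.27, z +4.31, p 1.62e-05
```

Each line is one strain: its measured experimental/control growth ratio,
the z-score of its log ratio within the screen-wide distribution, and the
two-tailed normal p-value — the planted 0.3× defects land deep in the tail
and exactly fill the positive-hits file. The other examples demonstrate
single-plate measurement in all three modes, the stage-folder directory
workflow, and cartoon rendering.

A command-line interface wraps the same pipeline:

```bash
colonygrid simulate --preset sdl-384 --seed 7 --hits 12 --out screen/
colonygrid measure  --mode standard --format 384 --arrangement 3x3 screen/
colonygrid review   --log screen/colony_log.tsv --key screen/key.tsv \
                    --test normal --out stats/
colonygrid view     --stats stats/*-all.txt \
                    --positions stats/reviewed_positions.tsv --out cartoons/
```

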