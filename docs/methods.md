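# Methods

## Model and procedure

The pipeline treats TMEM doorway detection as a deterministic chain of
image operations; there is no randomness anywhere between input image and
score, which is what makes rescoring a slide exactly repeatable.

**Optical density and stain unmixing.** Chromogens absorb light roughly
multiplicatively, so stains combine additively in optical density,
`OD = −log₁₀((v+1)/256)` per RGB channel (the +1 keeps OD finite at v=0).
Each stain (Vector Blue, DAB, Fast Red, light-green counterstain) is one
unit direction in 3-D OD space, configured as a named RGB reference color.
Four stain vectors in a 3-D space make the least-squares decomposition
underdetermined, and the minimum-norm solution smears a pure-stain pixel
across all correlated stains. We therefore solve the *non-negative*
least-squares problem exactly by enumerating the 15 stain subsets per
pixel (vectorized), preferring the smallest support among feasible
equal-residual solutions, so a pure DAB pixel loads only the DAB channel.
The counterstain is modeled as a fourth direction precisely so that
light-green background does not bleed into the three signal channels. A
3×3 median filter (radius 1, configurable) suppresses speckle before
classification.

**Pixel classification.** Gaussian linear discriminant analysis with a
shared pooled covariance — the standard model that is both "linear" and
"Bayesian". Priors default to uniform because training pixels come from
pathologist-guided (not frequency-representative) sampling. The pooled
covariance is ridge-regularized by `1e-6 · tr(Σ)/d · I` so exactly
rendered (zero-variance) training colors remain invertible. The model is
trained once from image/label-mask pairs and frozen as JSON.

**Morphometry.** The two tumor tones are merged; each class mask is closed
(dilate-then-erode) with a disk of radius 2 µm; overlaps created by
closing are resolved with priority vessel > macrophage > tumor > stroma
(rarest structure wins, keeping the map a partition). Components use
8-connectivity. Contact is defined discretely: a boundary pixel is an
object pixel with a non-object 8-neighbor (image-edge pixels included), and
a contact fraction is the share of boundary pixels 8-adjacent to the
neighbor class — a ratio, so the unit of perimeter cancels. Area filters
apply the printed thresholds with strict inequalities (an object of
exactly 800 µm² or exactly 5 µm² is kept); cascade gates are inclusive
("at least"). In cascade step (c), vessel contact is measured against the
union of all post-filter vessels, and step (d) uses the TA-macrophage
union recomputed after step (c); step (b), which has no printed
percentage, uses any contact > 0. TMEM markers are per-vessel 50 µm disk
dilations (computed by Euclidean distance transform); overlapping markers
stay distinct, one per TA vessel.

**Scoring.** Tiles are a disjoint grid of 300 × 400 µm fields anchored at
the ROI bounding box (the 439 × 330 µm manual-field preset is available).
A marker is assigned to the single tile containing its parent vessel's
centroid — one doorway, one count, even when the dilated footprint spans
tiles. Tiles with under 50 % ROI coverage are excluded, approximating a
pathologist choosing fields inside tumor nests. Ranking sorts by count
descending with row-major index as the deterministic tie-break; the score
sums the top 10. Risk: low ≤ 6 < intermediate ≤ 23 < high (the boundary
convention is not fixed by the cutoff definition; it is exposed in config
and echoed in reports).

## Calibration

The physical pixel size is a required configuration value: scanner
hardware and any downsampling change it, and the morphometric thresholds
are meaningful only in µm. The default for real-slide configs is
0.357 µm/px, the value consistent with a 140-px = 50 µm dilation radius.
All thresholds are stored in physical units and converted per run.

## Synthetic slides: what they emulate and what they do not

The generator renders the staining scheme (blue vessels, brown
macrophages, two-tone pink/red tumor, light-green stroma) as
anti-aliasing-free rectilinear shapes at **1 µm/px** on a 900 × 800 px
slide — exactly a 3 × 2 grid of 300 × 400 µm fields. At this scale every
area threshold (5–800 µm²) is an exact pixel count and the planted
geometry is reproducible bit-for-bit. Each planted triad is a 10 × 10 px
vessel wrapped on two sides by an L-shaped 78 µm² macrophage inside a
two-tone tumor nest; its discrete contact fractions are measured at build
time with the pipeline's own adjacency definition and exceed every cascade
gate with ≥ 2× margin (measured minimum: 0.41 against a 0.20 gate).
Because a sub-40 µm² macrophage cannot hold such margins at this
resolution, planted triads exercise the large-macrophage path; the
small-macrophage path is exercised by constructed label maps in the unit
tests. Five distractor kinds each violate exactly one stage: an isolated
macrophage, a vessel without macrophage, a vessel+macrophage pair with no
tumor contact, a > 800 µm² aggregate, and a < 5 µm² fragment. Structures
sit on a shuffled grid whose pitch exceeds twice the 50 µm dilation plus
smoothing, so plants never interact. Gaussian RGB noise (default σ = 6) is
added after geometry and never moves class boundaries.

Passing plant-and-recover on these slides therefore demonstrates the
correctness of the *measurement chain* — unmixing, classification,
filtering, cascade logic, tiling, ranking — under controlled colors and
geometry. It does not demonstrate robustness to real-tissue variability:
staining gradients, touching structures with ambiguous boundaries, folds
and retraction artifacts, out-of-focus regions, or scanner color drift are
all absent. Real deployments must re-fit the stain colors and retrain the
classifier on annotated fields from actual slides.

## Numerical choices and degenerate inputs

- Polygon ROIs rasterize by strict pixel-center inclusion; degenerate or
  self-intersecting polygons and empty masks are rejected.
- Tile ROI-overlap uses the nominal tile area as denominator, so
  edge-clipped slivers are penalized rather than inflated.
- Classifier ties break to the lowest class code; ranking ties break
  row-major; both are reachable and tested.
- Panels with constant scores make Pearson/Spearman undefined; the
  evaluation harness reports these as missing rather than NaN.
- Closing is computed on zero-padded arrays so border structures are
  treated exactly as interior ones.

## Problem sizes

Validation panels use 900 × 800 px slides (0.72 Mpx): 12 slides scored
twice for repeatability, 40 slides spanning 0–30 planted doorways for
metric concordance, and 50 noise-free slides for plant-and-recover; the
geometric brute-force oracles run on ≥ 200 random ≤ 20 × 20 px
configurations. These sizes exercise every code path, including multi-tile
ranking, at roughly a second per slide. Images larger than memory are out
of scope for this version; the tile iterator is the intended seam for a
streamed implementation (a halo of 50 µm plus the largest structuring
element would keep border dilations exact).

## Known limitations

- The feature-channel transform of the original commercial implementation
  is unpublished; equivalence is functional (class separability), not
  numerical.
- Whether step (c) "contact with vessels" means the parent vessel only or
  all vessels is ambiguous in the written cascade; the union of all
  post-filter vessels is used.
- The 50 µm algorithmic marker radius vs the 60 µm manual circle diameter
  convention is inherited as printed, not reconciled.
- Scores on real slides depend on the drawn ROI; ROI reproducibility is a
  property of the pathologist, not of this pipeline.
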