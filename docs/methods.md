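# Methods

`vesquant` quantifies 2D retinal vasculature the way generation-resolved
vessel-mapping tools (most prominently NASA's VESGEN) do: a binary vessel
image is thinned to a centerline graph, every segment is assigned a
branching generation, and three endpoints are reported in pixel units —
tortuosity (Tv), vessel length density (Lv) and vessel area density (Av) —
both in total and within the Large (G1–3), Medium (G4–5) and
Microvascular (G≥6) generation groups. A synthetic vasculature generator
with exact ground truth stands in for patient angiography images, so the
whole pipeline is validated end to end without any clinical data.

## Image processing

**Binarization.** Grayscale images are thresholded by Otsu's method (or a
fixed threshold), and 8-connected components below `min_object_px`
(default 20 px) are removed as speckle. Already-binary inputs pass through
untouched, so externally curated masks are respected. Binarization is
idempotent on its own output.

**ROI.** Density metrics are normalized over a region of interest. Three
constructions are supported: the convex hull of the vessel foreground
dilated by the 95th-percentile vessel radius (default — a vessel-bounded
region that always contains the mask), the full image frame, or a
user-supplied mask. How a clinical ROI should be drawn for a given field
of view is a genuinely open choice, which is why it is a mode, not a
constant.

## Skeleton graph

The mask is thinned with a topology-preserving algorithm
(`skimage.morphology.skeletonize`); the exact Euclidean distance transform
sampled on the centerline gives the local radius (local diameter =
2·radius). Skeleton pixels are linked with a reduced 8-adjacency in which a
diagonal link is dropped whenever one of its axial intermediates is also a
skeleton pixel — this keeps staircases at degree 2 and junction detection
stable. Pixels of degree ≥3 cluster (touching ones merge) into junction
nodes at their centroid; degree-1 pixels are endpoints; maximal
junction-free runs become edges carrying an ordered polyline, arc and chord
length, and a per-pixel radius profile. Components that are pure cycles get
a single anchor node with a self-loop edge.

**Arc length.** The naive chain-code sum (1 per axial step, √2 per
diagonal) is exact on straight axial/diagonal runs but overestimates
oblique and curved digital paths by 5–8% (a digital line at 22.5° measures
1.082× its true length), which would bias tortuosity far beyond its
discretization tolerance. Edge arc length is therefore measured on a
moving-average smoothing of the pixel chain (half-window 2, endpoints
pinned, window shrinking symmetrically near the ends). This estimator is
exact for collinear chains — all straight-line contracts keep their exact
values — and recovers smooth curves to well under 1% (a rasterized
semicircle measures within ~2% of πr). The raw chain sum is retained on
every edge as `arc_length_chain`.

**Spur pruning.** Thinning produces short leaf spurs near junctions and,
rarely, tiny "bubbles" (a short self-loop or a pair of short parallel
edges at a complex junction). Leaf edges shorter than
`max(min_len, radius_factor · junction radius)` (defaults 5 px, 1.5) are
removed, tiny bubbles are collapsed by the same threshold, and chains
across degree-2 nodes are re-merged; the procedure runs to a fixpoint and
is idempotent. Genuine capillary loops are orders of magnitude longer than
the threshold and are never touched.

## Generation assignment

*Tree mode* (open branching trees, e.g. fluorescein angiography arterial or
venous patterns): the root is the thickest edge touching an endpoint
(deterministic tie-break on coordinates). Daughters normally advance one
generation per junction; the single largest daughter *continues* its
parent's generation when its mean radius is ≥ `continuation_ratio` × the
parent's (default 0.8), emulating the convention that a dominant trunk
keeps its identity through an asymmetric branch point. There is no single
published rule for this step, so the ratio is exposed; any value > 1 gives
the pure "+1 per junction" rule, which is also what ground-truth recovery
is scored against. Cyclic inputs are refused with a pointer to network
mode.

*Network mode* (closed capillary meshes, e.g. the OCTA superficial
plexus): generations cannot be defined by descent in a graph with loops,
so they are radius bins on a halving scale,
`g = 1 + floor(log_base(r_max / r))` per connected component (default
base 2). The rule is deterministic, loop-safe and monotone: a thinner
vessel never gets a lower generation than a thicker one.

Grouping is fixed at the clinical convention G1–3 / G4–5 / G≥6.

## Morphometry

- **Tv** per segment is arc/chord (distance method), ≥1 with 1 = straight.
  Per-eye and per-group aggregates are arc-length-weighted means over
  segments (switchable to unweighted); since no standard defines the
  per-eye average, the weighting is documented rather than hidden.
  Zero-chord self-loops are excluded with a logged count. Empty groups
  give missing values, never 0: a tree with no G≥6 vessels has undefined,
  not zero, microvascular tortuosity.
- **Lv** is summed centerline arc length / ROI pixel count (px/px²).
- **Av** is vessel pixel count / ROI pixel count. For per-group areas each
  vessel pixel is claimed by the generation group of its *nearest skeleton
  pixel* (Euclidean), so group areas exactly partition the total — the
  alternative (per-segment disks) double-counts junction pixels.

Scale behavior, tested: Av is exactly invariant under nearest-neighbor
upsampling, Lv scales as 1/s, Tv changes by <2% under 2× upsampling.

## Synthetic data

`synthgen` emulates two geometries with exact ground truth (centerline
polylines, radii, arc/chord lengths, generation labels, pixel counts):

- **Trees**: complete bifurcating trees with geometric radius taper
  (`root_radius · radius_ratio^(g−1)`, defaults 6 px and 0.8), geometric
  length decay, and sinusoidal centerline displacement (amplitude 1.5 px,
  wavelength 30 px by default) whose true arc length has a closed
  quadrature form — the independent oracle for all tortuosity tests.
  The default layout is an H-tree (90° branch angle, length ratio 0.70):
  a complete binary tree of depth 7–8 laid out in the plane with constant
  moderate branch angles inevitably self-intersects, while the H-tree
  keeps all `2^g − 1` segments disjoint with ~3 px clearance at depth 8.
  The generator verifies non-overlap of all non-adjacent segments at
  generation time and refuses geometry that would merge in the mask.
  Asymmetry (one daughter scaled 1+a, the other 1−a) models unequal
  branching.
- **Networks**: jittered square lattices; `loop_fraction` sets the share
  of the lattice's independent cycles retained (cycle edges are removed at
  random without disconnecting the mesh, never below one cycle). Edge
  radii are Gaussian.

Rasterization stamps disks of the local radius at ≤0.5 px steps along the
centerline, guaranteeing 8-connected width-faithful masks. The grayscale
model is two-level (vessel 200, background 30) with additive Gaussian
noise, clipped to [0, 255]. Identical spec + seed gives byte-identical
output.

**Cohorts** draw eyes from a shared template with lognormal between-eye
variability on tortuosity amplitude (CV 0.15) and root length (CV 0.05) —
values chosen once as plausible biological spread — and apply per-group
effect multipliers to the tortuosity amplitude (and optionally extra
generations). The defaults mirror a three-arm design (control, diabetic
without retinopathy, diabetic with retinopathy with a 1.5× tortuosity
effect). What the generator does *not* model: dye leakage, microaneurysms,
hemorrhages, uneven illumination, partial-volume gray levels, crossing
arterial/venous trees, or 3D plexus structure — so passing tests show the
measurement machinery is correct on known geometry, not that segmentation
of real angiograms is solved.

## Statistics

Per metric × scope, a Shapiro–Wilk gate across all groups (α = 0.05)
routes to either one-way ANOVA with Holm–Šídák all-pairs comparisons
(pooled-variance t statistics, step-down Šídák adjustment) or
Kruskal–Wallis (tie-corrected) with Dunn all-pairs mean-rank z tests.
Dunn's family-wise correction is Holm by default, switchable to
Bonferroni or none, since practice varies. Generation-group × cohort
layouts use ordinary two-way ANOVA with Type II sums of squares (the
conventional default for unbalanced eye counts absent an interaction
focus) and Tukey HSD within each generation level using the single pooled
error variance and the studentized range distribution. Constant groups are
degenerate and treated as non-normal with a warning; an all-identical
table short-circuits to statistic 0, p = 1. Outliers are never removed.
Eyes, not subjects, are the analysis unit; inter-eye correlation within a
subject is not modeled — a documented simplification.

Validation: statistic/p-value equivalence with R's `stats` package
(`shapiro.test`, `anova(lm(...))`, `kruskal.test`) to ≤1e-6 relative on
random fixtures; a 5,000-replicate Gaussian null simulation of the full
gate+test ladder (3 groups × 15 eyes) with rejection rate required in
[0.03, 0.07]; and a 500-replicate power simulation of the default effect
cohort (geometry-only fast path) required ≥0.80.

## Numerical choices and problem sizes

- Coordinates are 0-based (row, col); foreground is True/255.
- Network generation bins use a 1e-9 slack inside the floor to keep exact
  radius halvings on the intended bin edge.
- Junction tie-breaks (root selection, daughter ordering) are resolved by
  coordinates then ids, so runs are deterministic and relabeling-invariant.
- Recovery tests use 20 trees of depths 3–8 on a 360×400 px canvas;
  simulations use geometry-only cohort generation (no rasterization), which
  is what keeps 500-replicate power runs cheap. The bundled demo study is
  3 groups × 4 eyes at depth 5.

## Known limitations

- Lv inherits a small negative bias (1–2%) from medial-axis tip retraction
  (the skeleton stops ~one radius short of each vessel tip); it stays well
  inside the 5% recovery tolerance and is not corrected.
- The continuation rule and the network radius-bin rule are reasonable,
  documented conventions, not reproductions of any proprietary assignment
  algorithm; with real VESGEN output, per-generation labels may differ at
  asymmetric junctions.
- Segmentation is deliberately minimal (threshold + cleanup); no
  vesselness filtering, illumination correction or artery/vein separation
  is attempted — pre-separated masks are accepted as inputs instead.
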