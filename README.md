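# vesquant

Branching-generation-resolved morphometry of 2D retinal vessel images,
with cohort-comparison statistics and a ground-truthed synthetic
vasculature generator.

Retinal vascular remodeling in early diabetic retinopathy shows up as
subtle changes in vessel tortuosity and density — often before clinically
gradable lesions. Generation-mapping analysis (the approach popularized by
NASA's VESGEN software) quantifies this by assigning every vessel segment
a branching generation G1…Gx and reporting, per eye and per generation
group:

- **Tv — tortuosity (distance method)**: centerline arc length divided by
  the straight distance between the segment's endpoints (≥1; 1 = straight);
  per-eye values are arc-length-weighted means.
- **Lv — vessel length density**: total centerline length / ROI area
  (px/px²).
- **Av — vessel area density**: vessel pixel area / ROI area.

Groups follow the clinical convention **G1–3 large, G4–5 medium, G≥6
microvascular**. Open branching trees (fluorescein angiography arterial or
venous patterns) are labeled by descent from the root with an optional
dominant-daughter continuation rule; closed capillary meshes (OCTA
superficial plexus) use a radius-halving rule, `g = 1 +
floor(log2(r_max/r))`. Cohort tables are compared with a Shapiro–Wilk
normality gate routing to one-way ANOVA + Holm–Šídák or Kruskal–Wallis +
Dunn, and two-way ANOVA (Type II) + Tukey HSD for generation × group
layouts, all at α = 0.05.

Because clinical angiograms are rarely shareable, the package includes a
synthetic generator (`vesquant.synthgen`) producing FA-like bifurcating
trees (H-tree layout, tapering radii, sinusoidal tortuosity with a
closed-form arc length) and OCTA-like capillary meshes, each with exact
ground truth — every pipeline stage is validated against known geometry.

## Worked example

```python
import numpy as np
from vesquant import synthgen, segmentation, vesselgraph, generations, morphometry

# synthetic "eye": depth-5 tree, noisy grayscale
spec = synthgen.TreeSpec(n_generations=5, noise_sigma=10, seed=1)
image, true_mask, truth = synthgen.generate_tree(spec)

mask  = segmentation.binarize(image)                      # Otsu + cleanup
graph = vesselgraph.prune_spurs(
    vesselgraph.build_graph(vesselgraph.skeletonize_map(mask)))
gm    = generations.assign_generations_tree(graph, continuation_ratio=1.1)
rec   = morphometry.measure_eye(mask, np.ones_like(mask), graph, gm, "eye1")

print(f"edges {len(graph.edges)} (truth {len(truth.segments)})")
print(f"Tv {rec.Tv_total:.4f}  (truth {truth.tortuosity_true():.4f})")
print(f"Lv {rec.Lv_total:.6f} (truth {truth.length_true()/truth.roi_pixels:.6f})")
print(f"Av {rec.Av_total:.6f} (truth {truth.total_vessel_pixels/truth.roi_pixels:.6f})")
```

prints

```
edges 31 (truth 31)
Tv 1.0260  (truth 1.0233)
Lv 0.009229 (truth 0.009335)
Av 0.064368 (truth 0.064368)
```

i.e. the measured graph recovers all 31 true segments; tortuosity is
within 0.3%, length density within 1.2% (medial-axis tips retract
slightly), and area density is exact at zero noise-flips. A whole study —
per-eye records, statistics ladder, box plots — runs with:

```sh
vesquant study --seed 0 --n-eyes 4 --out results/demo
```

or, for your own images, `vesquant study --manifest manifest.csv --out DIR`
with columns `image_path, eye_id, subject_id, group`. Individual stages are
exposed as `vesquant synth|segment|measure|stats`.

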