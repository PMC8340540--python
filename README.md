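# thinedges

Post-processing for object-boundary predictors in biological and natural
image analysis: turn a predicted **boundary** — a gray-scale image whose
pixel intensity encodes per-pixel edge confidence, forming a ramp several
pixels wide — into a **thin edge**: a binary, 1-pixel-wide, 8-connected
contour suitable for quantitative evaluation and downstream geometry.

Boundary predictors (typically neural networks, e.g. for kidney-boundary
detection in laparoscopic video) emit blurry, noisy ramps with spurious
responses and occasional gaps. `thinedges` implements the edge-extraction
function

```
E(g; α, β, γ):  gray boundary image  →  binary thin edge
```

as three parameterized stages:

1. **Threshold (α ∈ [0, 255])** — intensities strictly below α are zeroed;
   a rudimentary noise filter.
2. **Skeletonize (β ∈ {'2D', '3D', 'GWPS'})** — reduce the boundary to a
   1-pixel curve. `'2D'` and `'3D'` are the classic Zhang–Suen and Lee
   binary-thinning algorithms (via scikit-image). **GWPS**
   (Gray-Weighted Path Skeletonize) is intensity-aware: it first computes
   the **GWDT** (gray-weighted distance transform),

   `t[i, j] = min over 4-connected paths W to the background of Σ f(i_r, j_r)`,

   the minimal accumulated intensity along a path to the nearest zero
   pixel, then extracts the ridge of that cost surface by ordered
   homotopic thinning: pixels are deleted in ascending cost order
   whenever the eight-way neighborhood number `N_c` equals 1 (deletion
   preserves local topology) and the pixel is not an endpoint.
3. **Prune (γ ∈ [0, 100])** — remove spurs (endpoint-terminated side
   branches) up to length `l = (γ/100)·√(w² + h²)` pixels.

The package also provides the evaluation metrics used to tune and compare
pipelines — **SDE** (symmetric mean distance between predicted and
ground-truth edge pixels; an empty map is scored via a single center
pixel) and **IoU-box** (mean bounding-box IoU over matched connected
components) — a deterministic combinatorial **grid search** over
{α, β, γ} minimizing mean SDE, and a **synthetic generator** of ramp
boundaries around known 1-pixel curves (Gaussian cross-profile, additive
noise, spur-inducing irregularities, gaps) so the whole toolchain is
testable without external data.

## Worked example

```python
from thinedges import (GeneratorConfig, ParamSet, SearchGrid, extract_edges,
                       generate_dataset, grid_search, sde, iou_box)

# five noisy synthetic boundaries around known ground-truth curves
samples = generate_dataset(5, GeneratorConfig(noise=10.0, irregularity=3.0, seed=42))

p = ParamSet(alpha=40, beta="GWPS", gamma=2)
pred = extract_edges(samples[0].boundary, p)
print(f"edge pixels: {int(pred.sum())} (gt: {int(samples[0].gt_edge.sum())})")
print(f"SDE: {sde(pred, samples[0].gt_edge):.3f} px")
print(f"IoU-box: {iou_box(pred, samples[0].gt_edge):.3f}")

grid = SearchGrid(alphas=(10, 40, 120), betas=("2D", "3D", "GWPS"), gammas=(0, 2, 5))
res = grid_search([s.boundary for s in samples], [s.gt_edge for s in samples], grid)
print(f"best: alpha={res.best.alpha} beta={res.best.beta} gamma={res.best.gamma} "
      f"(mean SDE {res.best_mean_sde:.3f})")
```

prints

```
edge pixels: 123 (gt: 121)
SDE: 0.159 px
IoU-box: 0.985
best: alpha=120 beta=GWPS gamma=5 (mean SDE 0.096)
```

The extracted edge has nearly the same pixel count as the 1-pixel ground
truth and lies a fraction of a pixel from it on average (SDE 0.159 px,
lower is better); its component bounding boxes overlap the ground truth's
at IoU 0.985. Over the grid, the search selects an intensity-aware GWPS
configuration with aggressive thresholding and mild pruning.

The same operations are available from the shell:

```sh
edges synth --n 10 --seed 1 --out data/
edges extract data/boundaries out/ --alpha 40 --beta gwps --gamma 2
edges evaluate --pred out/ --gt data/gt --out report.csv
edges search --boundaries data/boundaries --gt data/gt --out search/
```

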