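# texslic

Superpixel segmentation for gray-scale brain MR images, built around an
improved SLIC (simple linear iterative clustering) that adds local texture
to the clustering distance and gates the center update by gray similarity.

Transaxial brain MR slices are hard to oversegment cleanly: gray levels
drift across the image (coil bias fields), edges are blurred by partial
volume effects, and acquisition noise scatters impulse-like outliers.
Plain SLIC, which clusters on intensity and position alone, lets these
artifacts drag cluster centers off tissue and bleed superpixels across
anatomical boundaries. `texslic` chains four stages against this:

1. **3-D histogram gray reconstruction** — each pixel's triple
   *(f, g, h)* (gray value, 3×3 mean, 3×3 median) is classified by its
   deviation from the histogram-cube diagonal and corrected
   (*f\** = (*g*+*h*)/2, *g\** = (*f*+*h*)/2, or *f\** = *g\** = *h*),
   the output pixel being (*f\**+*g\**+*h\**)/3 — a robust local cleanup
   of impulse outliers and gray non-uniformity.
2. **Gamma enhancement** — *I′* = 255·(*I*/255)^γ with γ = 0.5, lifting
   dark target tissue before clustering.
3. **LTriDP magnitude texture** — an LBP-family 8-bit code per pixel that
   compares, at each of the eight ring neighbors, a center-referenced
   squared-difference energy *M₁* against a neighbor-referenced energy
   *M₂*; bit *i* is 1 iff *M₁* ≥ *M₂*.
4. **Improved SLIC** — k-means in (gray, position, texture) with
   per-cluster adaptive normalizers,
   *D* = √((*d_c*/*N_c*)² + (*d_s*/*S*)² + (*d_t*/*N_t*)²), windowed
   search of 2*S*×2*S* per seed (*S* = √(N/K)), and a **gray-gated
   update**: only members with |gray − center gray| < α (α = image gray
   standard deviation) contribute to the new center.

Segmentations are scored by **undersegmentation error**
(UE = (|⋃{sᵢ : sᵢ∩g≠∅}| − |g|)/|g|, lower better) and **boundary match**
(BM = |SP ∩ GT|/|SP|, higher better), and a seeded synthetic phantom
generator provides brain-like test images (elliptical regions, bias
field, blur, impulse noise) with exact ground truth, so the whole
pipeline is testable without any external data.

## Worked example

```sh
$ texslic phantom --seed 1 --case combined --out img.png --truth gt.png
phantom 'combined' -> img.png, truth -> gt.png
$ texslic segment --input img.png --k 100 --variant proposed --out labels.png --overlay overlay.png
91 superpixels -> labels.png
$ texslic eval --labels labels.png --truth gt.png --bm-tol 1
{
  "UE": 0.059224163458691144,
  "BM": 0.16414737836561172
}
```

The phantom is a 128×128 two-tissue slice (grays 50/200) degraded with a
±20% bias field, 1 px edge blur and 2% salt-and-pepper noise.  Requesting
100 superpixels seeds a 9×9-ish grid (91 survive connectivity
enforcement).  UE ≈ 0.06 means the superpixels that touch the target
region spill under 6% of its area beyond it; BM counts the fraction of
*all* superpixel boundary pixels lying within 1 px of the true contour —
with ~90 superpixels over a 2-region truth most boundaries are interior,
so BM is structurally far below 1 (see `texslic.metrics.boundary_recall`
for the converse question "was every true edge found?").

Variants `slic`, `enforced_slic`, `improved_slic`, `proposed` switch the
stages on one at a time (`--variant`), forming the ablation ladder the
library's tests exercise.  The same operations are available as plain
functions:

```python
from texslic import PhantomSpec, PipelineConfig, generate_phantom, run_pipeline, evaluate
img, truth, _ = generate_phantom(PhantomSpec(seed=1))
state = run_pipeline(img, PipelineConfig(n_superpixels=100))
print(evaluate(state.labels, truth, bm_tol=1).to_dict())
```

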