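# lumpwire

Interactive Live Wire segmentation of breast lumps in mammography ROIs, with
a texture-based link cost built from a Gabor filter bank and fuzzy c-means
(FCM) clustering.

## The problem

Delineating a mass on a mammogram is hard for fully automatic methods and
tedious by hand: lesions are low contrast, noisy, and surrounded by a *fuzzy
halo* — a faint transition zone that is clinically part of the lesion but
carries almost no gradient at its outer rim. Live Wire (intelligent
scissors) splits the work: the reader marks a handful of points on the
boundary, and a graph search snaps a minimum-cost path through them.

The image is an 8-connected directed graph over pixels. The cost of the link
from pixel *p* to neighbor *q* is

```
C(p,q) = w_Z f_Z(q) + w_G f_G(q) + w_D f_D(p,q),   (w_Z, w_G, w_D) = (0.43, 0.43, 0.14)
```

where `f_Z` is a binary Laplacian-of-Gaussian zero-crossing feature, `f_G =
1 − G/max(G)` the inverted gradient magnitude, and `f_D` the gradient
direction cost `(2/3π)(arccos d_p + arccos d_q)`. Dijkstra's algorithm from
each seed yields the optimal path to any free point; consecutive clicks are
chained into a closed contour and rasterized to a mask.

Gradient and Laplacian features are exactly what the fuzzy halo defeats:
the tracker locks onto the strong inner rim and excises the halo. This
package therefore also implements the texture replacement for `f_Z`:

1. filter the ROI with a Gabor bank — orientations 0°–150° in 30° steps
   crossed with radial frequencies `0.25 ± 2^(i−0.5)/N`, `i = 1..log2(N/8)`;
2. rectify, smooth and standardize each response into per-pixel texture
   feature vectors;
3. cluster the vectors with FCM (c = 10, m = 2, ε = 10⁻⁵), minimizing
   `J = Σᵢ Σₖ μᵢₖᵐ ‖xₖ − vᵢ‖²`;
4. mark every boundary between hardened cluster labels as edge evidence
   (cost 0) — this map substitutes `f_Z` in `C(p,q)`.

Accuracy against a reference mask `S_B` is reported as
`TP = |S_A∩S_B|/|S_B|`, `FP = |S_A∖S_B|/|S_B|`, `FN = |S_B∖S_A|/|S_B|`, and
the misclassification error `ME = 1 − |S_A∩S_B|/|S_A∪S_B|` (one minus the
Jaccard overlap).

Because clinical images cannot ship with the code, a phantom generator
produces mammogram-like lumps (low-contrast plateau, faint decaying halo
skirt, oriented background texture, Gaussian noise) with exact ground truth,
plus simulated boundary clicks.

## Worked example

```python
import lumpwire as lw

img, truth = lw.make_lump_phantom(lw.textured_spec(seed=9))
clicks = lw.simulate_clicks(truth, n_points=10, seed=9)
for method in ("classic", "gaborfcm"):
    mask = lw.segment_image(img, clicks, method=method)
    print(method, lw.compute_metrics(mask, truth).to_dict())
```

prints

```
classic {'tp': 86.9027, 'fp': 1.5929, 'fn': 13.0973, 'me': 14.4599, 'area_sa': 2500, 'area_sb': 2825}
gaborfcm {'tp': 97.6283, 'fp': 3.5398, 'fn': 2.3717, 'me': 5.7094, 'area_sa': 2858, 'area_sb': 2825}
```

The classical cost stops at the strong inner rim and misses 13% of the
lesion (high FN — the halo); the texture cost recovers it (TP 97.6%) and
more than halves the misclassification error.

The same pipeline is scriptable from the shell:

```
lumpwire phantom --preset textured --seed 9 --out-image img.png \
    --out-mask gt.png --out-clicks clicks.json
lumpwire segment --image img.png --clicks clicks.json --cost gaborfcm --out mask.png
lumpwire evaluate --pred mask.png --truth gt.png
```

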