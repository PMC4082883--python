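# Methods

## Model and procedure

`lumpwire` segments a lesion boundary as a minimum-cost closed path over the
8-connected pixel graph of a grayscale ROI. Directed link costs combine
three local features of the destination pixel `q` (and, for the direction
term, the source `p`):

* **Laplacian zero-crossing `f_Z`** — binary: 0 where the
  Laplacian-of-Gaussian response is zero or changes sign against a
  4-neighbor with larger magnitude, 1 elsewhere. Zero crossings of the LoG
  mark loci of maximal gradient, so they should be cheap to traverse.
* **Gradient magnitude `f_G = 1 − G/max(G)`** — strongest edges cost 0; a
  constant image (max G = 0) costs 1 everywhere, since it carries no edge
  evidence.
* **Gradient direction `f_D = (2/3π)(arccos d_p + arccos d_q)`** — `d_p`,
  `d_q` are dot products of the unit link vector with the unit vectors
  perpendicular to the gradients at the two endpoints; the link vector's
  sign is chosen so `d_p ≥ 0`, capping `f_D` at 1. This smooths the path by
  penalizing links that cut across the local edge orientation.

Weights default to (0.43, 0.43, 0.14). Diagonal links are scaled by √2 so a
straight boundary is never beaten by an axial staircase of equal per-link
cost. Dijkstra's algorithm (binary heap, FIFO tie-break among equal keys for
cross-platform determinism) computes the optimal spanning tree from each
click; consecutive clicks contribute optimal segments that are concatenated,
closed last-to-first, and filled (4-connected background flood, boundary
pixels included) into a binary mask.

### Texture edge map

The replacement for `f_Z` targets lesions whose rim drowns in noise or fades
through a fuzzy halo. Per-pixel texture features are Gabor energies: the
image is convolved with zero-mean (DC-removed) real Gabor kernels
`exp(−(u² + γ²v²)/2σ²)·cos(2πfu + φ)` at orientations {0°,…,150°} step 30°
and frequencies `0.25 ± 2^(i−0.5)/N` (N the image size rounded down to a
power of two, i up to log2(N/8)); each response is rectified, Gaussian
smoothed, and standardized per channel. Fuzzy c-means clusters the feature
vectors by alternating the closed-form membership and centroid updates of
the weighted objective `J = Σᵢ Σₖ μᵢₖᵐ ‖xₖ − vᵢ‖²` until `|J_t − J_{t−1}| <
ε`. Hardened labels (argmax membership, ties to the lower index) yield an
edge map that is 0 wherever two 4-neighbors carry different labels. All
cluster boundaries are marked; the user's clicks select which boundary the
path follows — the clustering typically produces concentric "layers" around
a lesion, and anchoring the path on the intended layer is exactly the
interactive part of the method.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `w_z, w_g, w_d` | 0.43, 0.43, 0.14 | empirical cost weights |
| `log_sigma` | 1.0 px | LoG scale for `f_Z`; larger blurs the edge, smaller admits noise |
| orientations | 0°–150°, step 30° | six-fold coverage exploiting Gabor symmetry |
| frequencies | `0.25 ± 2^(i−0.5)/N` | denser sampling near mid-band, where natural-image spectra discriminate best |
| `sigma_rule` | σ = 0.56/f | ≈ one-octave envelope bandwidth per channel |
| `gamma` | 0.5 | envelope aspect ratio (elongated along the carrier) |
| smoothing | 2σ per channel | energy pooling window |
| `c` | 10 | clusters; enough to separate lump core, halo layers and background |
| `m` | 2.0 | FCM fuzziness exponent |
| `eps` | 1e-5 | objective-decrease stopping threshold |
| `max_iter` | 300 | safety net on the alternating updates |

## Numerical choices

* Images are min–max normalized to [0,1] on load; constant images map to
  all zeros (they carry no edges, and this avoids 0/0).
* Gradients are central differences (one-sided at borders); Sobel is
  available by option. All filtering uses reflect padding.
* The discrete LoG of a flat or linear patch is not exactly zero (kernel
  truncation leaves ≈ 1e-4 at unit intensity), so the `L = 0` branch of
  `f_Z` triggers at `|L| ≤ 5e-4`. Zero crossings are assigned to the
  smaller-|L| side; exact ties go to the negative-L side so an antisymmetric
  step marks a single line. Because any finite padding bends the LoG at the
  image border, border pixels can carry padding-induced crossings.
* Zero-gradient pixels have no defined perpendicular; they contribute
  `d = 0` (neutral cost 2/3 per endpoint) rather than NaN.
* FCM starts from a seeded uniform-random membership matrix (columns
  normalized); a pixel coinciding exactly with a centroid receives crisp
  membership (the limit of the update formula). Feature channels whose
  standard deviation is below 1e-12 are left at zero instead of being
  standardized, so float-epsilon responses to constant images are not
  amplified into unit-variance noise.
* Directed link costs are kept asymmetric exactly as defined (`f_D` depends
  on the link direction); each click pair gets its own Dijkstra tree.

## The phantom generator

The phantom emulates the target imagery: a lump plateau of contrast 0.25
over a 0.4 background, an oriented background grating (30°, 0.2
cycles/pixel, amplitude 0.12), Gaussian noise (σ = 0.05), and a boundary
perturbed by a 3-harmonic, 2 px sinusoid. Its halo reproduces the feature
that defeats gradient trackers: at the plateau rim the intensity drops
sharply to a faint skirt (half contrast) that decays to zero across the
halo (6 px), so the strongest lesion gradient lies at the rim *inside* the
truth while the outer halo boundary carries almost no gradient. The
background grating is attenuated where lesion signal is present — dense
masses locally obliterate tissue texture, and a grating passing unchanged
under the lump would be invisible to DC-free texture features. Ground truth
is the full lesion extent (plateau plus halo), since the halo is clinically
part of the lesion; with `halo_width = 0` it is exactly the perturbed
ellipse. Simulated clicks sample the ground-truth boundary chain at equal
arc length (counterclockwise from the top-left-most boundary pixel), with
optional radial Gaussian jitter.

What the phantom does **not** reproduce: anatomic clutter (ducts, vessels,
pectoral shadow), spatially varying texture statistics, quantum-noise
intensity dependence, and lesion spiculation. Passing the phantom suite
shows the machinery behaves as designed under the modeled degradations; it
is not evidence of clinical-grade accuracy.

## Problem sizes

Phantoms are 96×96 with lump radii 24 px and ten clicks — large enough for
a 36-channel Gabor bank (the frequency rule at N = 64) and a few hundred
boundary pixels, small enough that the full two-variant, ten-seed suite
runs in well under a minute. The shortest-path engine is verified exactly
against an exhaustive relaxation oracle on 6×6 graphs, where enumeration is
cheap and exact float agreement is well defined.

## Known limitations and open choices

* Texture energies localize boundaries only to within the analysis window
  (kernel support + pooling), so the cluster-boundary edge map can sit a
  few pixels off the true rim and, on fragmented clusterings, offer
  spurious paths; with few anchor clicks the texture variant's
  per-phantom error spread is wider than the classical one's, and on easy
  high-gradient boundaries the classical cost can win. Its advantage is
  systematic exactly where built for: boundaries whose evidence is textural
  rather than gradient (the halo).
* The direction term is implemented with arccos. Reading the composition
  literally as `cos(x) − 1` would produce negative link costs, breaking
  cost minimality (and Dijkstra's preconditions); the arccos form is the
  original intelligent-scissors definition and keeps `f_D ∈ [0, 1]`.
* `f_Z` and `f_G` are evaluated at the destination pixel only, per the cost
  definition; the graph is genuinely directed.
* Cluster count is fixed (default 10), not selected automatically; which
  cluster boundary is "the" lesion contour is deliberately left to the
  clicks.
* No on-the-fly training of cost histograms, no path cooling, no GUI;
  interaction is simulated by programmatic click placement.
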