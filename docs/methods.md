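# Methods

## Imaging model and stain separation

The pipeline treats a brightfield H&E image as Lambert–Beer absorption:
per-pixel optical density `−log(I/I₀)` is linear in stain amounts, mixed
through a 3×3 stain matrix `M` whose unit columns are the OD-space colors
of hematoxylin, eosin and a residual direction. Intensities are guarded as
`max(I, 1)` before the log so a zero pixel has the finite density
`−log(1/255)`; the background intensity `I₀` is fixed at 255 (configurable)
rather than estimated per image.

`M` is estimated by the SVD-plane method: pixels with OD magnitude above
0.15 are projected onto the plane of the top two (uncentered) singular
vectors, and the directions at the 1st/99th percentiles of the in-plane
angle are taken as the two stain vectors; the residual column is their
normalized cross product, and hematoxylin is the column with the larger
red-OD component. Two failure modes fall back to the published
Ruifrok–Johnston vectors (H ∝ (0.650, 0.704, 0.286), E ∝ (0.072, 0.990,
0.105), unit-normalized): fewer than 100 pixels above the OD floor (a
near-white field) and a second singular value below 10 % of the first
(an effectively one-stain image, e.g. pure eosin background, where the
two-stain mixture is unidentifiable — without this check the estimator
happily labels a noise direction "hematoxylin"). The estimator's percentile
and floor values are configurable and not claimed to match any particular
published calibration.

Deconvolution itself is the exact linear solve `c = M⁻¹·OD` with no
clipping, so it is invertible for round-trip testing; the hematoxylin
channel used downstream is channel 0 clipped at zero and rescaled by its
own maximum to [0, 1].

## Coarse segmentation

All structure sizes assume 40x magnification (~0.25 µm/pixel).

* Opening then closing by reconstruction with a disk of radius 7 px
  (about half a nucleus radius) removes bright and dark texture smaller
  than the disk while exactly preserving surviving outlines; grayscale
  hole filling (erosion reconstruction from a border-seeded marker)
  removes residual dark spots. Results are insensitive to the exact radius
  below ~8.
* Otsu's threshold is computed by exhaustively scanning all 256 histogram
  cuts of the image's own value range for the minimum within-class
  variance; an empty class contributes zero, ties go to the smallest
  threshold, and a constant image is flagged degenerate. Nuclei are the
  high-hematoxylin class (`> T`); it is concentration, not luminance, that
  is thresholded.
* A tile whose 99th-percentile hematoxylin absorbance is below 0.2 OD is
  declared empty before thresholding. Otsu always finds *some* cut, so a
  pure-background tile would otherwise be split along its noise; 0.2 sits
  several standard deviations above the noise-induced hematoxylin signal
  of an eosin-only field and a factor ~5 below the per-nucleus signal.
* Internal markers are the H-maxima of the exact Euclidean distance
  transform of the (radius-3-opened, hole-filled) mask: grayscale
  reconstruction of `dist − h` under `dist` with `h = 3 px`, then
  8-connected plateau regional maxima restricted to the foreground. The
  plateau construction matters: marking only the pixels whose reconstruction
  residue reaches `h` (as some library routines do) fragments the near-flat
  distance ridge of an elliptical nucleus into several specks and the
  watershed then cuts the nucleus apart. `h = 3` only separates slightly
  touching nuclei by design; proper clump splitting is the refinement
  stage's job, and a small `h` avoids losing small nuclei.
* The external marker is the homotopic-thinning skeleton of the background,
  which preserves background connectivity (one connected curve threading
  between nuclei when the background is connected). An erosion/opening
  skeleton can disconnect, which would let watershed basins leak.
* Regional minima of the Sobel gradient magnitude of the filtered image
  are imposed exactly at the markers (erosion reconstruction of the
  pointwise minimum of the offset gradient and a sentinel marker image) and
  the watershed floods with 4-connected ridge semantics; components and
  extrema elsewhere use 8-connectivity, the standard pairing that lets a
  1-pixel ridge separate basins. Basins are confined to the threshold
  mask; the external skeleton stops them at the boundary. Components below
  30 px are dropped as debris.

## Splitting touching nuclei

Each labeled region is processed independently, cropped with a 4-px pad:

* The gradient-weighted distance `Dg = D·exp(1 − (G−Gmin)/(Gmax−Gmin))`
  (normalization over mask pixels; the degenerate constant-gradient case is
  defined as `Dg = D·e`, the continuous limit) is high near object centers
  and depressed near internal boundaries. Its 8-connected plateau maxima —
  one representative per plateau, the centroid rounded to the nearest
  in-plateau pixel — are candidate centers; a region with `n` maxima holds
  at most `n` nuclei. `n` is capped at 12 (top `Dg` values) to bound the
  `O(n)` watersheds evaluated on pathologically irregular regions.
* `G` here is the gradient of the **raw** hematoxylin channel, not the
  reconstruction-filtered one used by the coarse watershed: the radius-7
  filters flatten the narrow high-gradient seam between abutting nuclei,
  which is precisely the splitting cue.
* For each `K = 1..n`, maxima are grouped by minimum within-cluster sum of
  squares. For the tiny point sets that occur per region (n ≤ 9) the
  optimum is found exactly by enumerating set partitions (restricted-growth
  order, first partition wins ties); beyond that, Lloyd iteration runs from
  a deterministic farthest-point initialization seeded at the maximum-`Dg`
  point. Lloyd alone misses the optimum on roughly a fifth of small random
  point sets, which destabilizes the `K` selection.
* Each cluster becomes one connected internal marker: its points plus the
  Bresenham rasterization of its Euclidean minimum spanning tree, clipped
  to the region mask (a clipped-off fragment still floods — accepted).
  The external marker is the erosion of the mask complement by a disk of
  radius 3. Minima imposition and watershed then split the region. The
  flood is confined to (mask ∪ external ring) and no internal ridge line is
  drawn, so the `K` sub-labels partition the mask exactly. Both choices are
  deliberate: if the external basin may claim pixels inside the region
  boundary, every `K ≥ 2` candidate loses a 1–2 px boundary ring that the
  `K = 1` candidate keeps, and the objective acquires a spurious
  anti-splitting bias of the order of the region perimeter — large enough
  to flip most decisions. A single internal marker cannot split anything,
  so `K = 1` returns the region itself.
* Each sub-region is fitted with the ellipse sharing its second central
  moments (center = centroid, semi-axes `2√λᵢ` of the coordinate
  covariance, `a ≥ b`, orientation in [0, π) from the +x/column axis;
  degenerate components clamp the axes at 0.5 px; a circular component
  takes orientation 0 for determinism). The canonical rotated-ellipse
  quadratic form is used for the interior test, evaluated at pixel centers
  over a grid that covers every fitted ellipse even outside the crop.
* `ξ(K)` = pixels covered by some ellipse but outside the region + region
  pixels covered by no ellipse. The minimum over `K` (ties to the smaller
  `K`, a parsimony choice) selects the split. Regions are processed in
  ascending label order and reassembled with consecutive global labels;
  the procedure only splits, never merges.

## Synthetic tiles

The generator emulates the study conditions end to end: 350×350 px tiles
at 40x with 70 nuclei of 9–16 px semi-axes (≈4.5–8 µm), 30 % of nuclei in
touching pairs (plus one triplet when the clump budget is odd) with
10–35 % pairwise area overlap (fraction of the smaller member), the rest
placed disjointly with ≥ 2 px clearance. Clump members are chained by
bisection on center distance to hit a target overlap; non-adjacent chain
members must stay disjoint and successive link directions stay within ±60°,
so a chain is chain-shaped rather than a folded cluster.

Rendering is the same forward model the deconvolution inverts. Nuclei are
opaque abutting objects: each covered pixel belongs to the nucleus with
the nearest center — the same convention as the ground-truth labels — and
carries that nucleus's concentration `c_i·p(r)`, where `p` is flat inside
normalized elliptical radius 0.9 and falls as a half-cosine to 0 at 1.0,
and `c_i ~ N(1, 0.15²)` models between-cell staining variation. Pixels
near the ownership boundary inside a clump are raised by a narrow
(σ ≈ 1.5 px) chromatin-rim factor of up to 1.5×, standing in for the
stacked nuclear envelopes and condensed peripheral chromatin that make the
junction between real abutting nuclei visibly darker. Within-nucleus
texture multiplies the field by `exp(0.08·s)` for a smooth unit-variance
field `s`; the eosin background is 0.35 concentration modulated ±40 % at
very low frequency; RGB is `255·exp(−M·c)` plus σ = 3 Gaussian sensor
noise, quantized to uint8. A fixed seed reproduces tiles byte-identically.

What the generator does *not* emulate — and hence what passing tests do
not establish about real slides: out-of-focus blur, scanner color
variation between slides, stromal and cytoplasmic texture, nucleoli and
chromatin clumps with sharp internal edges, non-elliptical (folded,
spindle) nuclei, and transparent projection overlap of nuclei from
different focal planes. The occlusion-with-rim clump model in particular
gives the splitting watershed a genuine but clean boundary cue; heavily
overlapping translucent nuclei in real tissue are harder than anything in
these fixtures.

## Evaluation conventions

Object matching is greedy one-to-one by descending IoU with a TP threshold
of IoU ≥ 0.5 — the field convention; the underlying criterion is
configurable. Whole-image DSC (not a per-object mean) is the headline
overlap number; per-object values appear in the CSV output. Clump-level
split errors classify each ground-truth clump (maximal group of touching
nuclei, found by union-find over 8-adjacent label pairs) into at most one
category, in priority order: *undersplit* if fewer predicted objects cover
it than it has members (covering = ≥ 20 % of a member's area);
*encroachment* if the counts agree but some member's best IoU falls below
0.5 (a boundary in the wrong place usually also makes objects straddle
their neighbors, so encroachment is tested before oversplit);
*oversplit* otherwise, when a single member is covered by two or more
objects. Ratios with empty denominators are reported as missing (NaN),
never as zero.

## Numerical and determinism notes

* The default pipeline contains no randomness; a seed option exists only
  for stochastic extensions. Identical input and configuration give
  byte-identical label images.
* Otsu ties break to the smallest threshold; `ξ` ties to the smallest `K`;
  plateau representatives and partition enumeration use fixed
  lexicographic orders; the circular-component orientation is pinned to 0.
* Minima imposition uses a float offset of `(max−min)/1000` (minimum 1e-6)
  and sentinels one unit beyond the data range.
* Problem sizes in the test and acceptance runs — ten 350×350 tiles, one
  hundred doublet and fifty single fixtures, 16×16–48×48 oracle grids —
  were chosen so every quantity is measured on hundreds of objects while
  the full suite stays interactive (tens of seconds).

## Known limitations

* The ellipse objective is nearly flat for 3-chains whose middle nucleus
  is cut on both sides: on the fixed triplet sweep the true `K = 3` is
  selected ~82–86 % of the time, with misses split between `K = 2` and
  `K = 4`. Doublets (96 %) and singles (100 %) are robust.
* Nuclei whose shape departs strongly from an ellipse are over-divided,
  an intrinsic property of the objective.
* The coarse stage cannot recover a nucleus whose hematoxylin signal falls
  below the Otsu cut (chromatin-poor nuclei on real slides).
* Splitting never merges, so coarse over-segmentation (rare with plateau
  H-maxima markers) is permanent.
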