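# Methods

## Overview

`upside` turns an unlabeled brightfield movie into (i) per-cell latent
representations of shape and texture, (ii) discrete morphological states,
(iii) human-interpretable decodings of what distinguishes those states, and
(iv) a row-stochastic matrix of state-transition probabilities per frame
interval. This note records the models, the parameters that matter, the
numerical choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not establish.

## Label-free segmentation

A regressor maps brightfield intensity to a synthetic
cytoplasm-fluorescence image, from which objects are segmented. The
regressor is a patch-wise dense encoder–decoder: overlapping square tiles
(default 32 px, 8 px works well on the synthetic data) are flattened,
passed through a bottleneck layer (default 128 units) and regressed against
the matching fluorescence tiles under mean-squared error with Adam.
Whole-frame inference stitches overlapping tile predictions with uniform
blending; predictions from different strides agree to within the blending
tolerance. We chose a dense patch architecture over a convolutional one
deliberately: at the patch sizes involved the mapping is local, the dense
model trains in seconds on one CPU, and the rest of the pipeline only
consumes the predicted image.

Segmentation of the predicted image is a global Otsu threshold followed by
a distance-transform watershed (peak markers at least 7 px apart), with an
area gate `[min_area, max_area]` in px². Detections touching the frame
border are flagged and excluded from linking, to avoid truncation bias in
displacement estimates.

Pearson correlation between predicted and true fluorescence is the
prediction metric; it is symmetric and affine-invariant, and undefined
(raised as an error) for constant images.

## Viability screening

A dense classifier (one hidden layer, sigmoid output) is trained with
binary cross-entropy `-(y log f(X) + (1-y) log(1-f(X)))` and Adam on
annotated Live/Dead crops. The decision threshold defaults to 0.5 and is
exposed in config. The Live set shrinks monotonically as the threshold
rises. On synthetic mixtures, leaving a ~7% dead fraction in the stream
changes the downstream clustering of surviving cells by less than 0.05 ARI,
which is why a compact classifier suffices here.

## Pose normalisation

Each crop is reduced to a canonical 64×64 mask image and texture image:

1. re-centre on the mask centroid (sub-pixel, bilinear for intensity,
   nearest for the mask);
2. rotate so the second-moment major axis is vertical — skipped when the
   moment-axis ratio is under 1.05, since orientation is undefined for
   near-circular cells (the tie rule);
3. reflect so pixel mass lies in the top and right halves, fixing the
   remaining mirror ambiguity;
4. rescale isotropically **only if** the aligned mask would overflow the
   frame minus a 10% margin (shrink-only). Always rescaling to the frame
   would erase absolute cell size, and size is one of the most informative
   morphological features; shrink-only preserves it for all but
   pathologically large crops while guarding against clipping.

The texture image z-scores the interior intensities and maps them linearly
to [0, 1] (min exactly 0, max exactly 1, per crop); all exterior pixels are
set to 0.5. A constant interior is degenerate: the image becomes uniformly
0.5 and the crop is flagged. Standardisation is per crop, not per dataset,
so texture encodes spatial pattern rather than absolute brightness.

Canonical outputs of a crop and its rotated/mirrored copies agree to within
a mean absolute pixel difference of 0.05; the residual comes from
interpolation. Note one consequence used later: the texture image
necessarily embeds the silhouette (the 0.5 exterior), so texture encodings
are never fully independent of shape.

## Twin variational autoencoders

Mask and texture images train two separate VAEs with loss

    L = A·(γ·MSE + (1−γ)·KLD),
    MSE = ||X − F(z, X)||²  (summed over pixels, averaged over the batch),
    KLD = −½ Σⱼ (1 + log σⱼ² − μⱼ² − σⱼ²),

with defaults A = 1, γ = 0.9, latent dimension J = 100 and ~10⁵ training
steps at full scale; the test suite and acceptance runs use a scaled-down
setting (J = 16, hidden 256→128, 600–800 steps, batch 32, Adam 1e-3) that
trains in ~15 s per branch on one CPU. Encoder and decoder are dense
(flatten → hidden ReLU → μ/log σ² heads; mirrored decoder with sigmoid
output); reparameterised sampling is used in training, and inference
encodes each image as the posterior mean μ, so encodings are
deterministic. log σ² is clipped to [−10, 10] for numerical safety, and a
non-finite loss aborts with diagnostics.

Per-cell codes are fused as `z = concat(w·z_shape, (1−w)·z_texture)` with
w ∈ [0, 1]. Baselines sharing the encode/decode surface: a vanilla AE
(pure MSE); adversarial AEs whose latents a discriminator pushes toward a
unit Gaussian (1x) or a 4-component Gaussian mixture with means
(−1, −0.5, 0.5, 1) and unit sd sampled per element (4x) — the
discriminator takes several update steps (default 5) per encoder step,
which is what makes the small-scale adversarial equilibrium stable, and
the encoder receives one combined reconstruction + fooling gradient; and
PCA on flattened images.

Interpretation: decode the population-mean latent vector, add a chosen
magnitude to selected latent dimensions (or a correlated group found by
hierarchically cutting the feature–feature Pearson matrix), decode again,
and inspect the signed difference image. Shifts are additive in latent
space, so group exaggeration equals the composition of single-feature
shifts.

## State analysis

Clustering is Louvain community detection on an unweighted Euclidean kNN
graph (defaults k = 15, resolution 1.0, seeded). Resolution directly
controls granularity: discovering a small number of coarse states from
well-separated data calls for a low resolution (the two-class benchmark
uses 0.1); the default suits the many-state regime. Raw communities can be
merged into named clusters only through an explicit merge map in config —
never heuristically. Identical-point inputs short-circuit to a single
cluster, since neighbour ranking is then meaningless.

The z-score clustergram uses `Z_f,C = (μ_f,C − μ_f)/σ_f` with rows and
columns ordered by average-linkage agglomeration; zero-variance features
get Z = 0 with a warning. The neighbour-similarity (homogeneity) score of
a type C is the mean, over its cells, of the fraction of each cell's N
nearest neighbours (self excluded, distance ties broken by index order,
default N = 20) sharing type C. The fusion-weight sweep recomputes fused
latents across a w grid and reports the w maximising mean homogeneity
(ties go to the first grid point).

Morphometrics: area = mask pixel count (×µm²/px² when calibrated);
eccentricity from the mask's second central moments; edge strength = the
maximum Sobel gradient magnitude within the mask dilated by 2 px (so the
rim is included), with values below 1e-12 clamped to exactly zero so
constant crops report 0. Marker quantification subtracts the per-frame
median of non-cell pixels and uses the marker frame nearest in time
(within half the marker interval by default); values near background may
be slightly negative, which is expected with in-situ antibody labeling.

## Transition dynamics

Linking is deliberately conservative and trajectory-free. For each cell i
in frame t: if every same-frame neighbour is farther than D₀, find i's
nearest cell in frame t+1 and link if that distance is below D₁. When two
isolated sources select the same target, the closer pair wins (source
order breaks exact ties) — the pairing rules are silent on collisions, and
this choice preserves both the minimum-distance principle and injectivity
in both roles. D₀ defaults to 1.5× the dataset's mean nearest-neighbour
distance; D₁ is set from config after inspecting displacement histograms.
Only adjacent frames are linked.

Transition probabilities are link counts normalised per source row,
`p(j|i) = f_ij / Σ_k f_ik`; rows with zero counts are reported as
undefined (NaN), not uniform. Velocities are link distances (µm if
calibrated) divided by the frame interval, grouped by the source cell's
cluster. The UMAP vector field grids the embedding extent and stores each
cell's mean displacement vector and magnitude (NaN where empty).
Population dynamics reports per-condition cluster-fraction time series and
a chi-square test of independence (no continuity correction) between
treatment and cluster identity over the endpoint window (last 5% of frames
by default), flagging cells with expected counts below 5.

## Synthetic data: what it emulates and what it does not

Cells are rendered as rotated ellipses whose area and eccentricity are
drawn per spec, with a low-harmonic radial boundary perturbation
(harmonics 3–6, sd 1.5% of radius — harmonics ≥ 3 roughen the outline
without biasing the second moments, keeping eccentricity under the spec's
control). Brightfield convention: background 0.5, interior offset, a dark
rim of amplitude `edge_contrast` with a faint outer halo, Poisson-placed
dark Gaussian granules, additive Gaussian noise (sd 0.02). Fluorescence is
a smoothed mask plus noise. Movies place cells with an exclusion radius,
evolve their states under a known row-stochastic matrix, and move them by
an isotropic Gaussian random walk with per-state step scale (reflecting at
a border margin), at 3 minutes per frame — matching typical acquisition —
with no divisions or deaths, since births would confound pairwise-linking
validation. Defaults: 0.325 µm/px, 512×512 frames.

Not emulated: realistic optics (PSF, shot noise), cell–cell contact and
overlap mechanics, 3-D structure, focus drift, uneven illumination, and
division/death. Passing tests therefore establish the *internal*
correctness and recoverability of the pipeline — planted classes are
recovered, planted Markov matrices and motility ratios are estimated
accurately, oracles agree — but not performance on real microscopy, where
segmentation errors and optical artifacts dominate.

One structural consequence worth stating: because canonical texture images
embed the silhouette, no image-level class pair can make the texture
branch truly uninformative about shape. The directional fusion-weight
controls therefore pair real VAE latents for the informative branch with a
constructed identical-noise branch (scaled to 1.5× the informative
branch's sd so that residual weight on noise measurably hurts); this
isolates the sweep's direction cleanly.

## Benchmark problem sizes

The bundled benchmarks are sized for a single CPU: 100 crops per class at
64×64 for state discovery (three seeds), 800 VAE steps per branch, 60
cells × 120 frames (≈7100 links) for Markov recovery, 100 random frame
pairs (≤300 cells each) for linking-oracle agreement, and n = 2000 for the
random-label homogeneity baseline. Full-scale settings (J = 100, ~10⁵–
2×10⁵ steps) remain reachable through config.

## Known limitations

- Dense (not convolutional) encoders limit texture sensitivity to patterns
  expressible after flattening; at 64×64 with the granularity/contrast
  levels tested this is sufficient, but subtle real-world textures may
  need more capacity.
- Louvain cluster counts are resolution-dependent; no automatic model
  selection is attempted, matching the exploratory intent.
- The linker discards non-isolated cells by design; in dense cultures the
  usable-link fraction falls and transition estimates lose power before
  they lose accuracy.
- Adversarial autoencoder training is stable at the scales tested but, as
  with any GAN-style objective, not guaranteed to converge for arbitrary
  settings.
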