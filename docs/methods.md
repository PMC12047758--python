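# Methods

This note records the models, parameter choices and numerical decisions
behind `eggsight`, and what the synthetic testbed does and does not
establish about real eggshell photographs.

## Synthetic egg model

An egg is rendered on a square canvas (default 256 px; all length
parameters are expressed in this 256-px reference frame and scaled with
the canvas) as:

* **Outline.** A one-parameter asymmetric oval: half-width
  `w(t) = (W/2)·sin(πt)·(1 + a·cos(πt))` for longitudinal position
  `t ∈ [0,1]` (t = 0 at the blunt pole), with length `L`, maximal width
  `W` and asymmetry `a ∈ [0, 0.9]`.  Positive `a` moves the widest
  section toward the blunt end, giving the blunt/sharp distinction the
  orientation step relies on.  Eggs are always rendered blunt-end-up;
  varied orientations are the preprocessing stage's problem.
* **Shell colour.** A uniform species-level RGB mean. The backdrop is
  neutral mid-gray (0.5), emulating a photo tent; mid-gray also equals
  the classifier's input-centring offset, so image borders carry no
  signal (see *Padding* below).
* **Spots.** Filled anti-aliased ellipses (edge transition ≈ 1 px at any
  radius) at three darkness offsets below the shell colour
  (moderate 0.22 < dark 0.40 < darkest 0.58 by default).  Longitudinal
  spot positions follow a wrapped von-Mises distribution centred at
  t = 0.28 (the blunt-end "crown"); concentration κ = 0 degenerates to
  uniform.  The diffuse field is placed disjointly (levels never
  overlap, so ground-truth masks partition the pigment); an optional
  extra ring component (`ring_extra_*`) layers blots that may merge
  with each other into a solid crown but never touch the diffuse field.
  When placement fails repeatedly the spot is retried at a smaller
  radius; an egg erroring out (> 50 % of spots unplaceable) signals an
  unrealistic density.
* **Ring ground truth.** The band of egg rows within ±2 SD of the spot
  position distribution around the ring centre, widened by the mean
  blot radius — i.e. the region that actually contains ring pigment.
* **Clutch structure.** One clutch-level draw perturbs colour, spot
  density, dimensions, asymmetry and ring concentration at the
  between-clutch spread; each egg adds a second perturbation at
  `clutch_sd_fraction` times that spread.  With the default fraction
  < 1 this yields positive intraclass correlation of every continuous
  parameter within clutches — the "signature" structure (replicable
  within, distinctive between clutches).
* **Noise.** I.i.d. Gaussian pixel noise, default sd 0.02 (0.04 in the
  harder planted-cue profiles), clipped to [0, 1].

What the generator does **not** model: real shell texture and gloss,
UV reflectance, illumination gradients, colour-chart calibration,
cracks/labels/tags, and within-spot pigment structure.  Tests passing
on this testbed therefore establish the *correctness of the analysis
machinery* (segmentation, training, attribution arithmetic, recovery of
planted signals), not performance claims about museum photographs.

## Preprocessing

Segmentation thresholds the Euclidean RGB distance from the median
border colour with Otsu's method, opens with a 2-px disk, closes with a
size-scaled disk (≥ 2 px) to bridge belts of spots whose colour is
close to the backdrop, fills holes, keeps the largest component and
takes its convex hull (eggs are convex; the hull repairs boundary bites
where dark spots touch the contour).  A second sizeable component
triggers a warning and is dropped.

Standardization rotates the principal axis vertical, crops with a 10 %
margin, puts the wider half up (blunt end), and flags orientation
unknown when the two halves' mean widths differ by < 2 %.  The egg mask
is clipped 2 px inside the frame.  The boundary band uses exact
Euclidean distance transforms with a half-pixel boundary offset, so a
rasterized disc's band matches the ideal annulus area to ~2 %; the
default radius is 5 px at 256, scaled with image size and floored at
1 px.

## Classifier and training

The network is the classic VGG16 block layout (conv counts 2/2/3/3/3,
3×3 kernels, 2×2 max-pooling, ReLU) with every channel count multiplied
by `width_scale`, a flatten + dense head, and softmax over species.
The engine is a compact numpy implementation with exact backprop
(finite-difference-verified to ~1e-10 in float64), which also provides
the activation/gradient access that Grad-CAM needs.

**Padding.** Convolutions replicate-pad their borders.  With zero
padding, frame-border activations are statistically distinctive at
every depth, and saliency maps develop spurious border hotspots; with
replicate padding on tent-style backdrops the borders look like the
interior.

**Optimization.** SGD with momentum 0.9, categorical cross-entropy,
batch 8.  The faithful default learning rate is 1e-6; the desk-scale
preset (`TrainConfig.desk_scale`: 64×64, width_scale 0.25) uses 0.001
with a 0.9 per-epoch decay, at which the quarter-width network
converges on separable four-class problems in 1–4 epochs.  The best
validation-accuracy checkpoint (first epoch attaining it) is restored
after training; training aborts on non-finite loss.  Splits are
0.5/0.2/0.3 and grouped by clutch, stratified by class, so
clutch-correlated images never straddle splits; a class with a single
clutch goes to training with a warning.

**Desk scale.**  The reference classification study uses 4 classes ×
200 eggs at 64×64 with width_scale 0.25 (≈ 1M parameters), which
trains in well under a minute per epoch on one CPU; the planted-cue
study uses 4 × 80 eggs at 128×128 with one medium-augmented copy per
training image and a fixed 10-epoch budget (no early stop — the
saliency analysis wants settled features, not merely separable logits).

## Augmentation and balancing

Operator parameters not fixed by the tier definitions: crops retain
70–100 % of the area (resized back), brightness/contrast shifts ±20 %,
gamma ∈ [0.8, 1.25]; rotations fill exposed corners with the median
border colour; the simple tier's rotation is exactly 180° (a pure pixel
permutation).  All probabilities are 0.5.  Balancing happens on the
training split only, after splitting, to avoid leakage; oversampled
rows are tagged (`augmented`, `source_egg_id`, `aug_seed`) so every row
traces to a source egg and the augmentation is reproducible.

## Grad-CAM

Channel weights are the spatial mean of the class logit's gradient on
the chosen block's last convolutional activation (post-ReLU, pre-pool);
the weighted channel sum is rectified, bilinearly upsampled and
normalized to max 1 (identically zero maps stay zero).  Aggregation
averages per-map-normalized heatmaps over correctly classified,
identically oriented images and renormalizes; "major impact" is the
region above 75 % of the maximum.  Normalization makes the map
invariant to positive rescaling of the logits.

Two practical limits, both visible in the planted-cue study: at
desk-scale image sizes the Block-5 receptive field covers most of the
egg, so localization is coarse (± one or two feature cells); and once
the task saturates (softmax confidence → 1 within an epoch or two of a
trivially separable problem), the rectified weighted sum can become
degenerate.  Augmented training and the harder planted-cue profiles
mitigate but do not eliminate this; the ring-recovery overlap is
therefore the most fragile quantity the test suite measures.

## Shapley attribution and the impact table

Players are square superpixels (default 8 px blocks at 64×64, 16 px at
128×128 — granularity chosen so a map costs seconds, not minutes).
With ≤ 12 superpixels every coalition is enumerated and the values are
exact; otherwise a permutation-sampling estimator walks random player
orders, cycling baselines so that the additivity identity
`Σ attributions = f(x) − mean_b f(b)` holds exactly by construction.
Model output is the softmax probability.  Attributions are broadcast
uniformly to the pixels of each superpixel.

Pigmentation regions come from K-means (k = 6) on RGB pixels within a
padded bounding box of the egg, with the backdrop homogenized to its
median colour first so sensor noise cannot fragment the background
over several centroids; clusters whose mask lies > 50 % outside the
egg are dropped as background and the 4 darkest survivors are kept,
ordered dark → light.  Clustering is per-image, matched across images
by luminance rank.  The impact table uses only correctly classified
images; Q2/Q3 thresholds (50 %/75 %) are taken against each image's
own maximum over the egg because attribution magnitudes vary strongly
between instances, and Q3 ⊆ Q2 by construction (the source analysis's
table contains two cells violating this; the implementation enforces
the nesting).

## Planted-cue study design

Four classes share a baseline (beige shell, diffuse moderate/dark spot
field, density 20) and differ by exactly one cue: `ringed` adds 35
small darkest spots concentrated at κ = 25 around t = 0.28; `darkspot`
adds ~12 large darkest blots (10–16 px radius at the 256 frame)
scattered over the shell; `hue` turns the shell greenish; `shape`
narrows and elongates the outline.  Spot-count totals are deliberately
similar across classes so the count itself is a weak cue.  Expected
recovery: `darkspot` maximal Q3 in Cluster_0 (darkest), `hue` in the
lighter clusters, `shape` in the boundary band; the Block-5 aggregated
Grad-CAM Q3 mask of `ringed` should overlap the ring band.

## Known limitations

* The Grad-CAM ring-overlap quantity is unstable across seeds at desk
  scale for the receptive-field and saturation reasons above.
* The Shapley estimator's superpixel granularity bounds how finely
  attribution can separate small spots from surrounding shell.
* Orientation standardization assumes a visible width asymmetry; truly
  symmetric eggs are flagged rather than oriented.
* The numpy engine is single-threaded apart from BLAS matmuls; it is
  sized for desk-scale studies, not for 256×256 full-width training.
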