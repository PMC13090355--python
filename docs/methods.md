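# Methods

This note records the models implemented in `retinopt`, the parameter
choices that matter, what the synthetic phantoms do and do not emulate,
and the numerical decisions taken where the design was open.

## Manta Ray Foraging Optimization and its improvement

The optimizer minimizes a black-box objective over the unit hypercube
[0, 1]^D; typed hyperparameters are decoded per coordinate (affine map for
continuous and integer parameters, equal-width binning with the endpoint
assigned to the last bin for categoricals, a 0.5 threshold for booleans).
Because the update arithmetic is defined on real vectors only, categorical
"adjacency" is ordinal in the declared order — a deliberate simplification.

Per generation, each member proposes one foraging move: with probability
0.5 cyclone foraging (taking the exploratory random-reference variant
while itr/MaxItr is below a fresh uniform draw, i.e. predominantly early),
otherwise chain foraging; a somersault pass over all members follows.
Every proposal is accepted greedily — the member moves only if the new
position improves its fitness — which is what makes the best-so-far trace
monotone. Positions are clipped to the bounds after every update (not
reflected), matching common MRFO practice. The draw r feeding √|log r| is
taken uniform on (0, 1] and floored at 1e−12 so the logarithm stays
finite. The chain rule is implemented with separate draws for the outer
coefficient and the logarithm's argument as printed in its source; a
`canonical_chain` flag reuses a single draw for both, the form common in
earlier MRFO implementations. In the leading member's chain and cyclone
updates both difference terms use the best solution.

The somersault rule is applied at each member's own current position.
In the exploratory cyclone rule the random reference point is drawn once
per member (uniform per coordinate) and used for both the anchor and the
difference term, so the leading member's middle term vanishes.

IMRFO wraps this loop with two truncation-selection moves:

* **opposition-based initialization** — N uniform samples plus their
  centroid opposites 2M − x, best N of 2N kept;
* **generation jumping** — with probability P_gj per iteration, each
  member contributes its centroid opposite and `n_partial` partial
  centroid opposites (a uniformly sampled non-empty proper subset of
  original coordinates retained, centroid-opposite values elsewhere), and
  the pool of N·(2 + n_partial) candidates is truncated back to N.

Defaults: population 20, 50 iterations, somersault factor 2, P_gj = 0.3
(the customary jumping rate in the opposition-learning literature; no
value is fixed by the method itself), n_partial = min(D, 5) to bound the
per-jump evaluation cost. Centroid opposites are clipped to the static
parameter bounds. Truncation uses a stable sort on fitness so ties break
by original order, keeping runs bit-reproducible under a seed. The
optimizer minimizes; maximization objectives are negated by the caller.
In a 1-D space partial opposition degenerates to the full centroid
opposite, which is logged.

On the 5-dimensional sphere benchmark (bounds [−5, 5], population 20,
50 iterations) the median final fitness over 10 seeds is computed by the
test suite and `scripts/acceptance.py`; the paired-seed comparison of
IMRFO against plain MRFO on sphere and Rastrigin (20 seeds) is likewise
recomputed there rather than quoted here.

## Fundus preprocessing

Stage order is fixed: Gaussian denoise → gamma correction → CLAHE →
black-padding removal → K-means disc/cup segmentation → ROI crop/resize.
Defaults: 5 × 5 blur (σ from the usual kernel-to-sigma convention),
γ = 0.4 (a strong brightening that standardizes under-exposed fundus
illumination), CLAHE clip limit 2.0 on an OpenCV-style scale (divided by
100 for the scikit-image implementation) with an 8 × 8 tile grid applied
to luminance with colour rescaled (a per-channel mode exists), padding
threshold 10, K-means k = 6 on grayscale intensity, 5 × 5 disk morphology,
crop margin 0.25 of the disc box per side, output 224 × 224. Boxes are
0-based and half-open throughout.

Disc/cup identification from the ordered cluster map was the one genuinely
open design point. Clusters are ordered by descending mean intensity and
accumulated while each stays below 12 % of the image — a brighter cluster
covering more than that is retinal background, not disc tissue. The disc
is the largest connected component of the accumulated set, opened, closed
and hole-filled. The cup is the brightest cluster inside the disc; when
that cluster spans essentially the whole disc (cup and neuroretinal rim
merged into one intensity cluster, common at low CDR), the disc interior
is re-thresholded by 1-D two-means and the *brightest* sufficiently large
component — not the largest, since adaptive equalization can brighten a
rim band — is taken as the cup. Cup ⊆ disc is enforced. A disc candidate
spanning more than half the image, or a cluster map with fewer than two
clusters, raises a segmentation failure naming the stage.

## Hybrid augmentation

Geometric augmentation composes rotation, shifts, zoom and shear into one
affine warp (bilinear, reflective borders, rotation about the pixel-center
image midpoint so quarter turns are exact); enabled flips apply with
probability 0.5. Noise injection adds zero-mean Gaussian noise with

    σ = k · (1 + brightness/255) · (1 − contrast/255),  k = 0.001·255,

where brightness is the image mean and contrast the population standard
deviation. With this k the σ ceiling is 0.51, which is negligible on the
0–255 intensity scale; the formula is therefore interpreted on the [0, 1]
normalized scale by default (σ is multiplied by 255 when applied to 8-bit
storage), with a raw-scale switch. Contrast above 255 is capped so σ is
never negative. Balancing augments each minority class up to the majority
count, cycling source images, and tags every synthetic image with its
source and sampled parameters so any output can be replayed. Augmentation
is applied to training data only.

## Dual-stream classifier

No GPU framework is used: the network is a compact numpy implementation
with explicit backprop (im2col 3 × 3 convolutions, max/average pooling,
dense layers, dropout, and hand-written SGD-with-momentum / Adam /
RMSprop update rules). Each stream downsamples the 224 × 224 input by
average pooling (factor 8) and applies three conv blocks; the structural
stream pools to 24 channels and the texture stream to 32, so the fused
vector has 56 components. Attention is a full square dense layer with
bias and sigmoid applied to the globally average-pooled stream vector;
modulation is elementwise; fusion is concatenation with the structural
stream first. The head is one 256-unit dense layer with ReLU, dropout 0.5
and a sigmoid output; the loss is binary cross-entropy.

The transfer-learning ratio is interpreted as the percentage of topmost
conv layers per stream left trainable (layer-count based, rounded); at 0
the stream features are computed once per fit and only attention and head
train. Pooled stream features are standardized per channel with
statistics frozen from the training set at the start of each fit — with
randomly initialized streams the raw pooled features have tiny
between-sample variance, and without this scaling the head needs far more
steps than a short search fit allows. Training restores the weights of
the best-validation-loss epoch.

## Evaluation

Splitting is stratified per class with largest-remainder rounding of the
70/15/15 fractions (ties go to the earlier split), shuffled under the
seed. Metrics follow the standard confusion-table definitions with
glaucoma as the positive class; precision and recall are reported as NaN
(with a warning), not zero, when undefined. AUC uses the rank-sum form
with mid-rank ties and the Mann–Whitney normalizer n₊·n₋, which makes it
the probability that a random positive outscores a random negative and
bounds it in [0, 1].

## Synthetic phantoms

A phantom renders the statistical structure the pipeline relies on: a
dark reddish background under a smooth diagonal illumination gradient, a
bright elliptical disc with jittered center, a brighter concentric cup of
radius CDR × disc radius, a few dark Bézier vessels, Gaussian sensor noise
(σ = 4 intensity units) and a black circular camera aperture. Truth masks
use the pixel-center rule on the generating ellipses. Labels follow the
clinical CDR heuristic (glaucoma iff CDR > 0.6), and dataset generation
draws CDR from class-conditional ranges (normal 0.2–0.5, glaucoma
0.65–0.9) on either side of the threshold, so classes are separable by
construction. Phantoms are 256 × 256 so the pipeline genuinely exercises
its 224 × 224 resize.

Phantoms deliberately omit photorealism: no peripapillary atrophy, no
vessel kinking at the disc border, no camera vignetting or compression
artefacts, and class separability is planted rather than clinical.
Passing tests therefore demonstrate that the machinery is wired correctly
and recovers planted structure — not clinical screening performance,
which requires real cohorts and full-scale pretrained backbones.

## Problem sizes

The test suite and acceptance script run everything at desk scale as a
matter of design: benchmark optimization at D = 5 with a 20 × 50 budget,
segmentation scoring over 20 seeded phantoms, and an end-to-end
experiment with 60 phantoms, an IMRFO budget of population 4 × 3
iterations with 2-epoch candidate fits, and a 5-epoch final fit. These
sizes exercise every code path while keeping a full run in tens of
seconds on one CPU.

## Known limitations

* Pretrained DenseNet121/ResNet50-scale backbones are out of scope; the
  streams are compact stubs, so absolute accuracy numbers are meaningful
  only relative to the phantom task.
* The K-means disc rule assumes the disc is the brightest compact
  structure; pathologies that break that assumption (severe PPA, bright
  exudates) would defeat it.
* Categorical parameters are ordinal inside the optimizer; with three
  optimizer choices the induced metric is harmless but not principled.
* The rank-AUC normalizer deliberately uses n₊·n₋; a rank-sum divided by
  n₊+n₋ is not a probability and is not implemented.
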