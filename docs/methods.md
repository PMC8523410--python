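# Methods

`usjoint` implements a click-guided system that segments and classifies a
focal hepatic lesion in a B-mode ultrasound image in one forward pass.
This note records the model, the synthetic data it is exercised on, and
the numerical and design choices that were genuinely open.

## Interaction model

A user marks a lesion with *foreground* clicks inside it and optional
*background* clicks around it.  Clicks are turned into Euclidean distance
maps: each pixel holds the minimum distance (between pixel centers) to
any click of that polarity, truncated at 255.  When a polarity has no
clicks, its map is the constant 255 — "no information".  The network
input stacks (image, foreground map, background map), each divided by
255.

Simulated interactions replace real click capture:

* foreground: a count k uniform on {1..5}, then k distinct pixels uniform
  over the lesion;
* background: a count m uniform on {0..10}, then m distinct pixels
  uniform over the band of background pixels at distance 5–40 px from the
  lesion.  The band limits are a design choice (the interaction rule only
  requires "a certain distance range"): near enough that the clicks
  inform the boundary, far enough that they are unambiguous background;
* 15 independent (foreground, background) click sequences are
  precomputed per training image, and each training step samples one.

Two inference modes are supported.  *One-click*: a single foreground
click, empty background map.  *Two-click*: the user supplies a bounding
box by its two corners; a simulated box starts from the lesion's tight
box, jitters each corner by ±10 % of the box side, enlarges by 10 % per
side, clamps to the image and forces lesion containment; the box becomes
one foreground click at its centre and four background clicks at its
corners.  Jitter and enlargement fractions are defaults of this package
(the protocol states only "a certain degree of positional error" and
"enlarged a little").

Conventions, used everywhere: 0-based (row, col) coordinates, distances
between pixel centers, boxes inclusive of both corner pixels.

## Networks

Three variants share one vocabulary of blocks (convolution 3x3 → batch
norm → ReLU):

* **seg_only** — encoder of D down-sampling stages (2x2 max pool after
  each block) and a decoder that restores resolution with fixed bilinear
  2x interpolation only; no learned transposed convolutions.  Encoder
  features re-enter the decoder through 1x1 projections added after each
  decoder convolution, so fine spatial detail survives the bottleneck.
  A 1x1 convolution produces the foreground logit map.
* **joint** — the same graph plus a classification branch: global
  average pooling of the deepest shared feature map, then fully
  connected layers (two hidden layers by default — the branch is only
  specified as "several fully connected layers") ending in class logits.
* **cls_only** — a VGG-style conv/BN stack on a 1-channel lesion patch:
  the patch is centred on the lesion tight box, twice its longer side,
  edge-replicated at borders and resampled to 64x64.

The **desk profile** (default) uses encoder widths (16, 32, 64, 128),
giving ~220k parameters for the joint network — small enough to train in
minutes on one CPU core, large enough to fit the phantom task.  The
`clinical` profile widens all stages 4x for users with more compute.  The
implementation is a small NumPy layer library with hand-written
backprop (im2col + GEMM convolutions; the input gradient is computed as
a same-padded convolution with 180°-rotated kernels, so no scatter-adds
appear in the hot path).

Two stabilizations matter at desk scale, where the learning rate is
relatively high for the tiny network: the fully connected branch uses
1-D batch normalization and leaky rectifiers (slope 0.01) so its narrow
layers cannot die into a constant-output state, and SGD clips the global
gradient norm at 5.  Without these the classification branch can
collapse to uniform probabilities early in training and never recover
(weight decay then freezes it there).

Inference binarizes the foreground probability map at 0.5 (unstated in
the protocol; 0.5 is the symmetric choice for a logistic output) and
takes the class by probability argmax.

Initialization is seeded He-style normal.  A published variant
initializes early layers from a network trained on breast-ultrasound
images; no such weights exist here, so random initialization is the
default and warm-starting on phantoms is available by simply training
twice.

## Training

* Losses: pixelwise focal loss for segmentation (mean over pixels of
  −(1−p_t)^γ log p_t) and α-balanced focal loss for classification
  (−α_y (1−p_y)^γ log p_y); the joint objective is their plain sum.
  γ = 2 and α = inverse class frequency normalized to mean 1 (the focal
  loss citation's canonical choices; the protocol fixes neither).
  Probabilities are clamped at ε = 1e−7 so losses stay finite.
* Optimizer: SGD, momentum 0.9, weight decay 5e−4.  The learning rate
  is constant in each half of training and steps down once at iteration
  ⌈N/2⌉.  The published clinical-scale schedules are available as
  `TrainConfig.clinical_joint()` (150 000 iterations, 5e−4 → 5e−5) and
  `TrainConfig.clinical_cls()` (40 000 iterations, 1e−3 → 1e−4).  The desk
  default is 2 000 iterations at 0.05 → 0.005 with batch 8: the
  published rates are tuned to 150k iterations on 3 909 clinical images
  and barely move a freshly initialized network in 2 000 steps, so the
  desk profile keeps the schedule's *shape* and rescales its magnitude.
* Augmentation: horizontal flip (p = 0.5) applied identically to image,
  mask and clicks; isotropic scaling with factor U(0.8, 1.2), the canvas
  restored by centre crop/pad (mask nearest-neighbour); brightness
  ±20/255 and contrast gain U(0.8, 1.25) on the image only.  Ranges are
  package defaults (the protocol names the transforms, not magnitudes).
  Click *coordinates* are transformed and the distance maps recomputed,
  rather than warping the maps as images — this preserves exact
  Euclidean semantics after augmentation.
* Every stochastic component (phantom sampling, click simulation, batch
  order, augmentation, initialization) is driven by explicit seeds;
  fixed seeds reproduce byte-identical phantoms and loss traces.

## Synthetic phantoms

No public clinical dataset with expert lesion outlines backs this
package, so a phantom generator emulates the statistical structure of
the clinical population it stands in for:

* four classes with the clinical mean ± SD longest dimensions — cyst
  16.8 ± 14.9 mm, hemangioma 17.4 ± 14.5 mm, metastasis 26.2 ± 15.7 mm,
  HCC 23.3 ± 14.7 mm — drawn from a log-normal law moment-matched to
  each mean/SD, truncated below at 4 mm (sub-resolution lesions are not
  useful) and above at 0.7x the image extent (the lesion must fit the
  canvas).  The clinical SDs describe population variation, not a
  generative law; the log-normal is a stand-in and is the main caveat
  when reading size-stratified results;
* outlines are ellipses (aspect 0.6–1.0, random orientation) with
  low-frequency radial harmonics (orders 2–5) whose amplitude is a
  per-class phenotype parameter — smallest for cysts, largest for HCC
  and metastases, reproducing the "unclear, irregular margin" failure
  mode of solid malignant lesions.  The outline is rescaled so its
  maximal diameter equals the drawn size, making the recorded
  `lesion_size_mm` faithful to the class law;
* rendering: cyst strongly hypoechoic (−70) with sharp margin (blur
  σ 0.6 px); hemangioma hyperechoic (+45), well defined; metastasis
  hypoechoic (−40), blurred margin (σ 2.5), dark peripheral halo;
  HCC mildly hypoechoic (−15) with strong smooth internal texture and
  irregular margin.  Speckle is multiplicative: a Rayleigh-amplitude
  field smoothed by a σ = 0.7 px Gaussian, mean-normalized, blended at
  scale 0.5 — the canonical fully-developed-speckle approximation;
* pixel spacing defaults to 0.5 mm/px on 256² images, which puts the
  clinical millimetre sizes at trainable pixel scales; the desk-scale
  study uses 64² images at 1 mm/px for the same reason.

What the phantoms do **not** model: attenuation and time-gain
compensation, probe geometry and scan-line artifacts, shadowing and
enhancement, surrounding anatomy, and inter-observer outline
variability.  Passing tests on phantoms therefore demonstrate that the
pipeline is implemented correctly and can learn class-linked appearance
— not that clinical-level accuracy would be reached on real images.

Dataset splits mirror the clinical protocol: records are ranked by
lesion area within each class, cut into as many equal groups as there
are test slots, and one record is drawn per group — the test set spans
each class's size range.  With 50 per class and a 0.2 split: 160
training and 40 test records, 10 per class.

## Evaluation

Per image and simulated user input: Jaccard index |A∩B|/|A∪B| between
the thresholded prediction and the reference mask (both-empty defined as
1, excluded by construction).  Five seeded user inputs per test image
(seed = 1000 x image index + input index).  Classification: confusion
matrix (rows = truth), per-class accuracy = diagonal/row sum, overall =
trace/total; ROC swept over all distinct score thresholds with
trapezoidal AUROC (equal to the tie-corrected Mann–Whitney statistic);
Youden-optimal operating point J = sens + spec − 1, ties broken toward
higher sensitivity (the tie rule is unspecified upstream; favouring
sensitivity suits a screening context).  For the benign/malignant task
evaluated with a 4-class model the malignancy score is
P(metastasis) + P(HCC); training a dedicated 2-class model is also
supported.  Multi-class ROC is one-vs-rest with unweighted macro
averaging.  AUROC confidence intervals use a percentile bootstrap
(2 000 resamples; the upstream CI method is unnamed).  System
comparison uses a two-sided paired sign-flip permutation test on the
per-image metric, exhaustive when 2^n fits the resample budget, Monte
Carlo otherwise (the upstream test behind its p-values is unnamed).

## Desk-scale study conditions

The standard end-to-end run — used by the acceptance script and the
slow acceptance test — generates 50 phantoms per class at 64² px
(1 mm/px), trains the desk joint network for 2 000 iterations at batch
8 (seed 0), and evaluates both click modes with 5 user inputs on the 40
stratified test records.  This size was chosen so the whole study runs
in minutes on a single CPU core.  Expected behaviour at this scale: the
joint training loss falls well below a quarter of its initial value,
four-class test accuracy clears 50 % (chance is 25 %), and the two-click
mode's mean Jaccard index is at least the one-click mode's — the same
ordering the clinical study reports (68.5 % vs 37.4 %), asserted only as
an inequality because absolute clinical values are not reproducible
without the clinical dataset.

## Known limitations

* The phantom law is a stand-in; none of the clinical headline values
  (mean JI, accuracy, AUROC) are comparable quantities here.
* The desk network is far smaller than any clinical model; its absolute
  metrics on phantoms measure the pipeline, not the clinical method's
  ceiling.
* Determinism holds within a fixed NumPy/BLAS build; across builds,
  floating-point reduction order may change low-order bits of training
  traces.
* The classification-only variant trains on ideal lesion-centred
  patches (reference masks), matching the published protocol's use of
  ideal patches; a fielded system would need patches from predicted
  masks.
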