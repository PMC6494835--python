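# Methods

## The segmentation model

Every voxel in a central brain region is classified into one of 15 classes
(background plus the seven bilateral sub-cortical structures: thalamus,
caudate, putamen, pallidum, hippocampus, amygdala, accumbens, each with left
and right parts) by a convolutional network with three input paths. For a
voxel v, three orthogonal 32×32 intensity tiles are extracted — axial,
sagittal and coronal planes through v — forming a "2.5D" sample that
approximates 3-D context at 2-D cost. Each tile passes through its own stack
of five 3×3 convolutions (rectifier after each, no pooling in the default
configuration) and a path-wise fully connected layer. The three path outputs
are concatenated together with the voxel's 15 atlas probabilities; with the
default path width of 180 units the concatenation is a 555-dimensional
feature vector. Two further fully connected layers (a fusion layer and a
softmax classifier) produce the class posterior.

The atlas vector is the explicit spatial prior: a probabilistic atlas built
by averaging (and Gaussian-smoothing) the one-hot label maps of the training
subjects, renormalised so the 15 channels sum to one at every voxel. The
atlas resolves the left/right ambiguity that pure intensity information
cannot (the two hemispheres look identical), and coarsely localises each
structure; the intensity patches resolve the exact boundary.

Patch tiles use the half-open window convention `[c-16, c+16)`, so the source
voxel sits at tile index (16, 16); out-of-grid positions are zero-filled.

### Parameter groups and transfer learning

Parameters are partitioned into eight named groups — one conv stack and one
path FC per orientation, the fusion FC, and the classifier — each with an
independent trainable flag. Adapting a trained model to a new acquisition
domain follows the freeze / fine-tune / reset protocol:

* all three convolutional stacks are frozen (they receive no optimizer
  state or updates, and tests assert bit-identity);
* the four fully connected groups are fine-tuned from their source values
  at a reduced learning rate;
* the classifier is re-initialised (seeded) and trained from scratch.

The rationale is the standard one: early convolutional layers encode
low-level, largely domain-general features, while the fully connected layers
encode how those features are interpreted, which is what a change of
intensity distribution invalidates.

## Training

Categorical cross-entropy on shuffled mini-batches of 128 with Adam. Default
full-training settings are 200 epochs maximum, patience 20, initial learning
rate 1e-2; transfer reduces the learning rate to 1e-4 and inherits the rest.
Early stopping tracks a validation metric (default: argmax accuracy on the
held-out 25% of samples); when `patience` epochs pass without a new best,
training stops and the best epoch's weights are restored. The executed epoch
count is therefore at most `best_epoch + patience + 1`. Batch shuffling is
reseeded per epoch from the master seed, so runs are bit-reproducible on a
fixed numeric backend.

Training samples are all structure voxels (positives) plus background voxels
drawn only from the boundary shell — the 26-connected (Chebyshev) dilation
of the structure union by five voxels, minus the structures themselves — so
the classifier spends its capacity on the hard border decisions. Samples are
split 75/25 into training and validation, pooled across subjects. A
`balanced` negatives policy (negatives capped at the positive count) and a
stratified per-subject cap with a per-class floor are available for
CPU-scale runs; the floor keeps the smallest structures (a few hundred
voxels) fully represented when the cap bites.

The network, its backprop and Adam are implemented in NumPy inside the
package (`subseg.nn`); convolution is im2col matrix multiplication, and all
analytic gradients are verified against finite differences in the test
suite.

## Inference

Classification is restricted to a region of interest derived from the atlas:
voxels where the maximum structure probability exceeds a threshold, dilated
by a few voxels. Defaults are threshold 0.1 and dilation 3. The threshold
must sit safely below the smallest structure's atlas peak: with 2 mm atlas
smoothing and per-subject jitter, the accumbens (radius ~3 voxels) peaks
near 0.35, so thresholds around 0.5 silently amputate it from the ROI (we
measured accumbens Dice collapsing to ~0.16 in an otherwise accurate model
before adopting the lower default). The dilation covers residual
inter-subject displacement while keeping the ROI near the boundary shell the
network was trained on. Both are exposed as flags.

Each ROI voxel is classified once (argmax, ties to the lowest class index);
voxels outside the ROI stay background. Because the network never saw
far-field background, spurious islands can appear inside the ROI; they are
removed by keeping, per class, only the largest 26-connected component
(equal-size ties: the component containing the lexicographically smallest
voxel index). Inputs are z-score normalised over the brain mask internally
if not already.

## Intensity pre-processing

Per-volume z-score normalisation (zero mean, unit variance over the brain
mask, transform applied to the whole grid) always precedes sampling and
inference. The optional two-stage histogram standardisation maps images onto
a common intensity frame: stage one learns a standard scale as the mean of
the training images' percentile-landmark vectors (defaults: ranks
{1, 10, 20, ..., 90, 99}, the deciles-plus-robust-extremes configuration;
output range [0, 100] — both configurable, as the original landmark choice
is not fixed by the protocol); stage two maps each image's landmarks onto
the standard landmarks piecewise-linearly, linearly extended beyond the
extreme landmarks and clamped to [0, 1.5·s_max] to bound outliers without
hard clipping. The map is monotone; flat histogram segments (non-increasing
image landmarks) are an error suggesting a coarser rank set.

## The phantom generator

The synthetic cohorts exist to make the domain-shift → recovery behaviour
reproducible without downloading any dataset. Each subject is a 64³, 1 mm³
grid containing 14 superellipsoid structures (exponent 2.5, semi-axis
factors (1, 0.9, 0.85)) placed symmetrically about the mid-sagittal plane,
with base radii 9..3 voxels from thalamus to accumbens — a strict volume
ordering spanning roughly 6000 to 190 voxels per family, mirroring the real
anatomical size spread. Per-subject Gaussian jitter (sd 1 voxel, clamped at
2 sd) displaces and rescales each structure independently, so a population
atlas built from several subjects is genuinely uncertain near boundaries;
generation fails loudly, naming the structure, if jitter pushes one outside
the grid.

Two scanner presets define the acquisition domains:

| | scannerA | scannerB |
|---|---|---|
| intensity scale | 2000 | 140 |
| in-brain background mean | 0.30 | 0.50 |
| structure contrast ordering | acc > pal > amy > put > tha > cau > hip > bg | put > cau > hip > acc > bg > pal > tha > amy |
| additive noise sd | 40 | 2.8 |
| bias-field amplitude | 5% | 8% |
| through-plane anisotropy | 1.0 | 1.5 |

Both presets keep at least 2·noise_sd of contrast between distinct tissue
means (left and right members of a pair share a mean, as in real tissue), so
segmentation is learnable in-domain. The two profiles are deliberately
disjoint — the intensity maxima differ by more than 10×, and the *relative*
contrast ordering differs, so after per-volume z-scoring a structure's
normalised intensity in one domain coincides with a *different* structure's
in the other. That is what makes the cross-domain model fail in an
instructive way (several structures collapse to Dice 0 while others survive)
rather than uniformly. Intensities follow
`bias_field × class_means[label] × intensity_scale + noise` inside the brain
mask (an ellipsoid united with the structures), zero outside. Anisotropy is
simulated by blurring + subsampling along the third axis and resampling
back, leaving grid shapes unchanged.

What the phantoms do **not** emulate: anatomical shape, cortical folding,
partial-volume mixtures beyond the anisotropy blur, motion artefacts, or
registration error in the atlas (all phantoms share one coordinate frame).
Passing the phantom benchmark therefore demonstrates the pipeline's
mechanics — sampling, optimisation, freezing, ROI logic, metrics — and the
qualitative domain-shift phenomenon, not clinical-grade accuracy.

## Evaluation

Per structure, the Dice similarity coefficient `2|A∩B| / (|A|+|B|)` between
the predicted and reference binary masks; per subject, the unweighted mean
over the 14 structures and the inverse-volume weighted mean
`Σ(DSC_s/V_s) / Σ(1/V_s)` with V_s the reference voxel count — the weighted
form stops the thalamus from hiding an accumbens failure. Structures absent
from both masks are undefined (recorded as NaN, excluded from averages);
reference volume zero with a defined score is an error.

Paired comparisons use the two-sided Wilcoxon signed-rank test: zero
differences dropped, mid-ranks for ties, W = the smaller signed-rank sum.
For n ≤ 25 the null distribution is computed exactly by dynamic programming
over the (doubled, hence integral) observed ranks; above that, a normal
approximation with tie correction and continuity correction. The exact
branch is tested against full 2ⁿ sign enumeration and against scipy.

## Desk-scale configuration

The shipped benchmark (`subseg.experiment.domain_adaptation_benchmark`, also
driven by `scripts/acceptance.py`) runs the four headline conditions —
in-domain reference, no-adaptation cross-domain, single-subject transfer,
full target training — with 5 training + 3 held-out subjects per domain on
64³ phantoms. To fit single-CPU runtimes it uses the `compact` network
preset (channels (8, 8, 16, 16, 16), strides (2, 2, 2, 1, 1), path FC 32,
fusion FC 64), a stratified cap of 4000 samples/subject (20k total, floor
200/class), 30 epochs at learning rate 1e-3 for full training, and for the
transfer stage a denser 8000-sample draw from the single target subject with
up to 100 epochs at the reduced rate 3e-4 (the stage is cheap, and the
re-initialised classifier needs the extra steps). These are the package's
scaling choices, not claims about the full-size configuration, which remains
the default `NetworkSpec`.

## Known limitations

* The NumPy backend is single-threaded BLAS-bound; the full-size
  architecture is practical for inference and contract tests but not for
  training at realistic sample counts.
* One prediction per voxel: no test-time augmentation or overlapping-patch
  fusion.
* The largest-component filter assumes each structure is one connected
  component, which is true of the phantoms and of the anatomy it imitates.
* Atlas and image are assumed co-registered; no registration is performed.
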