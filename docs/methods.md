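# Methods

`mslesionseg` implements a transfer-learning study design for volumetric
lesion segmentation at desk scale: synthetic 3D brain phantoms with exact
lesion ground truth stand in for clinical MRI, and the pipeline reproduces
the full chain — preprocessing, stratified patch sampling, 3D U-Net training
(de-novo vs fine-tuned from a source-domain "default" model), longitudinal
subtraction analysis, lesionwise evaluation, and rotation cross-validation
with repeated-measures statistics.

## The phantom model

A study is an ellipsoidal "brain" (semi-axes 26 x 30 x 24 mm at the 64³
desk default) containing a darker central "ventricle" ellipsoid, a smooth
Gaussian random texture field (SD 0.05 in tissue units, 4 mm correlation
length), additive white Gaussian voxel noise (SD 0.05), and hyperintense
lesions rendered hard-edged at a contrast of +0.25 over tissue (tissue mean
1.0, air 0). Three lesion regimes emulate the tasks' statistics:

* **ms_focal** — 2–12 (2–5 at the 32³ benchmark scale) small
  spheres/ellipsoids of radius 2–6 mm, placed by rejection sampling with a
  minimum center separation of the two radii plus two voxels (so the
  connected-component count of the mask equals the number of placed lesions
  exactly), preferentially near the ventricle surface with probability 0.5
  (periventricular geography).
* **source_geographic** — one or two large irregular blobs (radius modulated
  ±25% by a smooth random field) covering at least 5% of the brain volume,
  confined to one hemisphere and hard-clipped at the midline. This is the
  source domain standing in for large geographic signal abnormalities
  (gliomas, leukoencephalopathy); unilateral placement is anatomically
  motivated and guarantees a lesion-free contralateral patch window.
* **source_enhancing_foci** — many (6–10) small bright foci, the
  metastasis-like source domain of the contrast-enhancement task.

Longitudinal pairs share one anatomy: the follow-up scene adds `k` new
lesions (non-overlapping with the persistent ones), is moved by a random
rigid jitter (up to ±2 mm / ±2° per axis by default) and re-noised; the
applied transform and the follow-up-space new-lesion mask are recorded.
Contrast pairs add enhancing foci (and optionally a 1-voxel-thick falx-like
mid-sagittal enhancing plane excluded from ground truth) only to the post
image, with independent noise per volume.

All generators are pure functions of `(config, seed)`.

**Choice of lesion contrast.** The contrast default (5x the noise SD) sits
deliberately just above the separability floor: a fixed threshold at
`tissue_mean + contrast/2` recovers ≈96% of lesion voxels (≥90% guaranteed),
so the learning problem is solvable — yet the texture field leaves
lesion-like lumps that an undertrained network false-positives on. A much
higher contrast makes every converged model perfect and erases the
fine-tune/de-novo differences the experiment exists to measure; a lower one
breaks the separability guarantee. Lesions are hard-edged (no partial-volume
blur of the lesion increment) so that component counts and voxel-recovery
guarantees are exact even for 2 mm lesions whose surface voxels dominate.

**What the phantoms do not model:** anatomy beyond two ellipsoids, MR
physics (no TE/TR, bias fields, or Rician noise), multi-site scanner
variation, and partial-volume lesion borders. Passing tests therefore
demonstrate that the *pipeline machinery* behaves as specified and that the
transfer-learning direction of effect emerges under controlled domain shift;
they are not evidence about segmentation accuracy on clinical MRI.

## Preprocessing and patch sampling

Images are z-normalized to zero mean and unit **population** SD over all
voxels (the population convention makes "unit SD" exact), then resampled to
1 mm isotropic resolution by trilinear interpolation (nearest-neighbour for
labels); the output shape per axis is `round(shape · spacing / target)`.
Whether to normalize over brain voxels only is moot for phantoms (no
consequential air background); the full volume is used.

Training patches are stratified per study: `n_inc` lesion-inclusive centers
drawn uniformly from lesion voxels (guaranteeing ≥1 lesion voxel per patch)
plus `n_exc` lesion-exclusive patches drawn uniformly from the set of
lesion-free windows, which is enumerated exactly with a 3D summed-area
table — an error is raised only when no lesion-free window exists.
Out-of-bounds centers are clamped (patch shifted inward), never padded.
Each study is then expanded by whole-volume elastic augmentation: a coarse
control grid (8 mm spacing) of Gaussian displacements (SD 1.5 mm) is
upsampled to voxel resolution and warps image (linear) and label (nearest)
with the same field. Augmentation 0 is the identity and augmentations ≥1
are random warps, so the same centers extracted from every copy give
`(n_inc + n_exc) · n_augmentations` patches per study — with the full-scale
defaults (30+30, 3 augmentations) exactly 180, and the identity copy
reproduces the 30/30 stratification exactly. The defaults are 30/30/3 with a
24-voxel desk patch (96 at full scale).

## The segmenter

A standard 3D U-Net: `n_levels` ∈ {3,4,5} encoder blocks (two 3×3×3
convolutions, each followed by instance normalization with learnable affine
and ReLU; feature count doubles per level), 2× max-pool downsampling, a
bottleneck block, a mirrored decoder with 2× nearest-neighbour upsampling
and skip concatenation, and a final 1×1×1 convolution to two classes.
`patch_size` must be divisible by `2^n_levels` with a bottleneck of at least
2 voxels. Nearest-neighbour upsampling (rather than trilinear) keeps the
hand-written backward pass small and exactly testable; seam quality at
inference is governed by overlap averaging, not the upsampler.

Because no deep-learning framework is part of the environment, the network
is implemented directly in numpy: im2col + BLAS matmul convolutions
(channels-last layout so the GEMM reshape is free), explicit backward passes
for every layer (verified against central finite differences in float64 to
~1e-7 relative error), softmax cross-entropy, and Adam. Everything is
float32 and exactly deterministic given seeds: same-seed training runs
produce bit-identical weights.

Training follows the voxelwise cross-entropy / Adam regime; the full-scale
defaults are 30 epochs at lr 1e-5, while desk-scale runs use lr 1e-3 – 1e-2
(a tiny network on a few dozen patches needs a correspondingly larger Adam
step; the single-patch overfit oracle converges to CE < 0.05 in ≈450 steps
at lr 1e-3). Class imbalance is handled only by the 50/50
inclusive/exclusive patch stratification, not by loss weighting.
Fine-tuning loads **all** weights from the parent checkpoint and re-trains
all layers at the same learning rate (no freezing); before the first
effective update a fine-tuned model predicts voxel-identically to its
parent — the key transfer contract, asserted end to end. Checkpoints are
single-file npz containers carrying weights plus a provenance record (mode,
parent id, data-manifest hash, seed, loss history), so the
default → fine-tuned lineage is traceable and acyclic.

Whole-volume inference tiles the volume with half-stride sliding windows and
averages class-1 probabilities over overlaps; volumes smaller than the patch
are reflect-padded and cropped back. Binarization thresholds at 0.5
(argmax-equivalent for two classes), configurable.

## Longitudinal subtraction

The follow-up scan is rigidly registered to the baseline by minimizing mean
squared intensity difference over the 6 rigid parameters (Powell search,
phase-correlation translation initialization). Two numerical details matter
at phantom noise levels: the objective is evaluated on σ=1-voxel blurred
copies resampled with **cubic splines**, because linear resampling of a
noisy image at fractional offsets smooths its noise and biases the raw-MSE
optimum away from true alignment by up to half the noise variance (observed
as a ~2° rotation bias before the fix). The registered output volume itself
is produced with linear interpolation, matching the pipeline's resampling
scheme. If optimization cannot improve on the identity transform, the
identity is returned with an explicit not-converged flag. Deformable
(SyN-style) registration is intentionally out of scope; rigid matches the
generator's jitter model, and an external displacement field can be applied
upstream when real data require it.

After registration both volumes are z-normalized and resampled, and the
baseline is subtracted from the follow-up (`follow − initial`, so new
lesions are positive). On jitter-free pairs the subtraction of identical
inputs is exactly zero, and `k` new lesions produce exactly `k` positive
components above 4× the (normalized) noise SD once components below 4
voxels are discarded — isolated suprathreshold noise voxels occur at this
threshold by chance but never in 4-connected-voxel clusters.

## Lesionwise evaluation

Lesions are connected components under 26-connectivity (configurable to
6/18), with no minimum lesion size by default. Matching uses asymmetric
denominators, the standard resolution of many-to-many matches: a **true**
component is detected if it overlaps the union of predictions by ≥1 voxel
(sensitivity counts true components), and a **predicted** component is a
true positive if it overlaps the union of truth (PPV counts predicted
components) — one prediction spanning two lesions detects both and is not
penalized. Sensitivity is undefined for studies with no true lesions and
PPV for studies with no predictions; undefined values are flagged and
excluded from aggregation. Summaries are mean ± standard error
(sample SD / √n). The implementation is tested for exact agreement with a
brute-force flood-fill oracle over 10⁴ random mask pairs. Dice is
2|A∩B|/(|A|+|B|), defined as 1.0 when both masks are empty.

## Experiment harness and statistics

Studies are shuffled once into subsets of fixed size (10 by default). Fold
`k` trains on subsets `{k … k+m−1}` (cyclic, `m` = training size / subset
size) and tests on subset `k+m` (cyclic), one fold per subset-as-test, so
each study is tested exactly once per arm and multi-subset training sets
still rotate symmetrically. The default checkpoint — pretrained only on
source-domain phantoms, provenance kind `default` — is evaluated on subset 0
only; its comparisons with rotated arms therefore use unpaired tests.

Statistics follow the study design: one-way repeated-measures ANOVA across
rotated arms (textbook sum-of-squares partition, subjects = test studies
defined under every arm), paired two-tailed t-tests for fine-tuned vs
de-novo at each size (paired by test study), unpaired two-tailed t-tests
against the default arm, and Bonferroni correction with the family equal to
all pairwise tests reported per metric per table. t-tests delegate to scipy;
the RM-ANOVA is implemented directly and cross-checked against pingouin and
statsmodels to 1e-6. Zero-variance inputs yield a flagged degenerate result
instead of an exception. The table renderer emits one row per (size, arm)
plus a default row with mean ± SE and adjusted p-value columns.

## The direction-of-effect benchmark

The scaled-down analogue of the study's headline comparison, with conditions
fixed once: 32³ phantoms, 16³ patches, a 3-level U-Net with 4 base features;
a default model pretrained on 12 source-geographic phantoms for 10 epochs;
fine-tuned vs de-novo arms trained on 3 MS-like focal phantoms and evaluated
on 10 held-out focal phantoms; 5 master-seed replicates. Free desk-scale
choices: 10+10 patches per study without elastic copies (augmentation is
exercised elsewhere), Adam at lr 3e-3, and 60 arm epochs — a budget at which
the de-novo arm is *semi-converged* (it predicts, with false positives, but
has not saturated). That operating point is the faithful analogue of the
small-training-set regime this design targets, where de-novo training is
data-limited; with enough budget on these separable phantoms both arms
converge to near-perfect masks and the comparison becomes uninformative,
mirroring how the fine-tune/de-novo gap closes in clinical studies once
training sets grow large. The benchmark reports per-seed mean lesionwise PPV for both
arms and the number of replicates in which the fine-tuned arm's PPV is at
least the de-novo arm's; a seed where the de-novo arm predicts nothing
anywhere (no defined PPV) counts as a fine-tuned win only if the fine-tuned
arm itself produced predictions.

One property of this readout deserves emphasis: on intensity-separable
phantoms, lesions are the brightest structures, so a data-limited de-novo
model's most confident voxels are always inside true lesions. In replicates
where the de-novo arm has just begun to predict, it therefore emits only
small lesion cores — low sensitivity and Dice but lesionwise PPV at or near
1.0 — and can beat the fine-tuned arm on PPV alone. Clinical FLAIR behaves
differently (bright non-lesion structures make undertrained models
imprecise), so the fine-tuned arm's PPV advantage is less consistent on
phantoms than in the clinical setting this design emulates; the benchmark
reports whatever the replicates produce.

## Numerical and degenerate-input policy

Constant volumes cannot be z-normalized (explicit error). Placement that
cannot satisfy non-overlap within a bounded number of attempts raises an
explicit placement error, as does stratified sampling on a study with no
lesion-free window; experiment cohorts are screened at enrollment so every
training study supports stratification. Probability maps are clipped only
by construction (softmax averages); binarization validates its threshold.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; one master seed fans out per-purpose seeds
recorded in result manifests.

## Known limitations

Desk-scale training (tiny networks, dozens of patches, minutes of CPU) shows
direction-of-effect and contract correctness, not clinical performance;
clinical-scale accuracy numbers require institutional MRI cohorts and
GPU-scale 96³ training and are out of scope by design. The rigid
registration model cannot represent the deformable component of real
inter-scan change. The phantom's statistical simplicity means lesionwise
scores here are far higher than anything achievable on clinical data.
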