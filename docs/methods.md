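# Methods

`decontrast` implements a complete, desk-scale framework for removing the
effect of a gadolinium-based contrast agent from T1-weighted brain MRI by
image-to-image translation: three 3D U-Net-like generators, a patch-based
conditional GAN, and a two-tier validation (brain-masked image similarity;
tissue-volume fidelity).  Because real paired clinical T1ce/T1nce data live
in access-restricted hospital warehouses, the package ships a paired
phantom generator that emulates the statistical structure of such a data
set, so every experiment here is fully synthetic, seeded and reproducible
on one CPU.

## The translation problem

A T1ce acquisition differs from the T1nce acquisition of the same head in
two systematic ways: vascular and meningeal structures are brightened by
the contrast agent, and the gray-matter/white-matter contrast is perturbed.
Standard neuroimaging segmentation tools are validated on non-enhanced
images; feeding them T1ce volumes biases the tissue volumes they report.
The framework learns a voxel-wise mapping G: T1ce → T1nce so that
downstream tissue segmentation of G(T1ce) behaves like segmentation of the
real T1nce.

## Paired phantom generator (`phantom`)

Each synthetic subject is a set of nested ellipsoids on a common grid: a
WM core, a GM ribbon, a CSF shell, and two ventricular CSF ellipsoids, with
per-subject random axis lengths and centre jitter.  Tissue assignment is
hard (one-hot probability maps; no partial-volume mixing — a known
simplification).  Intensities follow the min-max-rescaled T1 convention:
WM 0.75, GM 0.55, CSF 0.20, background 0 by default, plus Gaussian
*texture* noise (σ = 0.01) that is part of the anatomy and therefore shared
by both images of a subject.

The enhancement operator produces the T1ce member:

    t1ce = clip( t1nce + δ·1[enhancing] + s·1[GM], 0, 1 )

where the enhancing compartment consists of thin meningeal shell patches
(random spherical caps of the outer shell) and dilated random tubes
(vessels), δ = 0.25 is the enhancement strength and s = +0.10 shifts the GM
mean toward WM (reduced GM/WM contrast).  δ and s are calibrated only so
that the *directions* of the clinical findings (similarity and
tissue-volume fidelity both favour synthetic T1nce) are reproducible at
desk scale; their magnitudes are not fitted to any clinical number.  The
shift must be large enough that the enhanced image's GM/WM overlap biases
the downstream segmenter consistently — at much smaller shifts the T1ce
segmentation is sometimes nearly as good as the T1nce one and the
tissue-volume comparison degenerates into noise.

Image quality is modelled as the field's three-axis 0/1/2 grading
(contrast, motion, noise).  Grades are sampled per acquisition with
probabilities chosen so that roughly one pair in six has a low-quality T1ce
while T1nce images are always of medium or good quality, mirroring the
selection rule of a paired clinical cohort.  Grades are *realised* by an
explicit degradation operator: grade-dependent compression of intensities
toward the foreground mean (factors 0, 0.25, 0.5), directional Gaussian
blur along a random axis (widths 0, 0.7, 1.5 voxels) and additive Gaussian
noise (sd 0, 0.01, 0.03).  Grade (0,0,0) is the identity, bit-exactly.

When a subject is materialised into the BIDS tree, each acquisition
additionally receives independent Gaussian *thermal* noise (σ = 0.02).
This matters: without it the two images of a pair would share one noise
realisation — something no pair of separate scans exhibits — and the
baseline SSIM(T1ce, T1nce) would be inflated to a level that no translator
(which cannot predict the test image's noise) could beat.

Default geometry is a 32³ grid with 6 mm voxels, chosen so the phantom's
intracranial volume lands near the adult human scale (≈1.3–2 L) and CPU
training takes minutes.  Grids up to the clinical 128³/1 mm are supported
by the same code.

What the phantom does *not* emulate: real cortical geometry, partial-volume
effects, lesions, bias fields, scanner/field-strength differences.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative mechanism of enhancement-induced segmentation bias, not
clinical performance.

## Preprocessing (`preprocess`)

In-scope steps are min-max intensity rescaling to [0, 1] (error on constant
images), a centred template crop (default 169×208×179, ties toward the
origin), and corner-aligned trilinear resampling (default to 128³; output
sample i of m maps to input coordinate i·(n−1)/(m−1)).  Bias-field
correction, affine registration to a template and skull stripping are
external preprocessing concerns: inputs are assumed grid-aligned, which the
phantom guarantees.  The quality rule maps grades to labels: any 2 → low,
else any 1 → medium, else good.  The split routine sends every pair with a
low-quality T1ce to a dedicated low-quality test set, holds out
round(fraction·n) of the remaining pairs (10 % of 256 pairs gives the
230/26 design), and is deterministic given its seed.

## Generators (`generators`)

All three variants map a single-channel volume in [−1, 1] to the same shape
through a tanh head; the data loader applies the affine maps from/to the
[0, 1] intensity convention.

* **Res-U-Net** — descending blocks of strided conv + instance norm +
  LeakyReLU(α = 0.2), each followed by a residual module of 1–3
  conv+LeakyReLU blocks with an additive skip; ascending blocks of
  transposed conv + ReLU with additive long skips; final upsample ×2 +
  conv + tanh.
* **Att-U-Net** — descending blocks of two conv + batch norm + ReLU
  stages with 2× average-pool downsampling (the downsampler is not
  specified in the reference description; average pooling was chosen over
  max pooling for its simpler gradient routing).  Ascending blocks
  upsample ×2 (trilinear), project channels, gate the encoder skip with an
  attention gate — coefficients = σ(ψ(ReLU(Wₓx + W_g g))) multiplied
  elementwise onto the skip — then concatenate and apply two conv + ReLU
  stages.  The final layer is also unspecified in the reference text; here
  it is a 1³ conv + tanh that predicts an additive *correction* to the
  input image (a global input residual, clipped to [−1, 1],
  `global_residual` in the config).  The residual head matters: the
  identity mapping is then the optimisation starting point, so small
  high-contrast structures (the phantom's ventricles) pass through intact
  instead of having to be reconstructed through the bottleneck — without
  it, a fraction of initialisations converge to solutions that erase them,
  which whole-volume L1 barely notices but local-structure metrics punish
  severely.  Batch statistics are used for normalisation in both training
  and inference (batch sizes here are 1–2 and the forward pass must be a
  pure function of its input for the determinism contracts).
* **Trans-U-Net** — a strided convolutional encoder, linear projection of
  the bottleneck voxels to tokens with a learned positional embedding,
  four pre-layer-norm transformer layers (multi-head self-attention +
  2×-wide feed-forward, residual connections), reshape, and a
  deconvolutional decoder with concatenated long skips.  The reference
  design ends in a softmax layer — a segmentation holdover that is
  degenerate for single-channel regression — so the head here is conv +
  tanh, deliberately.

Depth and width are configurable; the full-scale layout (depth 5 for
res/att, 4 for trans, 128³ input) and the desk-scale layout (depth 3,
base 4 channels, 32³) share one implementation.  Exact per-layer kernel
tables of the original networks are not reproduced; defaults follow the
cited reference architectures (kernel 3/4, stride-2 downsampling, channel
doubling capped at 8×), so parameter counts differ from the originals.
Weights are initialised N(0, 0.02), seeded.

The tensor machinery underneath (`decontrast.nn`) is a compact
reverse-mode autodiff on numpy with exactly the primitives these networks
need; its gradients are verified against central finite differences in the
test suite.

## Adversarial training (`adversarial`)

Patches: from a 128³ volume, 64³ patches at stride 50 give the 2×2×2 = 8
patch lattice; at desk scale, 16³ patches at stride 12 give the same
lattice on 32³ volumes.  The discriminator scores a channel-concatenated
(conditioning T1ce patch, candidate T1nce patch) pair through three
strided conv + LeakyReLU(0.2) blocks and a final conv + global average
pool, squashed by a sigmoid to a score in (0, 1) interpretable as p(real).

Two loss modes coexist deliberately, because the field's practice
(least-squares GAN for stability) and the log-loss formulation of the
objectives are both part of the design space:

* least_squares (default): L_G = mean(p(fake) − ℓ_real)² + λ·L1,
  L_D = ½·mean(p(real) − ℓ_real)² + ½·mean(p(fake) − ℓ_fake)².
* cross_entropy (literal): L_G = −log p(fake) + λ·L1,
  L_D = −½·log p(real) − ½·log(1 − p(fake)), with a 1e−7 floor inside
  logs.

λ = 1 by default (unweighted sum).  Soft labels are uniform draws from
narrow sub-intervals; the default `conventional` direction (real ∈
[0.7, 1.0], fake ∈ [0.0, 0.3]) is consistent with the losses' optima, and a
`paper_literal` mode with the two ranges swapped is available because the
opposite convention also circulates.  Patch scores enter the losses as
independent samples (not volume-averaged) by default.

Training protocol: generators are first trained alone with Adam on the L1
loss (batch 2); discriminators are pretrained against the frozen generator
(real vs generated patches); then both are trained jointly with alternating
1:1 updates at batch size 1, warm-started from the pretrained checkpoints.
The checkpoint kept is the epoch with the best mean training loss (L1 for
generator-only training, total L_G for the cGAN — the tie between L_G and
L1-only is genuinely open; total L_G was chosen as it is the optimised
objective).  Full-scale defaults are Adam(2e−4, β = 0.5/0.999), 300
epochs.  The desk-scale schedule uses Adam(2e−2, β = 0.9/0.999) with a 4×
step decay at epoch 45: at lower rates some initialisations sit on a loss
plateau of unpredictable length before reaching the converged basin, while
the higher rate crosses it reliably and the decay tail restores a quiet
final descent.  The pipeline additionally trains from two initialisations
(restarts) and keeps the one whose translations score the higher mean SSIM
on the *training* set: the L1 loss barely distinguishes a well-converged
generator from one with residual texture artifacts, whereas
local-structure fidelity separates them sharply, and scoring on training
data keeps the held-out sets untouched.  Non-finite losses abort with a
diagnostic; a warning is logged if the discriminator's real/fake scores
collapse to an indistinguishable constant for a full epoch.

## Similarity validation (`eval_similarity`)

MAE (reported in percent of the [0, 1] range), PSNR (data_range 1.0, +inf
at zero error) and single-scale SSIM (7³ uniform window, K1 = 0.01,
K2 = 0.03, population moments, reflective boundaries) are computed within a
brain mask — for clinical data the union of the two skull-strip masks; for
phantoms the ground-truth mask.  SSIM zeroes intensities outside the mask
before filtering and averages the SSIM map over mask voxels, so all three
metrics depend only on in-mask intensities.  Group comparisons use
two-sided paired t-tests with Bonferroni correction; zero-variance
difference vectors are flagged degenerate rather than given a p-value.

## Tissue-volume fidelity (`eval_segmentation`)

A deliberately simple stand-in segmenter — a three-class Gaussian
intensity mixture fitted by EM inside the brain mask, initialised at the
15/55/85th intensity percentiles, classes identified as CSF < GM < WM by
sorted mean — replaces the full unified-segmentation pipeline, whose
probability maps can equally be read from NIfTI and fed to the same
downstream operations.  Two numerical guards matter:

* each class sd is floored at 0.03 (the thermal-noise scale).  Without the
  floor, the WM class collapses onto the sharp intensity peak of denoised
  synthetic images (fitted sd → 0.01) and silently hands its boundary
  voxels to the broader GM class — a segmenter pathology that has nothing
  to do with translation quality;
* if the fitted means end up closer than 0.02 the maps are flagged
  degenerate (this happens under severe motion blur) but still returned,
  since low-quality images must still flow through the pipeline.

Binarisation assigns each voxel to its maximum-probability tissue (ties
broken GM > WM > CSF, fixed); volumes are voxel counts times voxel volume
in cm³; TIV is the sum of the three tissue volumes.  The normalised volume
differences between a reference segmentation I (real T1nce) and a
comparison J (T1ce or synthetic T1nce) are

    VD  = (V_t^I − V_t^J) / TIV^I × TIV̄        (signed; negative = J over-estimates)
    AVD = |VD|

with TIV̄ the mean reference TIV across the test sets — a constant rescale
that puts the numbers in cm³ without affecting comparisons.  Dice overlap
is reported per tissue.

## Pipeline, I/O and configuration (`io_cli`)

Volumes are NIfTI-1 via nibabel (isotropic voxel size in the header); the
dataset layout is BIDS-like with the `ce-gadolinium` filename entity
marking T1ce, JSON sidecars carrying grades, ground truth under
`derivatives/phantom-truth/`, and a root `manifest.tsv`.  The run
configuration is a single YAML file validated strictly (unknown keys are
rejected); one master seed derives all stage seeds by fixed offsets, and a
hash of the scientific configuration is embedded in the outputs.  The CLI
(`decontrast simulate|run-all|translate|evaluate`) is a thin layer over
the library.  `run-all` executes simulate → preprocess → split → train →
translate → evaluate and writes per-pair and summary CSV tables plus a
JSON summary.

## Problem sizes used by the shipped experiments

The test suite and the acceptance script run the desk-scale configuration:
36 phantom subjects (≈24 training pairs after the quality split), 32³
grid, attention-gated generator with base width 4, two training restarts
of 60 epochs each.  These sizes were chosen so a full run completes in
minutes on one CPU while leaving the directional findings — higher
similarity and smaller GM/WM/CSF volume errors for synthetic T1nce than
for T1ce — clearly resolved.

## Known limitations

* The phantom's hard tissue boundaries make segmentation easier than on
  real anatomy; absolute MAE/SSIM/AVD values are not comparable to
  clinical numbers, only the directions of the comparisons are meaningful.
* The stand-in segmenter is intensity-only (no spatial priors); its
  absolute volume errors on degraded images are large by clinical
  standards.
* cGAN training at desk scale is demonstrated for stability and API
  completeness; the shipped directional experiments use the
  generator-only attention U-Net, which the similarity tier already
  favours.
* Batch-norm layers use batch statistics at inference; checkpoints are
  exact only together with the batch composition convention used here
  (whole-volume batches).
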