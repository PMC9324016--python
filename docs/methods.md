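# Methods

## Model

The package implements a Retinex-theory enhancement pipeline for
endoscopic images.  The observed image `S` is modelled as the
element-wise product of a reflectance map `R` (an (H, W, 3) intrinsic
tissue/vessel image) and a single-channel illumination map `I`
broadcast over the colour channels:

    S = R ∘ I

Enhancement proceeds in three steps: a decomposition network estimates
`(R, I)`; an illumination-correction network (ICN) maps `I` to a
corrected map `Î`; a closed-form reflection-component enhancement (RCE)
sharpens vessel contrast in `R`; the enhanced image is `R_out ∘ Î`,
clipped to [0, 1].  All internal arithmetic is on [0, 1] floats; 8-bit
files are divided by 255 on read and rounded back on write.  Clipping
happens at recomposition, before any metric is computed on the result.

### Decomposition network

Input is the RGB image concatenated with its per-pixel channel maximum
(4 channels — the max is a cheap illumination prior, and only this
variant yields the published 207,748-parameter / 0.831 MB figure).  One
9×9 convolution lifts to 64 features, five 3×3 convolutions with ReLU
form the body, and a 3×3 convolution with sigmoid emits 4 channels that
split 3 + 1 into `R` and `I`.  Head and output layers carry no ReLU.
Both members of a training pair pass through the same weights.

Losses (L1 norms are means over elements, so magnitudes are
resolution-independent):

* invariable reflectance `L_ir = mean|R_abnormal − R_normal|`;
* illumination smoothness
  `L_is = Σ_i mean( |∇I_i| · exp(−λ_g |∇R̄_i|) )`, `λ_g = 10`, summed
  over both pair members; `R̄` is the plain average of the three
  reflectance channels; the gradient operator is forward differences
  with replicate padding (last row/column difference is zero),
  |horizontal| + |vertical| added; the exp weight uses the raw gradient
  with no extra smoothing;
* cross reconstruction
  `L_recon = Σ_i Σ_j λ_ij mean|R_i ∘ I_j − S_j|` with `λ_ij = 1` on the
  diagonal and 0.1 off it;
* total `L_decom = L_recon + 0.1 L_is + 0.01 L_ir`.

### Illumination-correction network

Three-level pyramid: `I` is max-pooled (2×2, stride 2; odd sizes floor)
into half- and quarter-resolution levels.  Each level runs a 3×3 entry
convolution and two residual blocks (conv–ReLU–conv plus skip) at 64
channels; the full-resolution branch adds a pyramid pooling module
(adaptive average pooling to 1/2/3/6 bins, per-bin 1×1 compression to
64/4 channels, bilinear upsampling, concatenation, 1×1 projection back
to 64, residual add).  Each level's final features are multiplied per
pixel by the attention map (computed once at full resolution, bilinearly
resampled to each level), then bilinearly upsampled and concatenated
into the next level with a 1×1 convolution halving the channels.  A
conv–ReLU–conv head with sigmoid yields `Î`.  No normalisation layers
anywhere.

The attention map stacks `[1 − I, G, B]` (inverse illumination plus the
green/blue channels of the input image, where vessel detail lives),
applies three parallel dilated 3×3 convolutions (rates 1, 2, 5; 3→1
channels, biased), takes the per-pixel mean of the three maps and a
sigmoid.  Dark regions get weights near 1; bright regions are
attenuated, which suppresses over-enhancement.  Disabling attention
skips the multiplication, which is exactly equivalent to an all-ones
map (asserted bit-for-bit in the tests).

The published per-branch depths/widths are not fully specified; the
choices above (entry conv + 2 residual blocks per branch, base width
64) are free parameters exposed through `ICNConfig`.  The resulting ICN
holds 511,573 parameters (2.046 MB) and makes no claim to match the
original's byte size.

ICN losses: `L_r = mean|R_abnormal ∘ Î − target|` and the same
edge-aware smoothness `L_i` as above, combined as `L_ICN = L_r + 0.1 L_i`.
The printed form of the reconstruction loss targets the abnormal image
itself, which would make the identity mapping optimal and contradicts
the stated goal of correcting toward normal illumination; the training
loop therefore supervises against the *normal* member of the pair
(abnormal→normal supervision).  The loss function itself is
target-agnostic, so both readings remain expressible.

### Reflection component enhancement

`stretch_channel`: `(I_c − μ_c) / (σ_c + τ)` per channel with that
channel's own mean and *population* standard deviation (well defined
for single-pixel channels; zero output for constant channels).  G and B
are stretched, R is kept unchanged.  Fusion:
`R_out = ((σ_G + σ_B)/2) · R_c + R`, where `σ_G, σ_B` are taken from
the **original** reflectance — taking them from the stretched map would
make the coefficient input-independent (stretched channels have
σ ≈ 1 / (1 + τ/σ) regardless of content), defeating the adaptive
intent.  `R_c` is not clipped before fusion; `R_out` is clipped once.
`τ` defaults to 0.5; raising it weakens the stretch, so fused contrast
(std of G) falls monotonically — the brightness of the *fused
reflectance* is essentially τ-invariant (the stretched channels are
zero-mean), brightness differences only appear in full reconstructions.
An all-channel stretch variant exists solely for ablation comparisons;
it visibly distorts colour.

## Training protocol

Two sequential stages with Adam (conventional β/ε), learning rate 1e-4,
batch size 8, inputs bilinearly resized to 224×224 by default, 30
epochs per stage.  The decomposition network trains first; during ICN
training its outputs enter as constants, so its weights are bit-identical
before and after (asserted).  No LR schedule, weight decay or gradient
clipping.  Initialisation is Kaiming fan-in for convolutions with zero
biases, seeded from the config; a user-supplied checkpoint can warm-start
either stage in place of unavailable pretrained weights.  Smoke-scale
runs in the tests and examples use 8 pairs at 64×64 (or 32×32) and
a few dozen steps via `max_steps`; these sizes are chosen so a full
two-stage smoke run finishes in minutes on one CPU core while still
showing the windowed-mean loss decrease and the end-to-end brightening
that the full protocol targets.

## Numerical engine

No deep-learning framework is used: `eien.autodiff` is a small
reverse-mode automatic-differentiation engine over numpy arrays with
exactly the primitives the networks need (broadcast arithmetic,
sigmoid/ReLU/|·|/exp, reductions, slicing/concatenation/padding,
stride-1 dilated convolution, 2×2 max pooling, and per-axis linear maps
that express bilinear resampling and adaptive average pooling).
Convolutions run as per-tap GEMMs on contiguous views of the padded
input — no patch gathering — and the input gradient is the transposed
convolution computed by the same routine with a flipped kernel.  Every
primitive is gradient-checked against central finite differences in the
test suite.  Parameters are float32; the loss oracles run in float64.

Tie-break and degenerate-input rules: max-pool backward routes the
gradient to the first argmax in each window; |·| has subgradient 0 at
exactly 0; constant channels stretch to all zeros; images smaller than
8×8 (two rounds of halving) are rejected.

## Synthetic phantoms

The paired datasets the method was built on are private, so training
and evaluation run on seeded phantoms that reproduce exactly the
structure the losses assume: a pinkish mucosa base (RGB ≈ 0.82/0.54/0.52)
with Gaussian-filtered low-frequency texture; curvilinear vessels drawn
as Gaussian-profile random-walk strokes that attenuate G fully, B by
0.85 and R by 0.25 of the vessel contrast (hemoglobin absorbs G/B far
more than R); a smooth off-centre spotlight field `0.25 + 0.75·exp(−d²/2σ²)`
with σ = 0.35 of the short side; the normal member is reflectance ×
field, the abnormal member uses the field raised to `exposure_gamma`
(default 2.5, a distinctly under-exposed capture), plus Gaussian noise
(σ = 0.01) and clipping.  A deterministic quarter of dataset pairs
replaces the abnormal member with the normal one brightened by the
Y-channel gamma-0.5 augmentation (full-range BT.601 YCrCb, exact matrix
inverse), forming the high-light class.

The two members therefore share reflectance content and differ by a
smooth multiplicative field — the generator self-check verifies the
pixel-wise ratio correlates > 0.9 with the field.  What the phantoms do
*not* model: specular highlights, motion blur, sensor noise structure,
colour non-linearities of real endoscopes, and real vessel morphology.
Passing tests demonstrate that the optimisation and wiring behave as
designed under the Retinex assumption, not clinical-grade enhancement
on real endoscopy.

## Metrics

PSNR uses MAX = 1 on [0, 1] data (dB values are scale-invariant given
consistent normalisation); identical images report +inf.  SSIM uses the
11×11 Gaussian window (σ = 1.5), K1 = 0.01, K2 = 0.03, dynamic range 1,
no sample-covariance correction, border crop of 5 pixels, channels
averaged; it matches `skimage.metrics.structural_similarity` with
Gaussian weights to ~1e-9 and the tests assert 1e-3.  GMSD computes
1/3-scaled 3×3 Prewitt gradients of the BT.601 luminance with symmetric
boundary handling, similarity stabiliser c = 0.0026 (the canonical 170
rescaled from the 255² scale), and reports the population standard
deviation of the similarity map; no down-sampling prefilter is applied.
NIQE is out of scope: it requires a natural-scene statistics model that
cannot be refitted from the available material.

## Known limitations

* The ICN branch depths/widths are a design choice, not a reproduction;
  only the decomposition network's size is architecture-determined.
* Smoke-scale training (dozens of steps) demonstrates optimisation
  trends, not converged enhancement quality.
* The engine is CPU-only and single-process; throughput is adequate for
  the shipped problem sizes, not for large-scale training.
* Reproducibility is exact under a fixed seed on a given
  BLAS/numpy build; across builds, reductions may reorder and results
  can differ in the last bits.
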