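# Methods

This note documents the science and the engineering decisions behind
`danisim`: what the model assumes, what the synthetic phantoms do and do
not emulate, which parameters matter, and where the design was genuinely
open.

## Problem setting

Given one baseline T1-like brain volume of a subject with known age θ and
diagnosis code d ∈ {0,1,2,3} (CN, SMC, MCI, AD), the simulator produces a
sequence of A volumes indexed by age bin, depicting plausible past and
future appearance of that brain under ageing/neurodegeneration. The
underlying biological assumption throughout is that normalized image
intensity proxies tissue density and is **monotonically non-increasing in
age**, with faster decline at more severe diagnoses.

Volumes are assumed already rigidly co-registered and skull-free. The
phantom generator emits them that way; for real data, registration and
skull-stripping must happen upstream — they are deliberately out of scope.

## Progression model

Each of the T axial slice positions carries an independent model set: a
convolutional encoder E (stride-1 convs with 2× average pooling down to a
4×4 core, dense head, tanh — the latent code lives in [−1,1]^latent,
matching the uniform prior), a generator G (dense stem from
latent+one-hot(a)+one-hot(d), 2× nearest-neighbour upsampling with stride-1
convs, sigmoid output in [0,1]), an image discriminator Db (conv/pool
classifier) and a latent discriminator Dz (3-layer MLP). Average
pooling/nearest upsampling instead of strided/transposed convolutions keeps
the hand-written gradients simple and avoids checkerboard artefacts; the
nets run on the package's own float64 numpy autodiff engine, which makes
every run single-threaded and bit-reproducible.

Age is discretized into A equal-width bins over the training age range,
with center m_i = mean age of the samples in bin i (midpoint when empty),
internal spread δ_i = max−min age in the bin (bin width with fewer than two
samples), and fuzzy Gaussian membership μ_i(θ) = exp(−(θ−m_i)²/(2σ_i²))
with σ_i = c·δ_i. The width factor c defaults to 1.0; only the
proportionality σ_i ∝ δ_i is essential, c rescales how sharply the
reconstruction loss concentrates on the input's own bin. Binning (rather
than conditioning on scalar age) stops the encoder from memorizing exact
ages in the latent space. Memberships are fuzzy, not probabilistic: they
are never normalized across bins.

### Losses

All losses act on the [0,1]-rescaled slice (per-slice standardization to
zero mean/unit sd followed by min–max rescaling; the records are kept and
inverted at simulation time). Working in [0,1] keeps the monotonicity and
ratio semantics well defined — sums of zero-mean signals can be negative,
which the ε = 0.1 regularizer alone would not fix — while the
standardization step still removes scanner gain and offset. L2 throughout
means mean squared error over pixels, so loss magnitudes are comparable
across image sizes.

* Reconstruction: Σ_i μ_i(θ)·MSE(X, G_i). The membership weights the
  *error*, not the image: scaling the image by μ_i would corrupt the
  intensities being constrained by the other losses.
* Voxel monotonicity: ½[MSE(G_a, min of earlier outputs) + MSE(G_a, max of
  later outputs)], element-wise min/max over the sequence prefix/suffix; at
  a boundary bin only the defined term is kept, at full weight.
* Regional progression: for each region mask r_q (with voxel count s_q) and
  each other time point o, the squared gap between the regressor prediction
  and the generated later/earlier ratio (Σ[G⊙r]+ε)/(Σ[G⊙r]+ε), multiplied
  by s_q and normalized by R(A−1). The size weighting favours consistent
  intensity in large regions and makes the loss robust to noise. The
  deviation is squared — an unsquared difference would be sign-indefinite
  and could be driven to −∞.
* Adversarial terms: the standard non-saturating BCE pair for each
  discriminator. The bundle logs the discriminator cross-entropies;
  the generator/encoder sides enter the weighted objective.

Discriminators are trained on their plain (unweighted) cross-entropies;
the PWF weights scale the generator/encoder-side terms and the logged
total. Weighting the discriminator updates themselves (w_b ≈ 0.002) would
effectively freeze them.

### PWF schedule

f_ℓ(t) = ϱ^t·b_ℓ + (1−ϱ^t)·b_ℓ·v^{d_ℓ}, with defaults ϱ = 0.99, v = 10,
shapes (b_reg, b_vox, b_b, b_z, b_rec) = (1.25, 1.25, 0.002, 0.05, 100)
and directions (+1, +1, +1, +1, −1). So reconstruction starts at weight 100
and decays toward 10, while the other four ramp up toward b·v: training
first learns a faithful conditional autoencoder, then progressively
enforces biological progression and realism. The shape/direction grid for
re-tuning (`danisim.pwf.DEFAULT_GRID`) spans b_reg, b_vox ∈ [1,2] step
0.25, b_b ∈ [0.001,0.004] step 0.001, b_z ∈ [0.05,0.1] step 0.01,
b_rec ∈ [75,175] step 25 and directions ±1; `grid_search` draws seeded
points without replacement and scores them with a caller-supplied
validation criterion (the CLI uses the final-epoch total loss of a short
training run on the central slice).

### Training

Per mini-batch the update order is: Db step, Dz step, then one joint E+G
step on the PWF-weighted objective (ADAM, α = 2·10⁻⁴, β₁ = 0.5, gradient
clipping at norm 10 as an engineering safeguard; a non-finite objective
raises a divergence error carrying the last good checkpoint). All T slice
models start from a common initialization — a model pre-trained for a small
number of iterations (default 100) on central-slice data — and share the
same schedule and seed-derived randomness; given that initialization they
are independent and could be trained concurrently by any scheduler (this
implementation runs them sequentially).

At inference the T generated slices for each time point are fused by a
Gaussian-weighted average over the ±2 nearest neighbours (σ = 1.5 slice
units, weights renormalized at the stack boundary). Smoothing is applied
to the generated outputs; it is linear and preserves the local intensity
range.

## Regional regressors

LR_{n,q} predicts the regional intensity ratio between baseline age o and
follow-up age a given diagnosis: ratio = sigmoid(β₀ + β₁·o + β₂·(a−o) +
β₃·d), fitted by least squares on logit-transformed ratios (clipped to
[10⁻⁴, 1−10⁻⁴]). This "logistic regressor" is a sigmoid-link regression of
a bounded continuous ratio, not a classifier — the target is a ratio in
(0,1] and the underlying decline is monotone and saturating, so a
sigmoid link is the natural bounded form. Sample pairs where regional
intensity increased (ratio > 1) are removed before fitting: under the
monotone-tissue-loss assumption they represent noise. At zero age gap the
prediction is pinned to exactly 1 by construction, and predictions are
clamped to (0,1]; with fewer than 4 filtered samples a region falls back to
the identity predictor (flagged). Region size enters the training loss,
not the fit. ε = 0.1 is shared between sample extraction and loss
evaluation so the two ratio definitions coincide.

Region masks come from an atlas slice: every base label plus one eroded and
one dilated variant per configured radius (empty variants discarded).
Masks may overlap; their union covers at least the foreground. The
augmentation adds robustness to subject-to-subject boundary variability.

## Super-resolution

Cross-slice smoothing trades artefact suppression for blur. The SR stage
is a *same-grid restoration* network — no upsampling factor — trained
separately from the main system on pairs (LR = the trained model's own
reconstruction of a training scan at its true age bin, slice-smoothed;
HR = the preprocessed scan itself). The network is a small densely
connected stack of 3D convolutions with a zero-initialized residual head,
so the untrained network is exactly the identity; training is patch-based
(configurable patch size) to keep memory flat, with a voxel-wise MSE
objective. Outputs are clipped to [0,1] and never change volume shape.

## Personalization and simulation

Personalization fine-tunes *all* slice-model parameters on the single
baseline scan for a fixed number of iterations (default 50), with all
losses active and the PWF weights held at their final-epoch values (the
schedule has essentially converged there, and a fine-tune should continue
the regime training ended in, not restart it). The SR network is frozen.
The input's age bin is the bin whose interval contains θ (ties to the
lower bin); diagnosis is held fixed along the simulated sequence.

Simulation encodes each slice once, generates all A conditioned outputs,
smooths across slices, applies SR, and inverts the stored per-slice
normalization, so outputs live in the input's intensity range. Axial
slices outside the modelled range keep their baseline content. Ages
between bin centers are produced by linear interpolation of the two
bracketing volumes; extrapolation beyond [m₁, m_A] is refused.

## Synthetic phantoms

The generator emulates exactly the structure the biological constraints
assume: longitudinal T1-like volumes whose per-region mean intensity
declines monotonically with age at diagnosis-dependent rates, with known
ground truth. A phantom is an ellipsoidal foreground on zero background;
each axial slice is tiled into grid-sector regions intersected with the
foreground. Region q of a subject with diagnosis d has mean intensity

    base_q · gain_p · (1 − w_q · κ_d / (1 + exp(−(θ − τ)/s)))

with defaults κ = (0.05, 0.12, 0.22, 0.35) across CN/SMC/MCI/AD (κ
non-decreasing with severity is enforced), inflection age τ = 75 y, slope
s = 5 y, per-region severity weights w_q uniform in [0.4, 1.0], and a
per-subject gain in [0.9, 1.1] standing in for scanner differences.
Defaults for cohort structure follow the ageing-cohort regime the model
targets: ages 63–87, 2–5 visits at ~1 y spacing with ±0.2 y jitter, and
diagnosis prevalences (0.28, 0.04, 0.54, 0.14). Additive Gaussian noise of
configurable sd is applied to foreground voxels.

Two design points deserve emphasis:

* **A stable reference region is load-bearing.** Per-slice normalization
  is an increasing affine map, pinning the zero background to 0 and the
  brightest structure to 1. If every region declined at the same relative
  rate, that map would absorb the decline completely and normalized data
  would carry no progression signal at all. Real atrophy is regionally
  heterogeneous relative to stable tissue; the phantom encodes this with
  the severity weights w_q plus region 1 as a non-declining, brightest
  reference (w = 0). With that anchor, normalized regional ratios equal
  the generative ratios exactly in the noiseless case, which is what makes
  regressor-recovery testing against the closed-form curve meaningful.
* **What phantoms do not emulate:** anatomy, tissue texture, bias fields,
  scanner/site effects, misregistration, skull, morphological (shape)
  atrophy — intensity decline stands in for tissue loss. Tests passing on
  phantoms therefore demonstrate that the machinery (losses, schedules,
  training, personalization, evaluation) behaves as specified on data
  satisfying its assumptions; they do not certify image realism or
  volumetric accuracy on clinical MRI.

## Evaluation

Region volume = count of voxels inside a mask with intensity above a
threshold; total brain volume = the same count over the foreground mask;
Err = |v_sim/tb_sim − v_real/tb_real|·100. The measurement is symmetric
and scale-invariant (threshold rescaled alike). On phantoms the masks come
from the ground-truth atlas; for real data externally produced
segmentation masks can be plugged into the same interface. Cohort
reporting gives per-region mean ± sample sd across subjects (sd = 0 for a
single subject).

## Problem sizes and numerical choices

The shipped defaults are full-scale (T = 95 slices, 128×128, A = 10,
latent 200, 300 epochs, batch 100). The test suite and worked examples run
deliberately small configurations — 16×16 slices, T = 3–5, A = 3–4,
cohorts of 8–200 subjects, ≤ 30 epochs — chosen so the complete pipeline
and the training-dependent properties execute quickly on one CPU while
still exercising every code path. Probabilities inside cross-entropies are
clipped at 10⁻⁷; ratios at 10⁻⁴ before logit; ties in element-wise min/max
route gradient to the first argument; equal-width age binning uses a
right-closed last bin. The toy training configurations use a faster PWF
decay (ϱ = 0.9) so the schedule traverses its regimes within the short
epoch budget; all published defaults remain in place for full-scale runs.

## Known limitations

Slice models are trained independently; coherence relies entirely on the
shared initialization, shared schedule and output smoothing. The sigmoid
link of the regional regressors is a modelling choice — the true
functional form of regional decline is unknown and only locally
approximated. Personalization has no quantitative stopping rule; the
iteration count is exposed in configuration. The numpy engine is CPU-only
and single-threaded: full-scale training is possible but slow, and the
design target of this implementation is correctness and reproducibility at
desk scale rather than cluster throughput.
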