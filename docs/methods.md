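# Methods

## Model

`pvae` implements a variational autoencoder whose latent variables are
discrete spike counts. Both the approximate posterior and the prior are
factorized Poisson distributions with a multiplicative residual
parameterization: the prior carries learnable rates `r ∈ R_{>0}^K`, the
encoder outputs per-input deviations `δr(x)` (as unconstrained `log δr`,
exponentiated), and the posterior rates are `λ = r ⊙ δr(x)`. The
parameterization is fully general — any pair of positive prior/posterior
rates is reachable — and makes the prior-matching point explicit: `δr = 1`
gives posterior = prior and zero KL.

The negative ELBO per sample is

    L = E_{z ~ Pois(λ)} ‖x − dec(z)‖² + β · Σ_i r_i f(δr_i),
    f(y) = 1 − y + y·log y,

where `f ≥ 0` with equality only at `y = 1`. The KL term is a metabolic
cost on firing-rate deviations, structurally similar to the L1 penalty of
classical sparse coding. With a linear decoder `x̂ = Φz` and an
overcomplete latent space (`K > M`) the model is amortized sparse coding,
and the reconstruction expectation is available in closed form for any
factorized posterior with mean `μ` and variance `v`:

    E‖x − Φz‖² = ‖x − Φμ‖² + Σ_k v_k ‖Φ_k‖²,

which for Poisson latents (`μ = v = λ`) is `‖x − Φλ‖² + λᵀ diag(ΦᵀΦ)`.

### Relaxed Poisson sampling

Counts are generated by the inter-event-time construction of a homogeneous
Poisson process: draw `n_exp` exponential wait times
`Δt_j = −log(u_j)/λ` (reparameterized through uniform noise), accumulate
arrival times `S_n`, and count arrivals inside the unit window. The hard
indicator `1[S_n < 1]` is relaxed to `sigmoid((1 − S_n)/T)`; at `T = 0`
the hard comparison is used (never the sigmoid limit, avoiding 0/0) and
counts are exact integers. Every evaluation-time quantity uses `T = 0`.

`n_exp` is chosen per batch as the smallest `n` with Poisson CDF
`(n; λ_max) ≥ 0.99999`, capped at 512 to bound the `n_exp × B × K` memory
footprint (the cap logs a warning; mass beyond the uncapped choice is
below 1e-5). Rates are floored at 1e-6 before sampling so wait times stay
finite; `log δr` is clamped to ±8 before exponentiation.

Internally the whole sampling chain is a single autodiff node whose
backward pass applies the analytic pathwise derivative
`dz/dλ = Σ_n σ'_n · S_n/(λT)` — identical to what the elementary-op chain
produces (a unit test asserts agreement to 1e-9) but without
materializing the intermediate tapes.

Two further training modes exist: a *hard-forward* surrogate-gradient
mode (integer counts forward, relaxed gradients backward; off by default
because it trains worse than the fully relaxed sampler) and a
*straight-through* estimator on the count scale, kept only as a contrast
case in the gradient-agreement analysis.

### Temperature annealing

Training anneals `T` from 1.0 to 0.05 over the first half of the steps
(linear by default; an exponential/log-linear mode is available), then
holds `T = 0.05`. The same schedule drives Gumbel-Softmax sampling for
categorical latents.

### Alternative latent families

Gaussian (standard-normal prior), Laplace (unit Laplace prior), and
Categorical (uniform prior, Gumbel-Softmax relaxation, one-hot argmax at
evaluation) families share the same encoder/decoder scaffolding, with
textbook closed-form KLs. Gaussian variants with a `relu` or `exp`
activation applied to sampled latents test whether positivity alone
reproduces the Poisson behavior. Categorical latents split the budget `K`
into `K/C` variables of `C = 8` categories (the factorization is not
canonical; it is configurable).

## Autodiff

No GPU/tensor framework is used; gradients come from a small reverse-mode
autodiff engine over float64 numpy arrays (`pvae.autodiff`), covering the
operations these models need (affine maps, strided convolution via
im2col, the usual elementwise ops, reductions, cumsum, log-softmax) plus
an Adam optimizer. All operations are verified against central finite
differences in the test suite.

## Sparse-coding baselines

ISTA iterates `z ← soft_threshold(z + ηΦᵀ(x − Φz), ηβ)` with `η = 1/L`
from a power-iteration estimate of `L = λ_max(ΦᵀΦ)`; written as a
proximal-gradient step this provably descends `‖x − Φz‖² + 2β‖z‖₁`, and
the objective trace records that functional. LCA integrates
`τ u̇ = Φᵀx − u − (ΦᵀΦ − I)a` with `a = soft_threshold(u, λ_lca)`
(hard-threshold variant by flag), whose fixed points are critical points
of the same objective at `β = 2λ_lca`; the two optimizers agree within 1%
on matched instances. Dictionary learning alternates inference with plain
gradient updates on the reconstruction term and unit-norm column
projection. `lca_on_fixed_dictionary` sweeps LCA thresholds against a
dictionary exported from a trained amortized model to quantify the
amortization gap.

## Synthetic data

The generator replaces downloaded natural images with Gaussian
random-phase images whose amplitude spectrum is `1/f` (exponent 1 by
default), overlaid with 12 random Gabor splats per image to create sparse
oriented structure. Whitening uses the classical frequency-domain filter
`R(f) = f·exp(−(f/f0)⁴)` with `f0 = 0.4 × Nyquist`, followed by per-image
zero-mean/unit-variance contrast normalization; images are tiled into
non-overlapping 16×16 patches (row-major flattening, image-scan order)
and split 90/10 train/val by seeded shuffle.

What this emulates: approximately decorrelated pixels after whitening,
heavy-tailed marginals (kurtosis > 3 with overlays on), and oriented
local structure — the statistical regime sparse coding assumes. What it
does not: phase alignment across scales, occlusion, and the full
higher-order statistics of photographic images. Tests passing on this
fixture demonstrate mechanism (sparsification, filter localization,
rate-distortion behavior), not photographic-image performance.

## Metrics

- **Lifetime sparsity** (per latent `j` over `N` stimuli):
  `s_j = (1 − 1/N)⁻¹ (1 − (Σ_i z_ij)²/(N Σ_i z_ij²))`, in [0, 1]; 1 for a
  one-stimulus responder, 0 for a uniform responder. Responses are
  posterior samples at `T = 0`. For signed families the statistic is
  computed on magnitudes `|z|`: selectivity must not depend on sign, and
  a unit-variance Gaussian noise latent then scores `1 − 2/π ≈ 0.363`
  (the squared-response alternative would pin it at 2/3, swamping the
  selectivity signal with sampling noise). All-zero latents score 0 with
  a warning.
- **Active fraction**: collapsed latents separate as a low mode in the
  histogram of log10 per-latent KL. The dead/alive threshold is the
  midpoint of the widest interior empty gap of a Freedman-Diaconis
  histogram; with no empty gap (unimodal KLs) an absolute 0.01-nat
  fallback applies.
- **Representations** for downstream tasks are deterministic: `log δr`
  (Poisson), `μ` (Gaussian/Laplace), flattened logits (Categorical).
- **KNN sample efficiency**: k = 5, Euclidean, label budgets
  {200, 1000, 5000} drawn without replacement from a train pool, scored
  on a disjoint test pool, averaged over 10 resamples.
- **Shattering dimensionality**: mean logistic-regression accuracy over
  all C(c, c/2) balanced dichotomies (complementary assignments counted
  separately; 252 for ten classes), L2-regularized with C = 1.
- **Seed protocol**: five seeds per configuration, t-distribution 99%
  CIs, paired t-tests against a baseline with Benjamini-Hochberg FDR
  control at q = 0.01. Zero-variance paired differences are flagged
  rather than silently producing NaN.

## Numerical and design choices

- Reconstruction likelihood is Gaussian with fixed unit variance, so the
  reconstruction term is plain squared error; the linear decoder has no
  bias and no output nonlinearity (the sparse-coding generative model).
- The KL is always analytic, never sampled; training uses one MC sample
  per step for the reconstruction term by default.
- Adam at learning rate 1e-3, batch size 64. The convolutional encoder is
  three stride-2 conv layers of widths 32/64/128 with ReLU and an affine
  head — deliberately minimal; it exists to demonstrate encoder-capacity
  (amortization) effects, not to maximize performance.
- Sigmoid arguments are clipped at ±700 before exponentiation; uniform
  draws are clipped away from {0, 1} before logs.
- A single integer seed determines everything: initialization, batch
  order, sampling noise, and evaluation streams are spawned as named
  independent substreams (CRC-stable across processes).

## Problem sizes used in the tests

The training-based checks run at deliberately small scale, chosen as the
smallest sizes at which the qualitative phenomena are stable: the
Poisson-vs-Gaussian comparison uses 2,560 patches of 16×16 pixels
(40 synthetic 128×128 images), K = 64 latents, and 20,000 Adam steps; the
rate-distortion sweep uses 8×8 patches, K = 16, and 4,000 steps per β.
At this scale the Poisson count-noise term `λᵀdiag(ΦᵀΦ)` is comparable to
the mean-reconstruction error, so the rate-distortion monotonicity check
measures distortion as the posterior-mean reconstruction error
`‖x − Φλ‖²` on the training pool; on the small validation pool a handful
of extrapolated rate outliers otherwise dominate the mean.

## Known limitations

- Homogeneous Poisson only; no over/under-dispersed count families.
- Convolutional *decoders* are not implemented (the closed-form loss and
  all analyses here require the linear generative model).
- The categorical factorization (C = 8) is a convention, not a calibrated
  choice.
- Filter "Gabor-likeness" is assessed by proxy statistics (spatial energy
  concentration, orientation-binned spectral power), not by Gabor fits.
- At desk scale the undercomplete K = 64 setting limits achievable
  sparsity; the amortized-sparse-coding regime proper (K > M) is
  supported but slower to train, so the default tests stay undercomplete.
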