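# pvae

Poisson variational autoencoders: spike-count latent variables, amortized
sparse coding, and representation-geometry analysis — in pure
numpy/scipy, with scikit-learn style estimators.

## The problem

Variational autoencoders normally use continuous Gaussian latents, but
biological neurons communicate in discrete spike counts with
approximately Poisson statistics over short windows. This package
implements a VAE whose posterior and prior are both Poisson:

- the prior has learnable firing rates `r`;
- the encoder outputs multiplicative *deviations* `δr(x)` from those
  expectations, giving posterior rates `λ = r ⊙ δr(x)`;
- sampling uses a **relaxed Poisson reparameterization**: counts are the
  number of reparameterized exponential inter-event times that fit in a
  unit window, with the hard threshold softened by a temperature-`T`
  sigmoid during training and exact integer sampling (`T = 0`) at
  evaluation.

The resulting loss is

```
L = E_{z~Pois(r⊙δr)} ‖x − dec(z)‖²  +  β Σ_i r_i f(δr_i),    f(y) = 1 − y + y log y,
```

whose KL term is a *metabolic cost* on firing-rate deviations. With a
linear decoder `x̂ = Φz` the model is **amortized sparse coding**, and the
reconstruction term has the closed form
`‖x − Φλ‖² + λᵀdiag(ΦᵀΦ)` — used both as an exact training loss and as
the ground truth for validating the pathwise gradient estimator.

Also included: Gaussian / Laplace / Categorical (Gumbel-Softmax) latent
families for controlled comparisons, classical sparse coding (ISTA and
LCA inference, dictionary learning, amortization-gap sweeps), a
synthetic whitened natural-patch generator (no downloads), and the
evaluation suite: lifetime sparsity, dead-neuron (active-fraction)
analysis, KNN sample-efficiency, shattering dimensionality, and a
multi-seed statistical protocol (99% CIs, paired t-tests, BH-FDR).

Who it is for: researchers in computational neuroscience / NeuroAI who
want an interpretable, fully seeded, CPU-sized testbed for spike-count
generative models and their relationship to sparse coding.

## Worked example

```python
import numpy as np
from pvae import VAE
from pvae.synthetic_data import make_patch_dataset
from pvae.metrics import lifetime_sparsity, active_fraction
from pvae._rng import spawn

ds = make_patch_dataset(n_images=40, size=128, seed=0)   # 2560 whitened 16x16 patches
model = VAE(latent_dim=64, latent_family="poisson", n_steps=4000,
            batch_size=64, beta=1.0, random_state=0).fit(ds.train)

state = model.encode_state(ds.val)
counts = spawn(0, "demo").poisson(state.posterior_rates.data)  # integer spikes, T=0
_, sparsity = lifetime_sparsity(counts.astype(float))
active, _ = active_fraction(model.kl_per_latent_)
print(f"val MSE            {model.eval_mse(ds.val):.1f}")
print(f"lifetime sparsity  {sparsity:.3f}")
print(f"active fraction    {active:.3f}")
print(f"mean firing rate   {state.posterior_rates.data.mean():.2f}")
```

prints

```
val MSE            137.1
lifetime sparsity  0.675
active fraction    1.000
mean firing rate   1.28
```

Reading the output: the model reconstructs 256-pixel whitened patches
with a mean squared error of ~137 per patch while keeping every latent
informative (no posterior collapse: active fraction 1.0) and responding
selectively (mean lifetime sparsity 0.68 on integer spike counts; 1.0
would mean each unit fires for exactly one stimulus). A matched
Gaussian-latent model trained the same way reconstructs better but with
markedly lower sparsity and a fraction of its latents collapsed — the
acceptance test `test_poisson_vae_is_sparser_and_livelier_than_gaussian_control`
makes that comparison at 20k steps.

The same estimators compose with scikit-learn:
`model.transform(X)` returns the deterministic representation (`log δr`)
for downstream classifiers, and `pvae.DictionaryLearner` exposes classic
sparse coding with the same `fit`/`transform` surface.

A command-line layer mirrors the library for config-driven runs:

```bash
pvae train --config experiment.yaml
pvae sweep --config experiment.yaml --betas 0.2,1,5 --out sweep.csv
pvae compare-gradients --config experiment.yaml
```

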