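"""Posterior/prior latent families and their KL divergences.

The Poisson family uses a multiplicative residual parameterization: the
prior has learnable rates ``r`` and the encoder outputs per-input deviations
``δr``, giving posterior rates ``λ = r ⊙ δr``. When ``δr = 1`` the posterior
equals the prior and the KL vanishes. The KL between the two Poisson
distributions reduces to a metabolic-cost form

    KL = Σ_i r_i · f(δr_i),    f(y) = 1 − y + y·log y ≥ 0,

which penalizes firing rates that deviate from the prior, mirroring the
sparsity penalty of classical sparse coding.

Gaussian, Laplace and Categorical (Gumbel-Softmax) families are provided as
alternatives, with standard closed-form KLs to their respective priors
(standard normal, unit Laplace at zero, uniform categorical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import relaxed_poisson as rp
from ._rng import as_generator
from .errors import ConfigError, ContractError, InvalidRateError

__all__ = [
    "LATENT_FAMILIES",
    "PoissonLatentState",
    "GaussianLatentState",
    "LaplaceLatentState",
    "CategoricalLatentState",
    "poisson_posterior_rates",
    "metabolic_cost",
    "poisson_kl",
    "gaussian_kl",
    "laplace_kl",
    "categorical_kl",
    "apply_latent_activation",
]

LATENT_FAMILIES = ("poisson", "gaussian", "laplace", "categorical",
                   "gaussian+relu", "gaussian+exp")

#: log δr is clamped to this range before exponentiation (numerical stability).
LOG_DEVIATION_CLIP = 8.0


def _check_positive(name: str, x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise InvalidRateError(f"{name} must be finite")
    if np.any(x <= 0):
        raise InvalidRateError(f"{name} must be strictly positive")


# --------------------------------------------------------------------- states
@dataclass
class PoissonLatentState:
    """Poisson posterior ``Pois(r ⊙ δr)`` against prior ``Pois(r)``."""

    log_prior_rates: ad.Tensor   # (K,), learnable
    log_deviation: ad.Tensor     # (B, K), encoder output

    def __post_init__(self):
        self.log_deviation = self.log_deviation.clip(-LOG_DEVIATION_CLIP,
                                                     LOG_DEVIATION_CLIP)

    @property
    def prior_rates(self) -> ad.Tensor:
        return self.log_prior_rates.exp()

    @property
    def deviation(self) -> ad.Tensor:
        return self.log_deviation.exp()

    @property
    def posterior_rates(self) -> ad.Tensor:
        return self.prior_rates * self.deviation

    def kl_per_latent(self) -> ad.Tensor:
        """Per-latent KL averaged over the batch, shape (K,)."""
        r = self.prior_rates
        logd = self.log_deviation
        d = self.deviation
        f = 1.0 - d + d * logd          # f(y) = 1 − y + y·log y
        return (r * f).mean(axis=0)

    def kl(self) -> ad.Tensor:
        """Total KL per sample (scalar, batch mean of the sum over latents)."""
        r = self.prior_rates
        d = self.deviation
        f = 1.0 - d + d * self.log_deviation
        return (r * f).sum(axis=1).mean()

    def mean(self) -> ad.Tensor:
        return self.posterior_rates

    def variance(self) -> ad.Tensor:
        return self.posterior_rates

    def rsample(self, temperature: float, rng, n_exp: int | None = None,
                hard_forward: bool = False) -> ad.Tensor:
        lam = self.posterior_rates
        if n_exp is None:
            n_exp = max(1, rp.required_exponential_samples(float(lam.data.max())))
        if temperature == 0:
            return ad.Tensor(rp.sample_exact(lam, rng).astype(np.float64))
        sampler = rp.rsample_hard_forward if hard_forward else rp.rsample
        return sampler(lam, n_exp, temperature, rng).counts

    def representation(self) -> np.ndarray:
        """Deterministic representation: log δr (pre-exponentiation encoder output)."""
        return self.log_deviation.data


@dataclass
class GaussianLatentState:
    """Factorized Gaussian posterior against a standard normal prior."""

    mean_: ad.Tensor      # (B, K)
    log_std: ad.Tensor    # (B, K)

    @property
    def std(self) -> ad.Tensor:
        return self.log_std.clip(-10.0, 10.0).exp()

    def kl_per_latent(self) -> ad.Tensor:
        mu, s, logs = self.mean_, self.std, self.log_std.clip(-10.0, 10.0)
        return (0.5 * (mu * mu + s * s - 1.0) - logs).mean(axis=0)

    def kl(self) -> ad.Tensor:
        mu, s, logs = self.mean_, self.std, self.log_std.clip(-10.0, 10.0)
        return (0.5 * (mu * mu + s * s - 1.0) - logs).sum(axis=1).mean()

    def mean(self) -> ad.Tensor:
        return self.mean_

    def variance(self) -> ad.Tensor:
        s = self.std
        return s * s

    def rsample(self, temperature: float, rng, **_) -> ad.Tensor:
        rng = as_generator(rng)
        eps = rng.standard_normal(self.mean_.shape)
        return self.mean_ + self.std * ad.Tensor(eps)

    def representation(self) -> np.ndarray:
        return self.mean_.data


@dataclass
class LaplaceLatentState:
    """Factorized Laplace posterior against a unit Laplace prior at zero."""

    loc: ad.Tensor        # (B, K)
    log_scale: ad.Tensor  # (B, K)

    @property
    def scale(self) -> ad.Tensor:
        return self.log_scale.clip(-10.0, 10.0).exp()

    def _kl_terms(self) -> ad.Tensor:
        # KL(Laplace(μ, b) || Laplace(0, 1)) = −log b + |μ| + b·exp(−|μ|/b) − 1
        b = self.scale
        am = self.loc.abs()
        return -self.log_scale.clip(-10.0, 10.0) + am + b * (-(am / b)).exp() - 1.0

    def kl_per_latent(self) -> ad.Tensor:
        return self._kl_terms().mean(axis=0)

    def kl(self) -> ad.Tensor:
        return self._kl_terms().sum(axis=1).mean()

    def mean(self) -> ad.Tensor:
        return self.loc

    def variance(self) -> ad.Tensor:
        b = self.scale
        return 2.0 * b * b

    def rsample(self, temperature: float, rng, **_) -> ad.Tensor:
        rng = as_generator(rng)
        # inverse-CDF: u ~ U(-1/2, 1/2); z = loc − b·sign(u)·log(1 − 2|u|)
        u = rng.random(self.loc.shape) - 0.5
        w = -np.sign(u) * np.log1p(-2.0 * np.abs(u))
        return self.loc + self.scale * ad.Tensor(w)

    def representation(self) -> np.ndarray:
        return self.loc.data


@dataclass
class CategoricalLatentState:
    """K_vars categorical variables with C categories, uniform prior.

    Sampling uses the Gumbel-Softmax relaxation during training and one-hot
    argmax at evaluation (temperature 0).
    """

    logits: ad.Tensor  # (B, K_vars, C)

    def kl_per_latent(self) -> ad.Tensor:
        """Per-variable KL to the uniform prior: log C − H(p), batch mean."""
        logp = ad.log_softmax(self.logits, axis=-1)
        p = logp.exp()
        C = self.logits.shape[-1]
        return ((p * logp).sum(axis=-1) + np.log(C)).mean(axis=0)

    def kl(self) -> ad.Tensor:
        logp = ad.log_softmax(self.logits, axis=-1)
        p = logp.exp()
        C = self.logits.shape[-1]
        return ((p * logp).sum(axis=-1) + np.log(C)).sum(axis=1).mean()

    def mean(self):
        raise ContractError("categorical latents have no scalar mean; "
                            "closed-form linear loss is unavailable")

    variance = mean

    def rsample(self, temperature: float, rng, **_) -> ad.Tensor:
        rng = as_generator(rng)
        if temperature == 0:
            idx = np.argmax(self.logits.data, axis=-1)
            onehot = np.eye(self.logits.shape[-1])[idx]
            return ad.Tensor(onehot.reshape(self.logits.shape[0], -1))
        u = np.clip(rng.random(self.logits.shape), 1e-12, 1 - 1e-12)
        g = -np.log(-np.log(u))
        y = ad.softmax((self.logits + ad.Tensor(g)) * (1.0 / temperature), axis=-1)
        return y.reshape(self.logits.shape[0], -1)

    def representation(self) -> np.ndarray:
        return self.logits.data.reshape(self.logits.shape[0], -1)


# ------------------------------------------------------------------ functions
def poisson_posterior_rates(prior_rates: np.ndarray,
                            deviation: np.ndarray) -> np.ndarray:
    """Posterior rates ``λ = r ⊙ δr`` (multiplicative residual rule)."""
    r = np.asarray(prior_rates, dtype=np.float64)
    d = np.asarray(deviation, dtype=np.float64)
    _check_positive("prior rates", r)
    _check_positive("deviation", d)
    if r.shape[-1] != d.shape[-1]:
        raise ContractError(f"latent-count mismatch: r has {r.shape[-1]}, "
                            f"deviation has {d.shape[-1]}")
    return r * d


def metabolic_cost(y: np.ndarray) -> np.ndarray:
    """The per-latent KL kernel ``f(y) = 1 − y + y·log y`` (≥ 0, zero at y=1)."""
    y = np.asarray(y, dtype=np.float64)
    _check_positive("y", y)
    return 1.0 - y + y * np.log(y)


def poisson_kl(prior_rates: np.ndarray, deviation: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """KL of ``Pois(r⊙δr)`` from ``Pois(r)`` per sample, with per-latent terms.

    Returns ``(total, per_latent)`` where ``per_latent`` has shape (B, K) and
    ``total = per_latent.sum(axis=-1)``.
    """
    r = np.asarray(prior_rates, dtype=np.float64)
    d = np.asarray(deviation, dtype=np.float64)
    _check_positive("prior rates", r)
    _check_positive("deviation", d)
    per_latent = r * metabolic_cost(d)
    return per_latent.sum(axis=-1), per_latent


def gaussian_kl(mean: np.ndarray, log_std: np.ndarray) -> np.ndarray:
    """KL of ``N(μ, σ²)`` from ``N(0, 1)`` summed over latents."""
    mu = np.asarray(mean, dtype=np.float64)
    ls = np.asarray(log_std, dtype=np.float64)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(ls))):
        raise ContractError("parameters must be finite")
    s2 = np.exp(2 * ls)
    return (0.5 * (mu ** 2 + s2 - 1.0) - ls).sum(axis=-1)


def laplace_kl(loc: np.ndarray, log_scale: np.ndarray) -> np.ndarray:
    """KL of ``Laplace(μ, b)`` from ``Laplace(0, 1)`` summed over latents."""
    mu = np.asarray(loc, dtype=np.float64)
    lb = np.asarray(log_scale, dtype=np.float64)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(lb))):
        raise ContractError("parameters must be finite")
    b = np.exp(lb)
    am = np.abs(mu)
    return (-lb + am + b * np.exp(-am / b) - 1.0).sum(axis=-1)


def categorical_kl(logits: np.ndarray) -> np.ndarray:
    """KL of ``Cat(softmax(logits))`` from uniform, summed over variables."""
    x = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ContractError("logits must be finite")
    x = x - x.max(axis=-1, keepdims=True)
    logp = x - np.log(np.exp(x).sum(axis=-1, keepdims=True))
    p = np.exp(logp)
    C = x.shape[-1]
    kl_per_var = (p * logp).sum(axis=-1) + np.log(C)
    return kl_per_var.sum(axis=-1)


def apply_latent_activation(z: ad.Tensor, activation: str = "none") -> ad.Tensor:
    """Optional elementwise activation applied to sampled latents pre-decoder."""
    if activation == "none":
        return z
    if activation == "relu":
        return ad.relu(z)
    if activation == "exp":
        return z.clip(None, 30.0).exp()
    raise ConfigError(f"unknown latent activation {activation!r}")
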