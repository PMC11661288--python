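"""Differentiable (relaxed) Poisson sampling via exponential inter-event times.

A homogeneous Poisson process with rate λ over a unit window produces a count
equal to the number of exponential inter-event times whose cumulative sum
stays below 1. Exponential draws reparameterize as ``Δt = −log(u)/λ`` with
``u ~ U(0,1)``, so the count becomes differentiable in λ once the hard
indicator ``1[time < 1]`` is relaxed to ``sigmoid((1 − time)/T)``. At
temperature ``T = 0`` the hard indicator is used and counts are exact
nonnegative integers.

The number of exponential draws needed, ``n_exp``, is set adaptively from the
largest rate in the batch via the Poisson inverse CDF at a high quantile
(default 0.99999), capped to bound the ``n_exp × B × K`` memory footprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import autodiff as ad
from ._rng import as_generator
from .errors import ContractError, InvalidRateError

__all__ = [
    "AnnealSchedule",
    "RelaxedCountSample",
    "required_exponential_samples",
    "rsample",
    "rsample_hard_forward",
    "sample_exact",
    "temperature_at",
]

logger = logging.getLogger(__name__)

#: Rates below this are clamped before sampling to avoid infinite wait times.
RATE_FLOOR = 1e-6

#: Default quantile for the adaptive truncation rule.
DEFAULT_QUANTILE = 0.99999

#: Default hard cap on the number of exponential draws per latent.
DEFAULT_CAP = 512


@dataclass(frozen=True)
class AnnealSchedule:
    """Temperature annealing over training steps.

    The temperature starts at ``t_start``, reaches ``t_final`` after
    ``anneal_fraction`` of the total steps, and stays there. ``linear``
    interpolates on the temperature scale, ``exponential`` on the
    log-temperature scale.
    """

    t_start: float = 1.0
    t_final: float = 0.05
    anneal_fraction: float = 0.5
    mode: str = "linear"

    def __post_init__(self):
        if not (self.t_start >= self.t_final >= 0):
            raise ContractError("require t_start >= t_final >= 0")
        if not (0 < self.anneal_fraction <= 1):
            raise ContractError("anneal_fraction must be in (0, 1]")
        if self.mode not in ("linear", "exponential"):
            raise ContractError(f"unknown anneal mode {self.mode!r}")
        if self.mode == "exponential" and self.t_final <= 0:
            raise ContractError("exponential mode requires t_final > 0")


@dataclass
class RelaxedCountSample:
    """Output of :func:`rsample`.

    Attributes
    ----------
    counts : Tensor, shape (B, K)
        Relaxed event counts; exact integers when ``temperature == 0``.
    temperature : float
        Temperature the sample was drawn at.
    n_exp : int
        Number of exponential inter-event draws actually used (counts are
        bounded above by this truncation).
    """

    counts: ad.Tensor
    temperature: float
    n_exp: int


def _validate_rates(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise InvalidRateError("rates must be finite")
    if np.any(values <= 0):
        raise InvalidRateError("rates must be strictly positive")
    return values


def required_exponential_samples(lambda_max: float,
                                 quantile: float = DEFAULT_QUANTILE,
                                 cap: int = DEFAULT_CAP) -> int:
    """Smallest ``n`` with ``PoissonCDF(n; lambda_max) >= quantile``, capped.

    This is the truncation depth guaranteeing that the probability mass
    beyond ``n`` draws is below ``1 − quantile``. May return 0 for tiny
    rates (where ``CDF(0) = exp(−λ)`` already exceeds the quantile);
    callers that sample should floor the result at 1.
    """
    if not np.isfinite(lambda_max) or lambda_max <= 0:
        raise InvalidRateError("lambda_max must be positive and finite")
    if not (0 < quantile < 1):
        raise ContractError("quantile must lie in (0, 1)")
    if cap < 1:
        raise ContractError("cap must be >= 1")
    n = int(stats.poisson.ppf(quantile, lambda_max))
    if n > cap:
        logger.warning(
            "truncation %d for lambda_max=%.3g exceeds cap %d; capping",
            n, lambda_max, cap,
        )
        return cap
    return n


def _draw_wait_times(rates: ad.Tensor, n_exp: int,
                     rng: np.random.Generator) -> ad.Tensor:
    """Reparameterized exponential inter-event times, shape (n_exp, B, K)."""
    raw = rates.data
    if np.any(raw < RATE_FLOOR):
        logger.debug("clamping %d rates below %.0e", int((raw < RATE_FLOOR).sum()),
                     RATE_FLOOR)
    lam = rates.clip(RATE_FLOOR, None)
    u = rng.random(size=(n_exp,) + rates.shape)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return ad.Tensor(-np.log(u)) / lam  # broadcast over leading axis


def _relaxed_counts(rates: ad.Tensor, n_exp: int, temperature: float,
                    rng: np.random.Generator,
                    hard_forward: bool = False) -> ad.Tensor:
    """Fused relaxed-count node: one autodiff primitive for the whole chain.

    Computes ``z = Σ_n sigmoid((1 − S_n)/T)`` with ``S_n`` the cumulative
    reparameterized arrival times, and backpropagates the analytic pathwise
    derivative ``dz/dλ = Σ_n σ'_n · S_n / (λT)`` in a single step — the
    same gradient the elementary-op chain would produce, without
    materializing its intermediate (n_exp × B × K) tapes.
    """
    lam = rates.clip(RATE_FLOOR, None)
    u = np.clip(rng.random(size=(n_exp,) + rates.shape), 1e-12, 1 - 1e-12)
    arrivals = np.cumsum(-np.log(u), axis=0)           # unit-rate arrival times
    S = arrivals / lam.data                            # rate-λ arrival times
    arg = np.clip((1.0 - S) / temperature, -700.0, 700.0)
    sig = 1.0 / (1.0 + np.exp(-arg))
    soft = sig.sum(axis=0)
    forward = (S < 1.0).sum(axis=0).astype(np.float64) if hard_forward else soft

    def bwd(out):
        dlam = (sig * (1.0 - sig) * S).sum(axis=0) / (lam.data * temperature)
        lam._accumulate(out.grad * dlam)

    return lam._make(forward, (lam,), bwd)


def rsample(rates: ad.Tensor | np.ndarray, n_exp: int, temperature: float,
            rng: int | np.random.Generator | None = None) -> RelaxedCountSample:
    """Draw relaxed Poisson counts, differentiable in the rates for T > 0.

    Parameters
    ----------
    rates : Tensor or array, shape (B, K)
        Strictly positive Poisson rates (unit window).
    n_exp : int
        Number of exponential inter-event draws per latent (>= 1); see
        :func:`required_exponential_samples`.
    temperature : float
        Relaxation temperature; 0 gives a hard threshold and integer counts.
    rng : seed or Generator
        Source of the uniform noise; identical seeds give identical samples.
    """
    if not isinstance(rates, ad.Tensor):
        rates = ad.Tensor(rates)
    _validate_rates(rates.data)
    if temperature < 0:
        raise ContractError("temperature must be >= 0")
    if n_exp < 1:
        raise ContractError("n_exp must be >= 1")
    rng = as_generator(rng)

    if temperature == 0:
        times = _draw_wait_times(rates, n_exp, rng).cumsum(axis=0)
        counts = ad.Tensor((times.data < 1.0).sum(axis=0).astype(np.float64))
    else:
        counts = _relaxed_counts(rates, n_exp, temperature, rng)
    return RelaxedCountSample(counts=counts, temperature=float(temperature),
                              n_exp=int(n_exp))


def rsample_hard_forward(rates: ad.Tensor | np.ndarray, n_exp: int,
                         temperature: float,
                         rng: int | np.random.Generator | None = None
                         ) -> RelaxedCountSample:
    """Surrogate-gradient variant: hard integer counts forward, relaxed backward.

    The forward value is the temperature-0 count of the same arrival times;
    the gradient is that of the relaxed count. Offered as an optional
    training mode (straight-through on the count scale tends to train worse
    than the fully relaxed sampler).
    """
    if temperature <= 0:
        raise ContractError("hard-forward mode requires temperature > 0")
    if not isinstance(rates, ad.Tensor):
        rates = ad.Tensor(rates)
    _validate_rates(rates.data)
    if n_exp < 1:
        raise ContractError("n_exp must be >= 1")
    rng = as_generator(rng)

    counts = _relaxed_counts(rates, n_exp, temperature, rng, hard_forward=True)
    return RelaxedCountSample(counts=counts, temperature=float(temperature),
                              n_exp=int(n_exp))


def sample_exact(rates: ad.Tensor | np.ndarray,
                 rng: int | np.random.Generator | None = None) -> np.ndarray:
    """Exact integer Poisson samples (evaluation-time encoding, T = 0)."""
    if isinstance(rates, ad.Tensor):
        rates = rates.data
    values = _validate_rates(rates)
    rng = as_generator(rng)
    return rng.poisson(values).astype(np.int64)


def temperature_at(step: int, total_steps: int,
                   schedule: AnnealSchedule | None = None) -> float:
    """Temperature at a training step under an annealing schedule.

    Equals ``t_start`` at step 0, ``t_final`` from ``anneal_fraction *
    total_steps`` onward, and is monotone nonincreasing in between.
    """
    schedule = schedule or AnnealSchedule()
    if step < 0:
        raise ContractError("step must be >= 0")
    if total_steps < 1:
        raise ContractError("total_steps must be >= 1")
    anneal_steps = schedule.anneal_fraction * total_steps
    frac = min(float(step) / anneal_steps, 1.0)
    if frac >= 1.0:
        return schedule.t_final
    if schedule.mode == "linear":
        return schedule.t_start + frac * (schedule.t_final - schedule.t_start)
    log_t = (1 - frac) * np.log(schedule.t_start) + frac * np.log(schedule.t_final)
    return float(np.exp(log_t))
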