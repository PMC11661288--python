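"""ELBO losses: Monte-Carlo and closed-form (linear decoder) variants.

The negative ELBO per sample is

    L = E_q ‖x − dec(z)‖² + β · KL(q ‖ p),

with the KL always computed analytically per family. For a linear decoder
``x̂ = Φz`` and any factorized posterior with mean μ and variance v the
reconstruction expectation has the closed form

    E‖x − Φz‖² = ‖x − Φμ‖² + Σ_k v_k ‖Φ_k‖²,

which for Poisson latents (μ = v = λ) is ``‖x − Φλ‖² + λᵀ diag(ΦᵀΦ)``. The
closed form is sample-free and exactly differentiable, which makes it the
reference against which the pathwise (reparameterized) and straight-through
Monte-Carlo gradient estimators are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from ._rng import as_generator
from .errors import ContractError

__all__ = ["LossBreakdown", "mc_loss", "closed_form_linear_loss",
           "compare_gradient_estimators"]


@dataclass
class LossBreakdown:
    """Total loss plus its components; ``total`` stays on the autodiff tape."""

    total: ad.Tensor
    reconstruction: float
    kl: float
    beta: float
    kl_per_latent: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mean_rate: float = float("nan")


def mc_loss(x: np.ndarray, model, temperature: float, n_mc: int = 1,
            rng=None) -> LossBreakdown:
    """Monte-Carlo negative ELBO: sampled reconstruction + analytic KL.

    The reconstruction term is averaged over ``n_mc`` reparameterized
    samples; the KL is always closed-form. Batch-mean of per-sample sums.
    """
    if n_mc < 1:
        raise ContractError("n_mc must be >= 1")
    rng = as_generator(rng)
    x = np.asarray(x, dtype=np.float64)
    state = model.encode_state(x)
    xt = ad.Tensor(x)
    recon_terms = []
    from .latents import apply_latent_activation
    for _ in range(n_mc):
        z = state.rsample(temperature, rng,
                          hard_forward=getattr(model, "hard_forward", False))
        z = apply_latent_activation(z, model.config_.activation)
        diff = xt - model.decoder_(z)
        recon_terms.append((diff * diff).sum(axis=1).mean())
    recon = recon_terms[0]
    for t in recon_terms[1:]:
        recon = recon + t
    recon = recon * (1.0 / n_mc)
    kl = state.kl()
    total = recon + model.beta * kl
    mean_rate = float(state.posterior_rates.data.mean()) \
        if hasattr(state, "posterior_rates") else float("nan")
    return LossBreakdown(total=total, reconstruction=float(recon.data),
                         kl=float(kl.data), beta=model.beta,
                         kl_per_latent=state.kl_per_latent().data.copy(),
                         mean_rate=mean_rate)


def closed_form_linear_loss(x: np.ndarray, Phi: ad.Tensor | np.ndarray,
                            posterior_mean: ad.Tensor,
                            posterior_var: ad.Tensor | float,
                            kl: ad.Tensor | float, beta: float = 1.0
                            ) -> LossBreakdown:
    """Exact negative ELBO for a linear decoder (sample-free).

    ``reconstruction = ‖x − Φμ‖² + Σ_k var_k·‖Φ_k‖²`` per sample, batch
    mean. Works for any latent family with a defined mean and variance
    (Poisson: μ = var = λ).
    """
    if not isinstance(Phi, ad.Tensor):
        Phi = ad.Tensor(Phi)
    if Phi.ndim != 2:
        raise ContractError("Phi must be a 2-D (M × K) matrix")
    mu = posterior_mean
    if not isinstance(mu, ad.Tensor):
        mu = ad.Tensor(mu)
    if mu.shape[-1] != Phi.shape[1]:
        raise ContractError("posterior mean width must match the number of "
                            "dictionary columns")
    x = np.asarray(x, dtype=np.float64)
    xt = ad.Tensor(x)
    diff = xt - mu @ Phi.T
    se = (diff * diff).sum(axis=1)
    col_sq = (Phi * Phi).sum(axis=0)            # ‖Φ_k‖², shape (K,)
    if isinstance(posterior_var, ad.Tensor) or np.ndim(posterior_var) > 0:
        var = posterior_var if isinstance(posterior_var, ad.Tensor) \
            else ad.Tensor(posterior_var)
        var_term = (var * col_sq).sum(axis=1)
        recon = (se + var_term).mean()
    else:
        recon = (se + float(posterior_var) * col_sq.sum()).mean()
    kl_t = kl if isinstance(kl, ad.Tensor) else ad.Tensor(float(kl))
    total = recon + beta * kl_t
    return LossBreakdown(total=total, reconstruction=float(recon.data),
                         kl=float(kl_t.data), beta=beta)


# ---------------------------------------------------------------- estimators
def _collect_grads(params) -> list[np.ndarray]:
    return [np.zeros_like(p.data) if p.grad is None else p.grad.copy()
            for p in params]


def _zero_grads(params) -> None:
    for p in params:
        p.grad = None


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(a.ravel() @ b.ravel() / (na * nb))


def _exact_gradient(x, model, params):
    """Gradient of the closed-form linear-decoder loss at current parameters."""
    state = model.encode_state(x)
    loss = closed_form_linear_loss(x, model.decoder_.Phi, state.mean(),
                                   state.variance(), state.kl(), model.beta)
    _zero_grads(params)
    loss.total.backward()
    return _collect_grads(params)


def _mc_gradient(x, model, params, temperature, n_trials, rng, estimator):
    """Averaged Monte-Carlo gradient (pathwise or straight-through)."""
    from .latents import PoissonLatentState

    acc = [np.zeros_like(p.data) for p in params]
    for _ in range(n_trials):
        _zero_grads(params)
        if estimator == "pathwise":
            loss = mc_loss(x, model, temperature=temperature, n_mc=1, rng=rng)
        elif estimator == "straight_through":
            state = model.encode_state(x)
            if not isinstance(state, PoissonLatentState):
                raise ContractError("straight-through contrast is defined for "
                                    "the Poisson family")
            lam = state.posterior_rates
            from .relaxed_poisson import sample_exact
            z_hard = sample_exact(lam.detach(), rng).astype(np.float64)
            # forward: integer counts; backward: identity in λ (dz/dλ = 1)
            z = lam + ad.Tensor(z_hard - lam.data)
            diff = ad.Tensor(x) - model.decoder_(z)
            recon = (diff * diff).sum(axis=1).mean()
            loss = LossBreakdown(total=recon + model.beta * state.kl(),
                                 reconstruction=float(recon.data),
                                 kl=float(state.kl().data), beta=model.beta)
        else:
            raise ContractError(f"unknown estimator {estimator!r}")
        loss.total.backward()
        for a, g in zip(acc, _collect_grads(params)):
            a += g
    return [a / n_trials for a in acc]


def compare_gradient_estimators(x: np.ndarray, model, temperature: float = 0.05,
                                n_trials: int = 200, rng=None,
                                include_straight_through: bool = True
                                ) -> dict[str, dict[str, float]]:
    """Agreement between MC gradient estimators and the exact gradient.

    Computes the exact gradient of the closed-form linear-decoder loss and
    the trial-averaged pathwise gradient of the sampled loss at the same
    parameters (optionally also a straight-through estimator on the count
    scale), reporting cosine similarity and relative L2 error per parameter
    block and overall.
    """
    if not hasattr(model.decoder_, "Phi"):
        raise ContractError("exact gradients require a linear decoder")
    rng = as_generator(rng)
    x = np.asarray(x, dtype=np.float64)
    params = model.parameters()
    names = [f"block{i}" for i in range(len(params))]
    exact = _exact_gradient(x, model, params)

    report: dict[str, dict[str, float]] = {}
    estimators = ["pathwise"]
    if include_straight_through and model.config_.latent_family == "poisson":
        estimators.append("straight_through")
    for est in estimators:
        grads = _mc_gradient(x, model, params, temperature, n_trials, rng, est)
        entry: dict[str, float] = {}
        for name, ge, gm in zip(names, exact, grads):
            entry[f"cosine_{name}"] = _cosine(ge, gm)
            denom = np.linalg.norm(ge)
            entry[f"rel_err_{name}"] = float(np.linalg.norm(gm - ge) /
                                             denom) if denom else float("nan")
        flat_e = np.concatenate([g.ravel() for g in exact])
        flat_m = np.concatenate([g.ravel() for g in grads])
        entry["cosine_overall"] = _cosine(flat_e, flat_m)
        entry["rel_err_overall"] = float(np.linalg.norm(flat_m - flat_e) /
                                         np.linalg.norm(flat_e))
        report[est] = entry
    return report
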