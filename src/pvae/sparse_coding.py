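"""Classical sparse coding: ISTA and LCA inference, dictionary learning.

The sparse-coding objective for a dictionary Φ (M × K) and codes z is

    L(x; Φ, z) = ‖x − Φz‖² + β‖z‖₁.

ISTA minimizes it by proximal gradient descent (soft thresholding); the
locally competitive algorithm (LCA) integrates membrane dynamics

    τ u̇ = Φᵀx − u − (ΦᵀΦ − I)a,   a = soft_threshold(u, λ_lca),

whose fixed points are critical points of the same objective with
β = 2·λ_lca. Dictionary learning alternates inference with gradient updates
on the reconstruction term, renormalizing columns to unit norm.

The ``lca_on_fixed_dictionary`` sweep runs LCA inference on a dictionary
exported from a trained amortized model, quantifying the amortization gap
between a feedforward encoder and per-sample iterative inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._rng import as_generator
from .errors import ContractError, DivergenceError, StepSizeError

__all__ = ["SparseCode", "sc_loss", "soft_threshold", "ista_infer", "lca_infer",
           "learn_dictionary", "lca_on_fixed_dictionary", "DictionaryLearner"]


@dataclass
class SparseCode:
    """Inference result: coefficients and the per-iteration objective trace."""

    coefficients: np.ndarray          # (B, K)
    objective_trace: np.ndarray = field(default_factory=lambda: np.zeros(0))


def sc_loss(x: np.ndarray, Phi: np.ndarray, z: np.ndarray,
            beta_sc: float) -> float:
    """Sparse-coding objective ``‖x − Φz‖² + β‖z‖₁``, batch mean."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    Phi = np.asarray(Phi, dtype=np.float64)
    if Phi.shape[0] != x.shape[1] or Phi.shape[1] != z.shape[1]:
        raise ContractError(f"shape mismatch: x {x.shape}, Phi {Phi.shape}, "
                            f"z {z.shape}")
    resid = x - z @ Phi.T
    return float(np.mean(np.sum(resid ** 2, axis=1) +
                         beta_sc * np.sum(np.abs(z), axis=1)))


def soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    """Proximal operator of the L1 norm: ``sign(v)·max(|v| − t, 0)``."""
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _lipschitz(Phi: np.ndarray, n_iter: int = 100, seed: int = 0) -> float:
    """Largest eigenvalue of ΦᵀΦ by power iteration."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(Phi.shape[1])
    v /= np.linalg.norm(v)
    for _ in range(n_iter):
        w = Phi.T @ (Phi @ v)
        n = np.linalg.norm(w)
        if n == 0:
            return 0.0
        v = w / n
    return float(v @ (Phi.T @ (Phi @ v)))


def ista_infer(x: np.ndarray, Phi: np.ndarray, beta_sc: float,
               step_size: float | None = None, n_iters: int = 200) -> SparseCode:
    """ISTA inference of sparse codes for a fixed dictionary.

    Iterates ``z ← soft_threshold(z + η·Φᵀ(x − Φz), η·β)`` from z = 0 with
    step size ``η = 1/L`` (L the largest eigenvalue of ΦᵀΦ) by default.
    Written as a proximal-gradient step on ``‖x − Φz‖²`` this update
    provably descends ``‖x − Φz‖² + 2β‖z‖₁``; the objective trace records
    that functional, and an LCA run at ``threshold = β`` targets the same
    effective penalty.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    Phi = np.asarray(Phi, dtype=np.float64)
    if step_size is None:
        L = _lipschitz(Phi)
        if L <= 0:
            raise ContractError("dictionary has zero spectral norm")
        step_size = 1.0 / L
    z = np.zeros((x.shape[0], Phi.shape[1]))
    trace = np.empty(n_iters)
    prev = np.inf
    for it in range(n_iters):
        grad = (x - z @ Phi.T) @ Phi          # Φᵀ(x − Φz), batched
        z = soft_threshold(z + step_size * grad, step_size * beta_sc)
        obj = sc_loss(x, Phi, z, 2.0 * beta_sc)  # the functional this step descends
        trace[it] = obj
        if obj > prev * (1 + 1e-9) + 1e-12:
            raise StepSizeError(f"ISTA objective increased at iteration {it}; "
                                "reduce step_size")
        prev = obj
    return SparseCode(coefficients=z, objective_trace=trace)


def lca_infer(x: np.ndarray, Phi: np.ndarray, threshold: float,
              time_constant: float = 10.0, n_steps: int = 400,
              hard: bool = False) -> SparseCode:
    """LCA inference: leaky integrator dynamics with lateral competition.

    Requires unit-norm dictionary columns. The returned activations at
    steady state are critical points of the sparse-coding objective with
    ``β = 2·threshold`` (soft-threshold variant; ``hard=True`` switches to a
    hard threshold).
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    Phi = np.asarray(Phi, dtype=np.float64)
    norms = np.linalg.norm(Phi, axis=0)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ContractError("LCA requires unit-norm dictionary columns")
    drive = x @ Phi                      # Φᵀx per sample
    G = Phi.T @ Phi - np.eye(Phi.shape[1])
    u = np.zeros_like(drive)
    trace = np.empty(n_steps)
    for it in range(n_steps):
        if hard:
            a = u * (np.abs(u) > threshold)
        else:
            a = soft_threshold(u, threshold)
        u = u + (1.0 / time_constant) * (drive - u - a @ G)
        if not np.all(np.isfinite(u)):
            raise DivergenceError(f"LCA dynamics diverged at step {it}")
        trace[it] = sc_loss(x, Phi, a, 2.0 * threshold)
    a = u * (np.abs(u) > threshold) if hard else soft_threshold(u, threshold)
    return SparseCode(coefficients=a, objective_trace=trace)


def learn_dictionary(patches: np.ndarray, K: int, method: str = "ista",
                     beta_sc: float = 0.1, epochs: int = 20,
                     rng=None, batch_size: int = 100, lr: float = 0.5,
                     n_infer_iters: int = 100, lca_tau: float = 10.0,
                     overcomplete_required: bool = False) -> np.ndarray:
    """Alternating inference / dictionary-gradient learning.

    Each update performs sparse inference on a minibatch, then a gradient
    step on the reconstruction term, then renormalizes columns to unit
    norm. Returns the learned Φ (M × K).
    """
    patches = np.asarray(patches, dtype=np.float64)
    M = patches.shape[1]
    if overcomplete_required and K <= M:
        raise ContractError(f"overcomplete mode requires K > M (got K={K}, M={M})")
    if method not in ("ista", "lca"):
        raise ContractError(f"unknown method {method!r}")
    rng = as_generator(rng)
    Phi = rng.standard_normal((M, K))
    Phi /= np.linalg.norm(Phi, axis=0, keepdims=True)
    n = patches.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            xb = patches[order[start:start + batch_size]]
            if method == "ista":
                code = ista_infer(xb, Phi, beta_sc, n_iters=n_infer_iters)
            else:
                code = lca_infer(xb, Phi, threshold=beta_sc,
                                 time_constant=lca_tau, n_steps=n_infer_iters)
            z = code.coefficients
            resid = xb - z @ Phi.T
            Phi += (lr / xb.shape[0]) * resid.T @ z
            norms = np.linalg.norm(Phi, axis=0, keepdims=True)
            Phi /= np.maximum(norms, 1e-12)
    return Phi


def lca_on_fixed_dictionary(patches: np.ndarray, Phi: np.ndarray,
                            threshold_grid, time_constant: float = 10.0,
                            n_steps: int = 400) -> pd.DataFrame:
    """Amortization-gap sweep: LCA inference on an externally learned Φ.

    Normalizes Φ columns (LCA contract), runs LCA at each threshold, and
    reports reconstruction MSE and mean lifetime sparsity per grid point.
    """
    from .metrics import lifetime_sparsity

    patches = np.atleast_2d(np.asarray(patches, dtype=np.float64))
    Phi = np.asarray(Phi, dtype=np.float64)
    norms = np.linalg.norm(Phi, axis=0)
    Phi = Phi / np.maximum(norms, 1e-12)
    rows = []
    for lam in threshold_grid:
        code = lca_infer(patches, Phi, threshold=float(lam),
                         time_constant=time_constant, n_steps=n_steps)
        a = code.coefficients
        mse = float(np.mean(np.sum((patches - a @ Phi.T) ** 2, axis=1)))
        _, mean_s = lifetime_sparsity(np.abs(a))
        rows.append({"threshold": float(lam), "mse": mse,
                     "mean_lifetime_sparsity": mean_s,
                     "active_per_sample": float(np.mean(np.abs(a) > 0))})
    return pd.DataFrame(rows)


class DictionaryLearner(BaseEstimator, TransformerMixin):
    """Sparse-coding baseline as a scikit-learn estimator.

    ``fit(X)`` learns an (optionally overcomplete) unit-norm dictionary with
    ISTA or LCA inference in the loop; ``transform(X)`` infers sparse codes
    against the learned dictionary.
    """

    def __init__(self, n_components: int = 512, method: str = "ista",
                 beta_sc: float = 0.1, epochs: int = 20, batch_size: int = 100,
                 lr: float = 0.5, n_infer_iters: int = 100,
                 lca_tau: float = 10.0, random_state: int = 0):
        self.n_components = n_components
        self.method = method
        self.beta_sc = beta_sc
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.n_infer_iters = n_infer_iters
        self.lca_tau = lca_tau
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        self.dictionary_ = learn_dictionary(
            X, K=self.n_components, method=self.method, beta_sc=self.beta_sc,
            epochs=self.epochs, rng=np.random.default_rng(self.random_state),
            batch_size=self.batch_size, lr=self.lr,
            n_infer_iters=self.n_infer_iters, lca_tau=self.lca_tau)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.method == "lca":
            code = lca_infer(X, self.dictionary_, threshold=self.beta_sc,
                             time_constant=self.lca_tau,
                             n_steps=self.n_infer_iters)
        else:
            code = ista_infer(X, self.dictionary_, self.beta_sc,
                              n_iters=self.n_infer_iters)
        return code.coefficients

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "dictionary_")
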