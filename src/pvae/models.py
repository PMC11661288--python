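"""Encoder/decoder networks and the VAE estimator.

Architectures follow the ⟨encoder|decoder⟩ convention: ``lin`` encoders are
a single affine map, ``conv`` encoders a small strided convolutional stack
with an affine head. The decoder is linear, ``x̂ = Φz`` with no bias by
default, so a Poisson-latent model with an overcomplete latent space
(K > M) is exactly amortized sparse coding and the reconstruction term of
the loss has a closed form (see :mod:`pvae.objectives`).

:class:`VAE` is a scikit-learn style estimator: ``fit(X)`` trains on flat
patch vectors with temperature annealing for the relaxed families,
``transform(X)`` returns the deterministic representation used for
downstream evaluation (log δr for Poisson, μ for Gaussian/Laplace, logits
for Categorical), and fitted attributes expose the dictionary and
per-latent KLs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import autodiff as ad
from . import latents as lt
from . import relaxed_poisson as rp
from ._rng import as_generator, spawn
from .errors import ConfigError, ContractError, DivergenceError

__all__ = ["ModelConfig", "build_encoder", "build_decoder", "VAE"]


@dataclass
class ModelConfig:
    """Architecture/hyperparameter bundle for one model."""

    input_dim: int = 256
    latent_dim: int = 512
    latent_family: str = "poisson"
    encoder_arch: str = "lin"
    decoder_arch: str = "lin"
    beta: float = 1.0
    activation: str = "none"
    n_categories: int = 8
    decoder_bias: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.beta <= 0:
            raise ConfigError("beta must be > 0")
        if self.latent_dim < 1:
            raise ConfigError("latent_dim must be >= 1")
        family = self.latent_family
        if family.startswith("gaussian+"):
            family, act = family.split("+")
            self.latent_family, self.activation = family, act
        if self.latent_family not in ("poisson", "gaussian", "laplace",
                                      "categorical"):
            raise ConfigError(f"unknown latent family {self.latent_family!r}")
        if self.encoder_arch not in ("lin", "conv"):
            raise ConfigError(f"unknown encoder arch {self.encoder_arch!r}")
        if self.decoder_arch != "lin":
            raise ConfigError("only linear decoders are supported")
        if self.latent_family == "categorical" and \
                self.latent_dim % self.n_categories != 0:
            raise ConfigError("latent_dim must be divisible by n_categories "
                              "for categorical latents")

    @property
    def head_dim(self) -> int:
        """Output dimension of the encoder for this latent family."""
        if self.latent_family == "poisson":
            return self.latent_dim          # log δr
        if self.latent_family in ("gaussian", "laplace"):
            return 2 * self.latent_dim      # (μ, log σ) / (loc, log b)
        return self.latent_dim              # K_vars * C logits


# ------------------------------------------------------------------ networks
class LinearEncoder:
    """Single affine map x ↦ xW + b."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(in_dim)
        self.W = ad.Parameter(rng.normal(0, scale, size=(in_dim, out_dim)))
        self.b = ad.Parameter(np.zeros(out_dim))

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[ad.Parameter]:
        return [self.W, self.b]

    def zero_(self) -> None:
        self.W.data[:] = 0.0
        self.b.data[:] = 0.0


class ConvEncoder:
    """Three stride-2 conv layers (widths 32/64/128, ReLU) with an affine head."""

    WIDTHS = (32, 64, 128)
    KERNEL = 3

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        side = int(round(np.sqrt(in_dim)))
        if side * side != in_dim:
            raise ConfigError("conv encoder requires square inputs "
                              f"(got {in_dim} pixels)")
        self.side = side
        self.convs: list[tuple[ad.Parameter, ad.Parameter]] = []
        c_in, s = 1, side
        for width in self.WIDTHS:
            fan_in = c_in * self.KERNEL ** 2
            w = ad.Parameter(rng.normal(0, np.sqrt(2.0 / fan_in),
                                        size=(width, c_in, self.KERNEL, self.KERNEL)))
            b = ad.Parameter(np.zeros(width))
            self.convs.append((w, b))
            c_in = width
            s = (s + 2 - self.KERNEL) // 2 + 1  # stride 2, padding 1
        flat = c_in * s * s
        self.head_W = ad.Parameter(rng.normal(0, 1.0 / np.sqrt(flat),
                                              size=(flat, out_dim)))
        self.head_b = ad.Parameter(np.zeros(out_dim))

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        B = x.shape[0]
        h = x.reshape(B, 1, self.side, self.side)
        for w, b in self.convs:
            h = ad.relu(ad.conv2d(h, w, b, stride=2, padding=1))
        h = h.reshape(B, -1)
        return h @ self.head_W + self.head_b

    def parameters(self) -> list[ad.Parameter]:
        ps = [p for wb in self.convs for p in wb]
        return ps + [self.head_W, self.head_b]

    def zero_(self) -> None:
        for p in self.parameters():
            p.data[:] = 0.0


class LinearDecoder:
    """Linear generative map x̂ = Φz (no bias by default); Φ is (M × K)."""

    def __init__(self, latent_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = False):
        self.Phi = ad.Parameter(rng.normal(0, 1.0 / np.sqrt(latent_dim),
                                           size=(out_dim, latent_dim)))
        self.b = ad.Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, z: ad.Tensor) -> ad.Tensor:
        out = z @ self.Phi.T
        if self.b is not None:
            out = out + self.b
        return out

    @property
    def dictionary(self) -> np.ndarray:
        return self.Phi.data

    def parameters(self) -> list[ad.Parameter]:
        return [self.Phi] + ([self.b] if self.b is not None else [])


def build_encoder(config: ModelConfig, rng: np.random.Generator | int | None = None):
    """Construct the encoder network mapping x to posterior parameters."""
    rng = as_generator(rng)
    cls = LinearEncoder if config.encoder_arch == "lin" else ConvEncoder
    return cls(config.input_dim, config.head_dim, rng)


def build_decoder(config: ModelConfig, rng: np.random.Generator | int | None = None):
    """Construct the (linear) decoder network mapping z to x̂."""
    rng = as_generator(rng)
    return LinearDecoder(config.latent_dim, config.input_dim, rng,
                         bias=config.decoder_bias)


# ------------------------------------------------------------------ estimator
class VAE(BaseEstimator, TransformerMixin):
    """Variational autoencoder with a choice of latent family.

    Parameters
    ----------
    latent_dim : int
        Number of latent units K (for categorical latents, total one-hot
        width; split into ``latent_dim / n_categories`` variables).
    latent_family : str
        One of ``poisson``, ``gaussian``, ``laplace``, ``categorical``,
        ``gaussian+relu``, ``gaussian+exp``.
    encoder_arch, decoder_arch : str
        ``lin`` or ``conv`` encoder; decoder must be ``lin``.
    beta : float
        Multiplier on the KL term (rate-distortion knob).
    n_steps, batch_size, learning_rate : training-loop hyperparameters.
    t_start, t_final, anneal_fraction, anneal_mode :
        Temperature annealing schedule for the relaxed samplers (Poisson and
        Gumbel-Softmax); annealing spans the first ``anneal_fraction`` of
        training, then holds at ``t_final``. Evaluation always uses T = 0.
    n_mc : int
        Monte-Carlo samples per step for the reconstruction term.
    hard_forward : bool
        Poisson only: integer counts in the forward pass, relaxed gradients
        in the backward pass (surrogate-gradient mode).
    random_state : int
        Seed controlling initialization, batching and sampling.

    Attributes
    ----------
    encoder_, decoder_ : fitted networks.
    dictionary_ : ndarray (M, K)
        Decoder basis Φ.
    kl_per_latent_ : ndarray (K,)
        Per-latent KL on the training data at the fitted parameters.
    loss_history_ : DataFrame
        Per-logged-step loss components and temperature.
    """

    def __init__(self, latent_dim: int = 512, latent_family: str = "poisson",
                 encoder_arch: str = "lin", decoder_arch: str = "lin",
                 beta: float = 1.0, n_steps: int = 5000, batch_size: int = 64,
                 learning_rate: float = 1e-3, t_start: float = 1.0,
                 t_final: float = 0.05, anneal_fraction: float = 0.5,
                 anneal_mode: str = "linear", n_mc: int = 1,
                 hard_forward: bool = False, n_categories: int = 8,
                 truncation_quantile: float = rp.DEFAULT_QUANTILE,
                 truncation_cap: int = rp.DEFAULT_CAP, decoder_bias: bool = False,
                 random_state: int = 0, log_every: int = 100):
        self.latent_dim = latent_dim
        self.latent_family = latent_family
        self.encoder_arch = encoder_arch
        self.decoder_arch = decoder_arch
        self.beta = beta
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.t_start = t_start
        self.t_final = t_final
        self.anneal_fraction = anneal_fraction
        self.anneal_mode = anneal_mode
        self.n_mc = n_mc
        self.hard_forward = hard_forward
        self.n_categories = n_categories
        self.truncation_quantile = truncation_quantile
        self.truncation_cap = truncation_cap
        self.decoder_bias = decoder_bias
        self.random_state = random_state
        self.log_every = log_every

    # ------------------------------------------------------------- internals
    def _config(self, input_dim: int) -> ModelConfig:
        return ModelConfig(input_dim=input_dim, latent_dim=self.latent_dim,
                           latent_family=self.latent_family,
                           encoder_arch=self.encoder_arch,
                           decoder_arch=self.decoder_arch, beta=self.beta,
                           n_categories=self.n_categories,
                           decoder_bias=self.decoder_bias,
                           seed=self.random_state)

    def _init_networks(self, input_dim: int) -> None:
        cfg = self._config(input_dim)
        rng = spawn(self.random_state, "init")
        self.config_ = cfg
        self.encoder_ = build_encoder(cfg, rng)
        self.decoder_ = build_decoder(cfg, rng)
        self.prior_log_rates_ = ad.Parameter(np.zeros(cfg.latent_dim)) \
            if cfg.latent_family == "poisson" else None
        self.schedule_ = rp.AnnealSchedule(self.t_start, self.t_final,
                                           self.anneal_fraction, self.anneal_mode)
        self.n_features_in_ = input_dim

    def parameters(self) -> list[ad.Parameter]:
        ps = self.encoder_.parameters() + self.decoder_.parameters()
        if self.prior_log_rates_ is not None:
            ps.append(self.prior_log_rates_)
        return ps

    def encode_state(self, X: np.ndarray):
        """Run the encoder and build the posterior state object."""
        x = ad.Tensor(np.asarray(X, dtype=np.float64))
        head = self.encoder_(x)
        if not np.all(np.isfinite(head.data)):
            raise DivergenceError("NaN/inf in encoder output")
        fam = self.config_.latent_family
        K = self.config_.latent_dim
        if fam == "poisson":
            return lt.PoissonLatentState(self.prior_log_rates_, head)
        if fam == "gaussian":
            return lt.GaussianLatentState(head[:, :K], head[:, K:])
        if fam == "laplace":
            return lt.LaplaceLatentState(head[:, :K], head[:, K:])
        C = self.config_.n_categories
        return lt.CategoricalLatentState(head.reshape(head.shape[0], K // C, C))

    def forward(self, X: np.ndarray, temperature: float,
                rng: np.random.Generator | int | None = None):
        """Full pass: encode, sample, decode.

        Returns ``(x_hat, z, state, kl_per_latent)`` with everything needed
        by the loss and the metrics; pass ``temperature=0`` for
        evaluation-mode (exact/hard) sampling.
        """
        state = self.encode_state(X)
        z = state.rsample(temperature, rng, hard_forward=self.hard_forward)
        z = lt.apply_latent_activation(z, self.config_.activation)
        if not np.all(np.isfinite(z.data)):
            raise DivergenceError("NaN/inf in latent sample")
        x_hat = self.decoder_(z)
        if not np.all(np.isfinite(x_hat.data)):
            raise DivergenceError("NaN/inf in decoder output")
        return x_hat, z, state, state.kl_per_latent()

    # ------------------------------------------------------------------- API
    def fit(self, X, y=None):
        from .objectives import mc_loss  # local import: objectives imports models' types

        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ContractError("X must be 2-D (n_samples, n_features)")
        self._init_networks(X.shape[1])
        opt = ad.Adam(self.parameters(), lr=self.learning_rate)
        batch_rng = spawn(self.random_state, "batches")
        sample_rng = spawn(self.random_state, "sampling")
        relaxed = self.config_.latent_family in ("poisson", "categorical")
        rows = []
        for step in range(self.n_steps):
            idx = batch_rng.integers(0, X.shape[0], size=self.batch_size)
            T = rp.temperature_at(step, self.n_steps, self.schedule_) \
                if relaxed else 0.0
            loss = mc_loss(X[idx], self, temperature=T, n_mc=self.n_mc,
                           rng=sample_rng)
            if not np.isfinite(loss.total.data):
                raise DivergenceError(f"non-finite loss at step {step}")
            opt.zero_grad()
            loss.total.backward()
            opt.step()
            if step % self.log_every == 0 or step == self.n_steps - 1:
                rows.append({"step": step, "total": float(loss.total.data),
                             "recon": loss.reconstruction, "kl": loss.kl,
                             "beta": self.beta, "temperature": T,
                             "mean_rate": loss.mean_rate})
        self.loss_history_ = pd.DataFrame(rows)
        self.dictionary_ = self.decoder_.dictionary.copy()
        eval_n = min(1024, X.shape[0])
        _, _, _, klpl = self.forward(X[:eval_n], temperature=0.0,
                                     rng=spawn(self.random_state, "eval"))
        self.kl_per_latent_ = klpl.data.copy()
        return self

    def transform(self, X) -> np.ndarray:
        """Deterministic representation (log δr / μ / loc / logits)."""
        X = np.asarray(X, dtype=np.float64)
        return self.encode_state(X).representation()

    def reconstruct(self, X, rng: np.random.Generator | int | None = None,
                    temperature: float = 0.0) -> np.ndarray:
        """Reconstruction through evaluation-mode sampling (T = 0 default)."""
        if rng is None:
            rng = spawn(self.random_state, "reconstruct")
        x_hat, _, _, _ = self.forward(np.asarray(X, dtype=np.float64),
                                      temperature=temperature, rng=rng)
        return x_hat.data

    def eval_mse(self, X, rng: np.random.Generator | int | None = None) -> float:
        """Mean over images of the per-image squared reconstruction error."""
        X = np.asarray(X, dtype=np.float64)
        x_hat = self.reconstruct(X, rng=rng)
        return float(np.mean(np.sum((X - x_hat) ** 2, axis=1)))

    def score(self, X, y=None) -> float:
        """Negative evaluation-mode MSE (larger is better), sklearn-style."""
        return -self.eval_mse(X)

    # -------------------------------------------------------------- persistence
    def save(self, path: str) -> None:
        """Serialize config + parameters to a ``.npz`` checkpoint."""
        payload = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        payload["config_json"] = np.frombuffer(
            json.dumps({**asdict(self.config_), **self.get_params()},
                       default=float).encode(), dtype=np.uint8)
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str) -> "VAE":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["config_json"].tobytes()).decode())
            init_keys = cls().get_params().keys()
            model = cls(**{k: cfg[k] for k in init_keys})
            model._init_networks(cfg["input_dim"])
            for i, p in enumerate(model.parameters()):
                p.data[:] = data[f"param_{i}"]
        model.dictionary_ = model.decoder_.dictionary.copy()
        return model

    def export_dictionary(self, csv_path: str | None = None,
                          png_path: str | None = None) -> np.ndarray:
        """Export Φ as a numeric matrix and/or an image grid.

        Tiles are ordered by per-latent KL ascending when available.
        """
        Phi = self.decoder_.dictionary
        order = np.argsort(self.kl_per_latent_) \
            if getattr(self, "kl_per_latent_", None) is not None \
            else np.arange(Phi.shape[1])
        if csv_path:
            np.savetxt(csv_path, Phi, delimiter=",")
        if png_path:
            _save_dictionary_grid(Phi[:, order], png_path)
        return Phi

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "dictionary_")


def _save_dictionary_grid(Phi: np.ndarray, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    M, K = Phi.shape
    side = int(round(np.sqrt(M)))
    ncols = int(np.ceil(np.sqrt(K)))
    nrows = int(np.ceil(K / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(ncols * 0.6, nrows * 0.6))
    for ax in np.atleast_1d(axes).ravel():
        ax.axis("off")
    for j in range(K):
        ax = np.atleast_1d(axes).ravel()[j]
        ax.imshow(Phi[:, j].reshape(side, side), cmap="gray")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
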