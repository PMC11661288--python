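"""Representation-geometry and sparsity metrics, plus the seed-level
statistical protocol.

Covers: lifetime sparsity (a selectivity index in [0, 1] per latent),
active-latent fraction from the per-latent KL distribution (dead-neuron /
posterior-collapse detection), deterministic representation extraction,
the limited-label KNN sample-efficiency protocol, shattering
dimensionality (mean linear-classification accuracy over all balanced
class dichotomies), and paired t-tests with Benjamini-Hochberg FDR
correction over seeds.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from statsmodels.stats.multitest import multipletests

from ._rng import as_generator
from .errors import ConfigError, ContractError

__all__ = ["lifetime_sparsity", "active_fraction", "extract_representation",
           "knn_protocol", "shattering_dimensionality", "seed_protocol_stats"]

logger = logging.getLogger(__name__)


def lifetime_sparsity(responses: np.ndarray,
                      signed: bool = False) -> tuple[np.ndarray, float]:
    """Lifetime sparsity per latent and its mean.

    For responses ``z`` of shape (N images, K latents),

        s_j = (1 − 1/N)⁻¹ · (1 − (Σ_i z_ij)² / (N · Σ_i z_ij²)),

    which is 1 when unit j responds to exactly one stimulus and 0 when it
    responds identically to all stimuli. For signed latent families pass
    ``signed=True`` to use response magnitudes |z| (selectivity should not
    depend on response sign; a unit-variance Gaussian noise latent then
    scores 1 − 2/π ≈ 0.36). All-zero columns get s = 0 with a warning.

    Returns ``(s, s.mean())`` with ``s`` of shape (K,).
    """
    z = np.atleast_2d(np.asarray(responses, dtype=np.float64))
    N = z.shape[0]
    if N < 2:
        raise ContractError("lifetime sparsity needs N >= 2 stimuli")
    if signed:
        z = np.abs(z)
    elif np.any(z < 0):
        raise ContractError("responses must be nonnegative; use signed=True "
                            "for signed latent families")
    sum_z = z.sum(axis=0)
    sum_z2 = (z ** 2).sum(axis=0)
    s = np.zeros(z.shape[1])
    alive = sum_z2 > 0
    if not alive.all():
        logger.warning("%d all-zero latents; their sparsity is set to 0",
                       int((~alive).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = 1.0 - (sum_z[alive] ** 2) / (N * sum_z2[alive])
    s[alive] = raw / (1.0 - 1.0 / N)
    s = np.clip(s, 0.0, 1.0)  # guard float round-off at the endpoints
    return s, float(s.mean())


def active_fraction(kl_per_latent: np.ndarray,
                    fallback_threshold: float = 0.01,
                    eps: float = 1e-12) -> tuple[float, float]:
    """Fraction of latents whose KL is above the dead/alive threshold.

    Collapsed ("dead") latents have near-zero KL and show up as a separate
    low mode in the histogram of log10(KL). The threshold is placed in the
    widest empty gap of a Freedman-Diaconis histogram of log10(KL + eps)
    that separates the lowest mode from the rest; if the histogram has no
    empty bin, an absolute threshold of ``fallback_threshold`` nats is
    used. Returns ``(fraction, threshold)`` with the threshold on the KL
    (not log) scale.
    """
    kl = np.asarray(kl_per_latent, dtype=np.float64)
    if kl.ndim != 1 or kl.size < 1:
        raise ContractError("kl_per_latent must be a nonempty 1-D array")
    if np.any(kl < 0):
        raise ContractError("KL values must be nonnegative")
    if np.all(kl <= eps):
        return 0.0, fallback_threshold
    logkl = np.log10(kl + eps)
    counts, edges = np.histogram(logkl, bins="fd")
    empty = np.flatnonzero(counts == 0)
    threshold = fallback_threshold
    if empty.size:
        # group consecutive empty bins into gaps; pick the widest gap that
        # has occupied bins on both sides (separates the low mode)
        groups = np.split(empty, np.flatnonzero(np.diff(empty) > 1) + 1)
        best = None
        for g in groups:
            if g[0] == 0 or g[-1] == counts.size - 1:
                continue  # gap at the boundary separates nothing
            width = edges[g[-1] + 1] - edges[g[0]]
            if best is None or width > best[0]:
                best = (width, 0.5 * (edges[g[0]] + edges[g[-1] + 1]))
        if best is not None:
            threshold = 10 ** best[1] - eps
    fraction = float(np.mean(kl > threshold))
    return fraction, float(threshold)


def extract_representation(model, X: np.ndarray) -> np.ndarray:
    """Deterministic (sample-free) representation for downstream tasks.

    Dispatches on the model's latent family: log δr for Poisson, μ for
    Gaussian, location for Laplace, flattened logits for Categorical.
    """
    if not hasattr(model, "transform"):
        raise ConfigError("model must expose transform() (a fitted VAE)")
    return model.transform(X)


def knn_protocol(representations: np.ndarray, labels: np.ndarray,
                 test_representations: np.ndarray, test_labels: np.ndarray,
                 n_train_grid=(200, 1000, 5000), k_neighbors: int = 5,
                 n_resamples: int = 10, rng=None) -> pd.DataFrame:
    """KNN classification accuracy at limited label budgets.

    For each ``n_train``, subsamples that many labeled examples without
    replacement from the train pool, fits a KNN classifier (Euclidean,
    ``k_neighbors`` neighbors), and scores on the full test pool; repeated
    ``n_resamples`` times with the mean reported.
    """
    X = np.asarray(representations, dtype=np.float64)
    y = np.asarray(labels)
    Xt = np.asarray(test_representations, dtype=np.float64)
    yt = np.asarray(test_labels)
    if X.shape[0] != y.shape[0] or Xt.shape[0] != yt.shape[0]:
        raise ContractError("representations and labels must align")
    rng = as_generator(rng)
    rows = []
    for n_train in n_train_grid:
        if n_train > X.shape[0]:
            raise ContractError(f"n_train={n_train} exceeds the train pool "
                                f"({X.shape[0]})")
        accs = []
        for _ in range(n_resamples):
            idx = rng.choice(X.shape[0], size=n_train, replace=False)
            knn = KNeighborsClassifier(n_neighbors=min(k_neighbors, n_train))
            knn.fit(X[idx], y[idx])
            accs.append(knn.score(Xt, yt))
        rows.append({"n_train": int(n_train), "accuracy": float(np.mean(accs)),
                     "accuracy_std": float(np.std(accs))})
    return pd.DataFrame(rows)


def shattering_dimensionality(representations: np.ndarray, labels: np.ndarray,
                              test_representations: np.ndarray | None = None,
                              test_labels: np.ndarray | None = None,
                              C: float = 1.0, max_iter: int = 1000
                              ) -> tuple[float, int]:
    """Mean linear-classification accuracy over all balanced dichotomies.

    With ``c`` classes, every assignment of ``c/2`` classes to one group
    (complementary assignments counted separately: C(c, c/2) dichotomies,
    252 for c = 10) defines a binary task. A logistic-regression classifier
    is trained per dichotomy on the train pool and scored on the test pool
    (train pool if none given). Returns ``(mean_accuracy, n_dichotomies)``.
    """
    X = np.asarray(representations, dtype=np.float64)
    y = np.asarray(labels)
    if test_representations is None:
        Xt, yt = X, y
    else:
        Xt = np.asarray(test_representations, dtype=np.float64)
        yt = np.asarray(test_labels)
    classes = np.unique(np.concatenate([y, yt]))
    if classes.size % 2 != 0:
        raise ContractError("shattering requires an even number of classes")
    half = classes.size // 2
    accs = []
    count = 0
    for group in combinations(classes, half):
        mask = np.isin(y, group)
        clf = LogisticRegression(C=C, max_iter=max_iter)
        clf.fit(X, mask.astype(int))
        accs.append(clf.score(Xt, np.isin(yt, group).astype(int)))
        count += 1
    return float(np.mean(accs)), count


def seed_protocol_stats(per_seed_values: pd.DataFrame, metric: str,
                        baseline_model: str | None = None,
                        confidence: float = 0.99,
                        fdr_q: float = 0.01) -> pd.DataFrame:
    """Seed-level protocol: t-based CIs and BH-FDR-corrected paired t-tests.

    ``per_seed_values`` must have columns ``model``, ``seed`` and the named
    metric, with every model trained on the same seed set (paired design).
    Each model gets a ``confidence``-level CI over seeds; if
    ``baseline_model`` is given, every other model is compared to it with a
    paired t-test and the p-values are Benjamini-Hochberg adjusted at
    ``fdr_q``.
    """
    df = per_seed_values
    for col in ("model", "seed", metric):
        if col not in df.columns:
            raise ContractError(f"missing column {col!r}")
    models = sorted(df["model"].unique())
    seed_sets = {m: tuple(sorted(df.loc[df["model"] == m, "seed"])) for m in models}
    if len(set(seed_sets.values())) != 1:
        raise ContractError("paired design requires identical seed sets "
                            "across models")
    rows = []
    pvals, compared = [], []
    for m in models:
        vals = df.loc[df["model"] == m].sort_values("seed")[metric].to_numpy()
        n = vals.size
        mean = float(vals.mean())
        if n > 1 and vals.std(ddof=1) > 0:
            half = stats.t.ppf(0.5 + confidence / 2, df=n - 1) * \
                vals.std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
        row = {"model": m, "mean": mean, "ci_low": mean - half,
               "ci_high": mean + half, "n_seeds": n}
        if baseline_model is not None and m != baseline_model:
            base = df.loc[df["model"] == baseline_model] \
                .sort_values("seed")[metric].to_numpy()
            diff = vals - base
            if np.allclose(diff.std(ddof=1) if n > 1 else 0.0, 0.0):
                p = 1.0 if np.allclose(diff, 0.0) else 0.0
                warnings.warn("zero-variance paired differences; p set by "
                              "whether the difference is identically zero")
            else:
                p = float(stats.ttest_rel(vals, base).pvalue)
            row["p_value"] = p
            pvals.append(p)
            compared.append(m)
        rows.append(row)
    out = pd.DataFrame(rows)
    if pvals:
        reject, p_adj, _, _ = multipletests(pvals, alpha=fdr_q, method="fdr_bh")
        adj = dict(zip(compared, zip(p_adj, reject)))
        out["p_adjusted"] = out["model"].map(
            lambda m: adj[m][0] if m in adj else np.nan)
        out["significant"] = out["model"].map(
            lambda m: bool(adj[m][1]) if m in adj else False)
    return out
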