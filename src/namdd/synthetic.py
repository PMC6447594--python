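"""Benchmark data generator with a genuine methylation -> gene -> disease
causal chain.

A block of causal methylation sites carries class-dependent signal: entry
(i, j) ~ Normal(class_shift * z_i * s_j, 1) with a random per-site sign s_j,
so cases and controls differ in mean at every causal site.  A fully
connected three-layer sigmoid network (causal sites -> hidden "gene" layer
-> disease status) is trained by full-batch backpropagation until it
predicts the status labels with accuracy above ``target_acc``; the hidden
activations then become the causal gene-expression columns, which guarantees
the expression layer genuinely mediates between methylation and disease.
Null sites are N(0, 1) draws and null genes are Gaussian with the causal
genes' pooled mean and variance; N(0, 1) noise is added to the null block by
default.  Columns are shuffled and the causal indices recorded as ground
truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import NamddError, OmicsDataset, ValidationError

logger = logging.getLogger("namdd")

__all__ = [
    "GeneratorSettings",
    "SyntheticDataset",
    "generate_labels",
    "generate_causal_methylation",
    "train_signal_network",
    "assemble_dataset",
]


class GenerationError(NamddError):
    """The signal network could not reach the target accuracy."""


@dataclass
class GeneratorSettings:
    """Benchmark conditions: 1000 sites and 100 genes of which 150 sites and
    10 genes (or 300 and 30) are causal, balanced labels, and a network
    trained to >95% label accuracy."""

    N: int = 200
    P_total: int = 1000
    Q_total: int = 100
    n_causal_sites: int = 150
    n_causal_genes: int = 10
    target_acc: float = 0.95
    max_epochs: int = 5000
    learning_rate: float = 0.5
    class_shift: float = 1.0
    noise_target: str = "null"  # "null", "all" or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 20:
            raise ValidationError("N must be >= 20")
        if not (0 < self.n_causal_sites < self.P_total):
            raise ValidationError("need 0 < n_causal_sites < P_total")
        if not (0 < self.n_causal_genes < self.Q_total):
            raise ValidationError("need 0 < n_causal_genes < Q_total")
        if not (0.5 < self.target_acc < 1):
            raise ValidationError("target_acc must be in (0.5, 1)")
        if self.noise_target not in ("null", "all", "none"):
            raise ValidationError("noise_target must be 'null', 'all' or 'none'")


@dataclass
class SyntheticDataset:
    data: OmicsDataset
    causal_site_idx: np.ndarray
    causal_gene_idx: np.ndarray
    nn_weights: dict[str, np.ndarray]
    train_accuracy: float
    settings: GeneratorSettings = field(repr=False, default=None)


def generate_labels(N: int, seed: int = 0) -> np.ndarray:
    """Balanced binary status: floor(N/2) zeros, ceil(N/2) ones, shuffled."""
    if N < 2:
        raise ValidationError("N must be >= 2")
    z = np.concatenate([np.zeros(N // 2, dtype=int), np.ones(N - N // 2, dtype=int)])
    return np.random.default_rng(seed).permutation(z)


def generate_causal_methylation(
    z: np.ndarray, n_causal: int, class_shift: float, seed: int
) -> np.ndarray:
    """N x n_causal matrix with entry (i, j) ~ Normal(class_shift * z_i * s_j, 1).

    The random per-site sign s_j makes hyper- and hypo-methylated disease
    sites equally likely; class-conditional means differ at every site when
    class_shift > 0.
    """
    z = np.asarray(z)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=n_causal)
    means = class_shift * np.outer(z, signs)
    return means + rng.standard_normal((len(z), n_causal))


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(t, -500, 500)))


def train_signal_network(
    X_causal: np.ndarray,
    z: np.ndarray,
    settings: GeneratorSettings,
) -> tuple[dict[str, np.ndarray], float]:
    """Train the causal-sites -> hidden -> status network by backprop.

    Fully connected, sigmoid hidden and output units, cross-entropy loss,
    full-batch gradient descent.  Training stops as soon as label accuracy
    exceeds ``target_acc``; up to 5 fresh initializations are tried before
    giving up.
    """
    X = np.asarray(X_causal, dtype=float)
    z = np.asarray(z, dtype=float)
    n, p = X.shape
    h = settings.n_causal_genes
    lr = settings.learning_rate
    for attempt in range(5):
        rng = np.random.default_rng(settings.seed + 1000 * attempt + 1)
        W1 = rng.normal(0.0, 1.0 / np.sqrt(p), size=(p, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, 1))
        b2 = np.zeros(1)
        for _epoch in range(settings.max_epochs):
            H = _sigmoid(X @ W1 + b1)  # N x h
            out = _sigmoid(H @ W2 + b2)[:, 0]  # N
            acc = float(np.mean((out > 0.5) == (z > 0.5)))
            if acc > settings.target_acc:
                weights = {"W1": W1, "b1": b1, "W2": W2, "b2": b2}
                return weights, acc
            # cross-entropy backprop, full batch
            delta_out = (out - z)[:, None] / n  # N x 1
            gW2 = H.T @ delta_out
            gb2 = delta_out.sum(axis=0)
            delta_h = (delta_out @ W2.T) * H * (1.0 - H)  # N x h
            gW1 = X.T @ delta_h
            gb1 = delta_h.sum(axis=0)
            W1 -= lr * gW1
            b1 -= lr * gb1
            W2 -= lr * gW2
            b2 -= lr * gb2
        logger.warning(
            "signal network attempt %d stalled at accuracy %.3f", attempt + 1, acc
        )
    raise GenerationError(
        f"could not exceed {settings.target_acc:.0%} training accuracy in 5 "
        "initializations; consider a larger class_shift"
    )


def assemble_dataset(settings: GeneratorSettings | None = None, **kwargs) -> SyntheticDataset:
    """Generate a complete benchmark dataset.

    Causal gene columns are the trained network's hidden-layer activations;
    null sites are N(0,1); null genes are Gaussian matched to the causal
    genes' pooled mean and variance; N(0,1) noise is added per
    ``noise_target``; columns are shuffled with the causal indices recorded.
    """
    if settings is None:
        settings = GeneratorSettings(**kwargs)
    rng = np.random.default_rng(settings.seed)
    z = generate_labels(settings.N, seed=settings.seed)
    X_causal = generate_causal_methylation(
        z, settings.n_causal_sites, settings.class_shift, seed=settings.seed + 1
    )
    weights, acc = train_signal_network(X_causal, z, settings)
    H = _sigmoid(X_causal @ weights["W1"] + weights["b1"])

    n_null_sites = settings.P_total - settings.n_causal_sites
    n_null_genes = settings.Q_total - settings.n_causal_genes
    X_null = rng.standard_normal((settings.N, n_null_sites))
    gene_mu = float(H.mean())
    gene_sd = float(H.std())
    Y_null = rng.normal(gene_mu, gene_sd, size=(settings.N, n_null_genes))

    X = np.hstack([X_causal, X_null])
    Y = np.hstack([H, Y_null])
    if settings.noise_target == "all":
        X = X + rng.standard_normal(X.shape)
        Y = Y + rng.standard_normal(Y.shape)
    elif settings.noise_target == "null":
        X[:, settings.n_causal_sites:] += rng.standard_normal((settings.N, n_null_sites))
        Y[:, settings.n_causal_genes:] += rng.standard_normal((settings.N, n_null_genes))

    site_perm = rng.permutation(settings.P_total)
    gene_perm = rng.permutation(settings.Q_total)
    X = X[:, site_perm]
    Y = Y[:, gene_perm]
    causal_sites = np.sort(np.argsort(site_perm)[: settings.n_causal_sites])
    causal_genes = np.sort(np.argsort(gene_perm)[: settings.n_causal_genes])

    data = OmicsDataset(
        X=X,
        Y=Y,
        z=z,
        sample_ids=[f"s{i}" for i in range(settings.N)],
        site_ids=[f"cg{p:05d}" for p in range(settings.P_total)],
        gene_ids=[f"g{q:03d}" for q in range(settings.Q_total)],
    )
    return SyntheticDataset(
        data=data,
        causal_site_idx=causal_sites,
        causal_gene_idx=causal_genes,
        nn_weights=weights,
        train_accuracy=acc,
        settings=settings,
    )
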