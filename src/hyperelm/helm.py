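"""Hypercomplex extreme learning machine (HELM).

A HELM classifies samples described by d+1 registered channels (e.g. the
blue/green/red/near-infrared bands of a multispectral palmprint) without an
explicit fusion step.  Each channel j gets its own random input weights
alpha^(j) and hidden matrix ``H^(j) = g([X^(j), 1] alpha^(j))``; the d+1
hidden matrices become the components of one hypercomplex hidden matrix
(channel 0 -> real part, channel j+1 -> unit e_j).  Targets are one-hot in
*every* component — the winning entry carries ``1 + e_1 + ... + e_d``.  The
output weights are the hypercomplex ridge solution of

    (H^H H + lambda I) beta = H^H T

solved either exactly through the real-embedding solver (default) or by the
blockwise recursive hypercomplex inverse.  At test time the network output
of a sample is a hypercomplex row per class; each of its d+1 components is
min-max rescaled by the training-output extrema of that component/node and
the rescaled components are summed (a sum-rule fusion across channels).
The predicted class is the argmax of the fused score.

With a single channel (d=0) everything above collapses to the ordinary
real-valued ELM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import MultichannelDataset
from .elm import ZERO_RIDGE_JITTER, _seed_streams, hidden_matrix, init_input_weights, one_hot_targets
from .hypercomplex import (
    HCMatrix,
    hc_block_inverse,
    hc_hermitian,
    hc_identity,
    hc_matmul,
    real_embed_solve,
)

__all__ = [
    "FusionStats",
    "HELMModel",
    "channel_hidden_matrix",
    "assemble_hidden",
    "encode_targets",
    "solve_output_weights",
    "helm_train",
    "helm_forward",
    "compute_fusion_stats",
    "fuse_scores",
    "helm_scores",
    "helm_predict",
]

SOLVERS = ("real_embedding", "blockwise")


@dataclass
class FusionStats:
    """Per-component, per-output-node extrema of the training outputs.

    ``min_t`` and ``max_t`` are (d+1) x m: row k holds the minimum/maximum
    of output component k at each of the m output nodes over all training
    samples.  They are the rescaling constants of the sum-rule fusion.
    """

    min_t: np.ndarray
    max_t: np.ndarray

    def __post_init__(self) -> None:
        self.min_t = np.asarray(self.min_t, dtype=float)
        self.max_t = np.asarray(self.max_t, dtype=float)
        if self.min_t.shape != self.max_t.shape:
            raise ValueError("min_t and max_t must share a shape")
        if np.any(self.max_t < self.min_t):
            raise ValueError("max_t must dominate min_t elementwise")


@dataclass
class HELMModel:
    """A trained HELM: d+1 real input-weight matrices, hypercomplex output
    weights, fusion statistics and the training configuration."""

    alphas: list[np.ndarray]       # d+1 matrices, each (n+1) x n_hidden
    beta: HCMatrix                 # n_hidden x m, d+1 components
    fusion_stats: FusionStats | None
    activation: str
    ridge: float
    solver: str
    n_classes: int
    channel_names: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.alphas) != self.beta.d + 1:
            raise ValueError("one input-weight matrix per hypercomplex component")
        if not self.channel_names:
            self.channel_names = [f"channel{j}" for j in range(len(self.alphas))]

    @property
    def d(self) -> int:
        return self.beta.d

    @property
    def n_features(self) -> int:
        return self.alphas[0].shape[0] - 1

    @property
    def n_hidden(self) -> int:
        return self.alphas[0].shape[1]


def channel_hidden_matrix(X_j: np.ndarray, alpha_j: np.ndarray, activation: str) -> np.ndarray:
    """Hidden matrix of one channel: ``g([X_j, 1] alpha_j)``."""
    return hidden_matrix(X_j, alpha_j, activation)


def assemble_hidden(H_list) -> HCMatrix:
    """Stack per-channel hidden matrices into one hypercomplex matrix.

    Channel 0 becomes the real component, channel j+1 the coefficient matrix
    of e_j — the dataset's channel order, recorded in the model, fixes the
    channel-to-unit mapping.
    """
    mats = [np.asarray(H, dtype=float) for H in H_list]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError("hidden matrices must share one shape")
    return HCMatrix(np.stack(mats))


def encode_targets(labels, n_classes: int, d: int) -> HCMatrix:
    """Hypercomplex one-hot targets: the winning entry is 1 in every component.

    Entry (i, label_i) equals ``1 + e_1 + ... + e_d``; all other entries are
    zero, expressing that every channel of a sample shares the same class.
    """
    T = one_hot_targets(labels, n_classes)
    return HCMatrix(np.broadcast_to(T, (d + 1,) + T.shape).copy())


def solve_output_weights(
    H: HCMatrix,
    T: HCMatrix,
    ridge: float = 0.0,
    solver: str = "real_embedding",
) -> HCMatrix:
    """Solve ``(H^H H + lambda I) beta = H^H T`` for the output weights.

    ``real_embedding`` (default) treats left-multiplication by the
    regularized Gram matrix as the real-linear map it is and solves one real
    system exactly; ``blockwise`` inverts the Gram matrix by the recursive
    Schur-complement inverse and multiplies.  The two agree for d <= 1; for
    d >= 2 the algebra is non-associative and only the embedding route has
    an exact residual guarantee.
    """
    if solver not in SOLVERS:
        raise ValueError(f"unknown solver {solver!r}; expected one of {SOLVERS}")
    lam = float(ridge)
    if lam < 0:
        raise ValueError("ridge parameter must be non-negative")
    if lam == 0.0:
        lam = ZERO_RIDGE_JITTER
    Hh = hc_hermitian(H)
    gram = hc_matmul(Hh, H) + lam * hc_identity(H.cols, H.d)
    rhs = hc_matmul(Hh, T)
    if solver == "real_embedding":
        return real_embed_solve(gram, rhs)
    return hc_matmul(hc_block_inverse(gram), rhs)


def helm_train(
    dataset: MultichannelDataset,
    n_hidden: int = 1000,
    activation: str = "sigmoid",
    ridge: float = 0.0,
    solver: str = "real_embedding",
    seed=0,
) -> HELMModel:
    """Train a HELM on a multichannel dataset.

    The d+1 input-weight matrices are drawn from mutually independent
    streams spawned from the master seed (stream j for channel j), so the
    d=0 model reproduces a plain ELM trained with the same seed exactly.
    """
    d = dataset.d
    rngs = _seed_streams(seed, d + 1)
    n = dataset.n_features
    alphas = [init_input_weights(n, n_hidden, rng) for rng in rngs]
    H_list = [
        channel_hidden_matrix(X, a, activation)
        for X, a in zip(dataset.channels, alphas)
    ]
    H = assemble_hidden(H_list)
    T = encode_targets(dataset.labels, dataset.n_classes, d)
    beta = solve_output_weights(H, T, ridge=ridge, solver=solver)
    model = HELMModel(
        alphas=alphas,
        beta=beta,
        fusion_stats=None,
        activation=activation,
        ridge=float(ridge),
        solver=solver,
        n_classes=dataset.n_classes,
        channel_names=list(dataset.channel_names),
        seed=seed if isinstance(seed, int) else None,
    )
    model.fusion_stats = compute_fusion_stats(model, dataset)
    return model


def _channel_matrices(model: HELMModel, channels) -> list[np.ndarray]:
    if isinstance(channels, MultichannelDataset):
        channels = channels.channels
    channels = [np.atleast_2d(np.asarray(c, dtype=float)) for c in channels]
    if len(channels) != model.d + 1:
        raise ValueError(
            f"model expects {model.d + 1} channels, got {len(channels)}"
        )
    for c in channels:
        if c.shape[1] != model.n_features:
            raise ValueError(
                f"expected {model.n_features} features per channel, got {c.shape[1]}"
            )
    return channels


def helm_forward(model: HELMModel, channels) -> np.ndarray:
    """Raw hypercomplex network outputs for a batch of samples.

    Returns an array of shape (d+1, N, m): component k of the output row of
    each sample at each output node.  The hidden hypercomplex row of a
    sample is ``sum_k g([x^(k), 1] alpha^(k)) * (unit k)`` and the output is
    its hypercomplex product with the output-weight matrix.
    """
    mats = _channel_matrices(model, channels)
    H = assemble_hidden([
        channel_hidden_matrix(X, a, model.activation)
        for X, a in zip(mats, model.alphas)
    ])
    return hc_matmul(H, model.beta).components


def compute_fusion_stats(model: HELMModel, dataset: MultichannelDataset) -> FusionStats:
    """Min/max of every output component at every node over the training set."""
    if dataset.n_samples == 0:
        raise ValueError("cannot compute fusion statistics on an empty dataset")
    nt = helm_forward(model, dataset)            # (d+1, N, m)
    return FusionStats(min_t=nt.min(axis=1), max_t=nt.max(axis=1))


def fuse_scores(nt: np.ndarray, stats: FusionStats) -> np.ndarray:
    """Sum-rule fusion of the d+1 output components.

    Each component/node score is rescaled by the training extrema,
    ``(nt_k(j) - min_k(j)) / (max_k(j) - min_k(j))``, and the rescaled
    components are summed.  A node whose training outputs were constant in a
    component (max = min) contributes zero for that component — the limit of
    an uninformative node.  Test values outside the training range are kept
    as-is (no clipping), so fused scores can leave [0, d+1].

    ``nt`` is (d+1, m) for one sample or (d+1, N, m) for a batch; the fused
    score has shape (m,) or (N, m) accordingly.
    """
    nt = np.asarray(nt, dtype=float)
    batched = nt.ndim == 3
    if not batched:
        nt = nt[:, None, :]
    span = stats.max_t - stats.min_t          # (d+1, m)
    safe = np.where(span > 0, span, 1.0)
    scaled = (nt - stats.min_t[:, None, :]) / safe[:, None, :]
    scaled = np.where((span > 0)[:, None, :], scaled, 0.0)
    fused = scaled.sum(axis=0)
    return fused if batched else fused[0]


def helm_scores(model: HELMModel, channels) -> np.ndarray:
    """Fused per-class scores, one row per sample."""
    if model.fusion_stats is None:
        raise ValueError("model has no fusion statistics; train it first")
    return fuse_scores(helm_forward(model, channels), model.fusion_stats)


def helm_predict(model: HELMModel, channels) -> np.ndarray:
    """Argmax of the fused score; ties break to the lowest class id."""
    return np.argmax(helm_scores(model, channels), axis=1)
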