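"""Baseline real-valued extreme learning machine and conventional fusion.

An extreme learning machine (ELM) trains a single-hidden-layer feedforward
network without iteration: the input weights are drawn once from a uniform
distribution on [-1, 1] and frozen, and the output weights are the ridge
least-squares solution

    beta = (H^T H + lambda I)^-1 H^T T

where H = g([X, 1] alpha) is the hidden-layer output matrix and T the
one-hot target matrix.  Two conventional ways of handling multichannel
inputs are included as baselines: feature-level fusion (concatenate the
channel vectors, train one ELM) and matching-score-level fusion (one ELM
per channel, min-max normalised output scores summed across channels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import MultichannelDataset

__all__ = [
    "ELMModel",
    "apply_activation",
    "init_input_weights",
    "elm_train",
    "elm_scores",
    "elm_predict",
    "feature_fusion_elm_train",
    "feature_fusion_elm_predict",
    "score_fusion_elm",
]

ACTIVATIONS = ("sigmoid", "sin", "atan")

#: diagonal jitter used when the ridge parameter is exactly zero, so the
#: unregularized normal equations stay numerically invertible
ZERO_RIDGE_JITTER = 1e-8


def apply_activation(Z: np.ndarray, kind: str) -> np.ndarray:
    """Elementwise hidden-node nonlinearity: sigmoid, sin or atan."""
    Z = np.asarray(Z, dtype=float)
    if kind == "sigmoid":
        # scipy.special.expit semantics, written out to avoid overflow warnings
        out = np.empty_like(Z)
        pos = Z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-Z[pos]))
        ez = np.exp(Z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    if kind == "sin":
        return np.sin(Z)
    if kind == "atan":
        return np.arctan(Z)
    raise ValueError(f"unknown activation {kind!r}; expected one of {ACTIVATIONS}")


def _seed_streams(seed, count: int) -> list[np.random.Generator]:
    """Derive ``count`` independent generators from one master seed.

    The hypercomplex model draws one stream per channel from the same
    derivation, so a single-channel model and the d=0 hypercomplex model see
    identical input weights for the same seed.  A Generator passed directly
    is used as-is (``count`` must then be 1).
    """
    if isinstance(seed, np.random.Generator):
        if count != 1:
            raise ValueError("a Generator seed can only feed one stream")
        return [seed]
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(count)]


def init_input_weights(n: int, n_hidden: int, rng) -> np.ndarray:
    """Random (n+1) x n_hidden input weights, i.i.d. uniform on [-1, 1].

    The extra row multiplies the constant-1 bias column appended to inputs.
    ``rng`` may be a Generator or anything acceptable as a numpy seed.
    """
    if n < 1 or n_hidden < 1:
        raise ValueError("n and n_hidden must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.uniform(-1.0, 1.0, size=(n + 1, n_hidden))


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.hstack([X, np.ones((X.shape[0], 1))])


def hidden_matrix(X: np.ndarray, alpha: np.ndarray, activation: str) -> np.ndarray:
    """Hidden-layer output matrix H = g([X, 1] alpha)."""
    return apply_activation(_augment(X) @ alpha, activation)


def one_hot_targets(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError("labels out of range")
    T = np.zeros((labels.size, n_classes))
    T[np.arange(labels.size), labels] = 1.0
    return T


def ridge_solve(H: np.ndarray, T: np.ndarray, ridge: float) -> np.ndarray:
    """Solve the normal equations (H^T H + lambda I) beta = H^T T."""
    lam = float(ridge)
    if lam < 0:
        raise ValueError("ridge parameter must be non-negative")
    if lam == 0.0:
        lam = ZERO_RIDGE_JITTER
    gram = H.T @ H + lam * np.eye(H.shape[1])
    return np.linalg.solve(gram, H.T @ T)


@dataclass
class ELMModel:
    """A trained ELM: frozen random input weights plus solved output weights."""

    alpha: np.ndarray          # (n+1) x n_hidden
    beta: np.ndarray           # n_hidden x n_classes
    activation: str
    ridge: float
    n_classes: int

    @property
    def n_features(self) -> int:
        return self.alpha.shape[0] - 1

    @property
    def n_hidden(self) -> int:
        return self.alpha.shape[1]


def elm_train(
    X: np.ndarray,
    labels: np.ndarray,
    n_hidden: int = 1000,
    activation: str = "sigmoid",
    ridge: float = 0.0,
    seed=0,
    n_classes: int | None = None,
) -> ELMModel:
    """Train an ELM classifier on real feature rows.

    With ``n_hidden`` equal to the sample count and ridge ~ 0, H is square
    and (generically) invertible, so the network interpolates the training
    targets exactly; the usual regime is n_hidden << N with a small ridge.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise ValueError("X must be (N, n) with one label per row")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in training inputs")
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    if len(np.unique(labels)) < n_classes:
        warnings.warn("some classes have no training samples", stacklevel=2)
    if n_hidden > X.shape[0]:
        warnings.warn(
            f"n_hidden={n_hidden} exceeds the sample count N={X.shape[0]}; "
            "the ridge solution is still defined but the extra capacity is idle",
            stacklevel=2,
        )
    (rng,) = _seed_streams(seed, 1)
    alpha = init_input_weights(X.shape[1], n_hidden, rng)
    H = hidden_matrix(X, alpha, activation)
    T = one_hot_targets(labels, n_classes)
    beta = ridge_solve(H, T, ridge)
    return ELMModel(alpha=alpha, beta=beta, activation=activation,
                    ridge=float(ridge), n_classes=n_classes)


def elm_scores(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Raw network outputs, one row of per-class scores per sample."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    return hidden_matrix(X, model.alpha, model.activation) @ model.beta


def elm_predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Argmax decode of the output row; ties break to the lowest class id."""
    return np.argmax(elm_scores(model, X), axis=1)


# ---------------------------------------------------------------------------
# conventional multichannel baselines
# ---------------------------------------------------------------------------

def _stack_channels(channels) -> np.ndarray:
    mats = [np.asarray(c, dtype=float) for c in channels]
    n_rows = {c.shape[0] for c in mats}
    if len(n_rows) != 1:
        raise ValueError("all channels must have the same number of samples")
    return np.hstack(mats)


def feature_fusion_elm_train(channels, labels, **config) -> ELMModel:
    """Feature-level fusion: concatenate channel vectors, train one ELM."""
    if isinstance(channels, MultichannelDataset):
        labels = channels.labels if labels is None else labels
        channels = channels.channels
    return elm_train(_stack_channels(channels), labels, **config)


def feature_fusion_elm_predict(model: ELMModel, channels) -> np.ndarray:
    if isinstance(channels, MultichannelDataset):
        channels = channels.channels
    return elm_predict(model, _stack_channels(channels))


def score_fusion_elm(
    channels_train,
    labels,
    channels_test,
    **config,
) -> np.ndarray:
    """Matching-score-level fusion across channels.

    One ELM is trained per channel.  Each network's output scores are
    min-max normalised per output node using the extrema of its *training*
    outputs, the normalised scores are summed across channels, and the
    argmax of the sum is the decision — the same sum rule the hypercomplex
    model applies to its output components.
    """
    if isinstance(channels_train, MultichannelDataset):
        labels = channels_train.labels if labels is None else labels
        channels_train = channels_train.channels
    if isinstance(channels_test, MultichannelDataset):
        channels_test = channels_test.channels
    if len(channels_train) != len(channels_test):
        raise ValueError("train and test must have the same channels")

    seed = config.pop("seed", 0)
    # every channel's network draws its weights from the same seed (input
    # weights depend only on dimensions and seed), so a single channel
    # reduces exactly to a plain ELM and duplicated channels sum equal terms
    fused = None
    for Xtr, Xte in zip(channels_train, channels_test):
        model = elm_train(Xtr, labels, seed=seed, **config)
        train_scores = elm_scores(model, Xtr)
        lo = train_scores.min(axis=0)
        hi = train_scores.max(axis=0)
        span = hi - lo
        test_scores = elm_scores(model, Xte)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(span > 0, (test_scores - lo) / np.where(span > 0, span, 1.0), 0.0)
        fused = norm if fused is None else fused + norm
    return np.argmax(fused, axis=1)
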