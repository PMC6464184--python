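"""The package's standard synthetic recognition benchmark.

One benchmark run generates a synthetic multichannel dataset, splits it in
half per class, and measures test recognition accuracy for:

* the hypercomplex model (HELM) at the standard and at a reduced hidden
  width (capacity trend);
* HELM on test images corrupted by each noise model (training images stay
  clean — robustness is probed at test time);
* a plain single-channel ELM per channel (is the multichannel model at
  least as good as its best single channel?);
* optionally the two conventional fusion baselines (feature-level and
  matching-score-level).

Aggregating over independent seeds gives the mean accuracies the package's
qualitative claims are stated on.  All accuracies are percentages.
"""

from __future__ import annotations

import numpy as np

from .elm import elm_predict, elm_train, feature_fusion_elm_predict, feature_fusion_elm_train, score_fusion_elm
from .evaluation import recognition_accuracy
from .helm import helm_predict, helm_train
from .preprocessing import stratified_split_indices
from .synthetic import SynthConfig, apply_noise, generate_images, images_to_dataset

__all__ = ["run_benchmark_seed", "run_benchmark", "DEFAULT_NOISE_KINDS"]

DEFAULT_NOISE_KINDS = ("gaussian", "saltpepper", "speckle")

#: hidden widths of the standard benchmark: the working width and the
#: deliberately narrow one used to expose the capacity trend
DEFAULT_N_HIDDEN = 500
SMALL_N_HIDDEN = 50


def run_benchmark_seed(
    seed: int,
    cfg: SynthConfig | None = None,
    n_hidden: int = DEFAULT_N_HIDDEN,
    n_hidden_small: int | None = SMALL_N_HIDDEN,
    activation: str = "sigmoid",
    ridge: float = 0.0,
    solver: str = "real_embedding",
    noise_kinds=DEFAULT_NOISE_KINDS,
    include_fusion_baselines: bool = False,
) -> dict[str, float]:
    """One full benchmark repetition driven by a single seed.

    The seed feeds four independent sub-streams: dataset synthesis, the
    train/test split, model initialisation and the test-time noise fields.
    Returns a flat dict of accuracy percentages.
    """
    cfg = cfg or SynthConfig()
    sub = np.random.default_rng(seed).integers(0, 2**31, size=4)
    data_seed, split_seed, model_seed, noise_seed = (int(s) for s in sub)

    images, labels = generate_images(cfg.with_seed(data_seed))
    tr, te = stratified_split_indices(labels, train_fraction=0.5, seed=split_seed)
    train_ds = images_to_dataset(images[tr], labels[tr])
    test_ds = images_to_dataset(images[te], labels[te])

    results: dict[str, float] = {}
    model = helm_train(
        train_ds, n_hidden=n_hidden, activation=activation,
        ridge=ridge, solver=solver, seed=model_seed,
    )
    results["helm"] = recognition_accuracy(helm_predict(model, test_ds), test_ds.labels)

    for kind in noise_kinds:
        noisy = apply_noise(images[te], kind, seed=noise_seed)
        noisy_ds = images_to_dataset(noisy, labels[te])
        results[f"helm_{kind}"] = recognition_accuracy(
            helm_predict(model, noisy_ds), noisy_ds.labels
        )

    if n_hidden_small is not None:
        small = helm_train(
            train_ds, n_hidden=n_hidden_small, activation=activation,
            ridge=ridge, solver=solver, seed=model_seed,
        )
        results["helm_small"] = recognition_accuracy(
            helm_predict(small, test_ds), test_ds.labels
        )

    for j, name in enumerate(train_ds.channel_names):
        elm = elm_train(
            train_ds.channels[j], train_ds.labels, n_hidden=n_hidden,
            activation=activation, ridge=ridge, seed=model_seed,
        )
        results[f"elm_{name}"] = recognition_accuracy(
            elm_predict(elm, test_ds.channels[j]), test_ds.labels
        )

    if include_fusion_baselines:
        ff = feature_fusion_elm_train(
            train_ds, None, n_hidden=n_hidden, activation=activation,
            ridge=ridge, seed=model_seed,
        )
        results["feature_fusion"] = recognition_accuracy(
            feature_fusion_elm_predict(ff, test_ds), test_ds.labels
        )
        sf_pred = score_fusion_elm(
            train_ds, None, test_ds, n_hidden=n_hidden,
            activation=activation, ridge=ridge, seed=model_seed,
        )
        results["score_fusion"] = recognition_accuracy(sf_pred, test_ds.labels)

    return results


def run_benchmark(
    n_seeds: int = 10,
    master_seed: int = 0,
    **kwargs,
) -> dict[str, np.ndarray]:
    """Repeat :func:`run_benchmark_seed` over derived seeds; stack results.

    Returns a dict mapping each measured quantity to its array of per-seed
    accuracy percentages (use ``.mean()`` for the headline numbers).
    """
    seeds = np.random.default_rng(master_seed).integers(0, 2**31, size=n_seeds)
    collected: dict[str, list[float]] = {}
    for s in seeds:
        for key, val in run_benchmark_seed(int(s), **kwargs).items():
            collected.setdefault(key, []).append(val)
    return {k: np.asarray(v) for k, v in collected.items()}


def best_single_channel(results: dict[str, np.ndarray]) -> tuple[str, float]:
    """Name and mean accuracy of the best-performing single-channel ELM."""
    channel_means = {
        k: float(np.mean(v)) for k, v in results.items() if k.startswith("elm_")
    }
    if not channel_means:
        raise ValueError("no single-channel results present")
    name = max(channel_means, key=channel_means.get)
    return name, channel_means[name]
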