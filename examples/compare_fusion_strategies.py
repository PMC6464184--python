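"""Hypercomplex representation versus conventional multichannel fusion.

Runs the synthetic benchmark three ways — HELM, feature-level fusion
(concatenate channels, one wide ELM) and matching-score-level fusion (one
ELM per channel, min-max summed scores) — plus each single channel alone,
over three repetitions, and prints mean test accuracies.  Higher is
better; the single-channel rows show what any one band achieves by itself.
"""

import warnings

import numpy as np

from hyperelm.benchmark import run_benchmark

warnings.simplefilter("ignore")
results = run_benchmark(n_seeds=3, master_seed=0, n_hidden_small=None,
                        noise_kinds=(), include_fusion_baselines=True)
print(f"{'method':<22}{'mean RA (%)':>12}")
for key in ("helm", "feature_fusion", "score_fusion",
            *(k for k in results if k.startswith("elm_"))):
    print(f"{key:<22}{np.mean(results[key]):>12.2f}")
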