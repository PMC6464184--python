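"""Recognition accuracy, repeated-run protocol and significance testing.

Recognition accuracy is the percentage of test samples whose predicted
identity matches the truth.  Because ELM-family training is randomized,
experiments are repeated over independent seeds and summarised as
mean +/- standard deviation.  Pairs of repeated-run accuracy series are
compared with the classical one-sided two-sample pooled-variance Student
t-test:

    t = (mean(x) - mean(y)) / sqrt(S_p^2 (1/n1 + 1/n2)),
    S_p^2 = ((n1-1) S1^2 + (n2-1) S2^2) / (n1 + n2 - 2)

with n1 + n2 - 2 degrees of freedom and a right-sided p-value; the null
(x's mean does not exceed y's) is rejected when p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as scipy_stats

__all__ = [
    "EvalReport",
    "TTestResult",
    "recognition_accuracy",
    "repeated_runs",
    "two_sample_t_test",
]


@dataclass
class EvalReport:
    """Accuracies (percent) of repeated randomized runs plus their summary."""

    accuracies: list[float]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        accs = [float(a) for a in self.accuracies]
        if not accs:
            raise ValueError("a report needs at least one run")
        if min(accs) < 0 or max(accs) > 100:
            raise ValueError("accuracies must be percentages in [0, 100]")
        self.accuracies = accs

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std(self) -> float:
        """Sample standard deviation (ddof=1); zero for a single run."""
        if len(self.accuracies) < 2:
            return 0.0
        return float(np.std(self.accuracies, ddof=1))

    def summary(self) -> str:
        return f"{self.mean:.2f}±{self.std:.2f}"


@dataclass
class TTestResult:
    """Right-sided pooled two-sample t-test outcome."""

    t: float
    p: float
    df: int
    alpha: float = 0.05

    @property
    def decision(self) -> str:
        """"H1" when the null of no improvement is rejected at ``alpha``."""
        return "H1" if self.p < self.alpha else "H0"


def recognition_accuracy(pred, truth) -> float:
    """Percentage of predictions equal to the truth."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    if pred.size == 0:
        raise ValueError("cannot score an empty test set")
    return 100.0 * float(np.mean(pred == truth))


def repeated_runs(run_fn, dataset, n_runs: int = 10, master_seed: int = 0,
                  config: dict | None = None) -> EvalReport:
    """Run ``run_fn(dataset, seed)`` over independent derived seeds.

    ``run_fn`` must return an accuracy percentage; a fresh seed (and hence
    fresh random input weights) is derived from the master seed for every
    run.  Derived seeds stay below 2**31.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = np.random.default_rng(master_seed).integers(0, 2**31, size=n_runs)
    accs = [float(run_fn(dataset, int(s))) for s in seeds]
    cfg = dict(config or {})
    cfg.setdefault("master_seed", master_seed)
    cfg.setdefault("n_runs", n_runs)
    return EvalReport(accuracies=accs, config=cfg)


def two_sample_t_test(x, y, alpha: float = 0.05) -> TTestResult:
    """One-sided (right) pooled-variance two-sample Student t-test.

    Tests H0: mean(x) <= mean(y) against H1: mean(x) > mean(y).  When the
    pooled variance vanishes the statistic is 0 if the means agree and
    +/- infinity otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least two measurements")
    df = n1 + n2 - 2
    s1 = np.var(x, ddof=1)
    s2 = np.var(y, ddof=1)
    pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
    diff = float(np.mean(x) - np.mean(y))
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    if denom == 0.0:
        t = 0.0 if diff == 0.0 else np.copysign(np.inf, diff)
    else:
        t = diff / denom
    p = float(scipy_stats.t.sf(t, df))
    return TTestResult(t=float(t), p=p, df=df, alpha=alpha)
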