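"""Half-sample bootstrap confidence intervals and rank-sum comparisons.

Confidence intervals on mean conservation statistics follow a
half-sample bootstrap: draw half of the values without replacement one
thousand times, compute each resampled mean, and take the 2.5th/97.5th
percentiles.  Distribution comparisons use the two-sided
Wilcoxon/Mann-Whitney rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = ["BootstrapResult", "bootstrap_mean_ci", "rank_sum_test"]


@dataclass
class BootstrapResult:
    estimate: float        # mean of the full sample
    ci_low: float
    ci_high: float
    n_resamples: int
    fraction: float
    seed: int


def bootstrap_mean_ci(
    values: Sequence[float],
    n_resamples: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    ci: float = 0.95,
) -> BootstrapResult:
    """Percentile CI of the mean from without-replacement half-samples."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 values to bootstrap")
    k = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)
    means = np.empty(n_resamples)
    for i in range(n_resamples):
        idx = rng.choice(n, size=k, replace=False)
        means[i] = values[idx].mean()
    alpha = (1.0 - ci) / 2.0
    low, high = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapResult(
        estimate=float(values.mean()),
        ci_low=float(low),
        ci_high=float(high),
        n_resamples=n_resamples,
        fraction=fraction,
        seed=seed,
    )


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test: (statistic, p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
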