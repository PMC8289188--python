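"""Summary statistics of AFM cross-sectional fibril heights.

AFM topographs of amyloid fibrils are summarized by the median
cross-sectional height, its median deviation and the number of
measurements.  "Median deviation" is the unscaled median absolute
deviation from the median — a descriptive spread, not a Gaussian sigma
estimate, so no 1.4826 consistency factor is applied.

A permutation test on the median difference (with a seeded bootstrap
confidence interval) quantifies shifts between conditions, e.g. the
broadening from 2.1 nm fibrils to ~3 nm protofilament aggregates seen
at high inhibitor ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "HeightSample",
    "HeightSummary",
    "HeightComparison",
    "height_summary",
    "compare_height_distributions",
]


class HeightInputError(ValueError):
    """Empty, nonpositive or undersized height samples."""


@dataclass
class HeightSample:
    """Cross-sectional heights (nm) for one incubation condition."""

    heights: NDArray[np.float64]
    condition: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.size == 0:
            raise HeightInputError("empty height sample")
        if np.any(self.heights <= 0) or not np.all(np.isfinite(self.heights)):
            raise HeightInputError("heights must be positive and finite")


@dataclass(frozen=True)
class HeightSummary:
    median: float  # nm
    median_deviation: float  # nm, median |h - median|
    n: int


@dataclass(frozen=True)
class HeightComparison:
    median_difference: float  # nm, median(b) - median(a)
    ci_low: float  # bootstrap CI on the difference
    ci_high: float
    p_value: float  # two-sided permutation p
    n_permutations: int


def height_summary(sample: HeightSample) -> HeightSummary:
    """Median, median deviation and count for a height sample."""
    med = float(np.median(sample.heights))
    mad = float(np.median(np.abs(sample.heights - med)))
    return HeightSummary(median=med, median_deviation=mad, n=int(sample.heights.size))


def compare_height_distributions(
    a: HeightSample,
    b: HeightSample,
    n_permutations: int = 10_000,
    n_bootstrap: int = 2_000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> HeightComparison:
    """Median height difference between two conditions with resampling inference.

    Returns median(b) − median(a) with a seeded percentile-bootstrap
    confidence interval and a two-sided permutation p-value obtained by
    shuffling condition labels (p = (1 + #{|perm| ≥ |obs|}) / (n + 1)).
    """
    if a.heights.size < 5 or b.heights.size < 5:
        raise HeightInputError("distribution comparison requires n >= 5 in both samples")
    rng = np.random.default_rng(seed)
    ha, hb = a.heights, b.heights
    obs = float(np.median(hb) - np.median(ha))

    pooled = np.concatenate([ha, hb])
    na = ha.size
    # vectorized label shuffles: one argsort of uniforms per permutation
    order = np.argsort(rng.random((n_permutations, pooled.size)), axis=1)
    perm = pooled[order]
    perm_diff = np.median(perm[:, na:], axis=1) - np.median(perm[:, :na], axis=1)
    p = float((1 + np.sum(np.abs(perm_diff) >= abs(obs))) / (n_permutations + 1))

    ia = rng.integers(0, na, size=(n_bootstrap, na))
    ib = rng.integers(0, hb.size, size=(n_bootstrap, hb.size))
    boot = np.median(hb[ib], axis=1) - np.median(ha[ia], axis=1)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])

    return HeightComparison(
        median_difference=obs,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        n_permutations=n_permutations,
    )
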