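"""Shared statistical containers and helpers for randomization nulls."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class NullDistribution:
    """Result of a randomization null for a scalar statistic.

    The empirical p-value is computed from a normal fit to the null
    distribution (tail probability of the observed value), which matches the
    practice of summarizing a Monte-Carlo null by its mean and SD.
    """

    statistic: str
    observed: float | None
    iterations: int
    values: np.ndarray = field(repr=False)
    seed: int | None = None
    tail: str = "upper"  # 'upper', 'lower' or 'two-sided'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def p(self) -> float | None:
        if self.observed is None:
            return None
        return normal_tail_p(self.observed, self.values, tail=self.tail)

    def central_interval(self, level: float = 0.99) -> tuple[float, float]:
        """Empirical central interval of the null (e.g. 99%)."""
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.values, [alpha, 1.0 - alpha])
        return float(lo), float(hi)


def normal_tail_p(observed: float, null_values: np.ndarray, tail: str = "upper") -> float:
    """Tail probability of `observed` under a normal fit to `null_values`."""
    null_values = np.asarray(null_values, dtype=float)
    mu = float(np.mean(null_values))
    sd = float(np.std(null_values, ddof=1)) if len(null_values) > 1 else 0.0
    if sd == 0.0:
        if tail == "upper":
            return float(observed <= mu)
        if tail == "lower":
            return float(observed >= mu)
        return float(observed == mu)
    z = (observed - mu) / sd
    if tail == "upper":
        return float(sps.norm.sf(z))
    if tail == "lower":
        return float(sps.norm.cdf(z))
    if tail == "two-sided":
        return float(2.0 * sps.norm.sf(abs(z)))
    raise ValueError(f"unknown tail: {tail!r}")


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile (inverted CDF), deterministic for ties."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("percentile threshold undefined for fewer than 2 values")
    if not 0 < q < 100:
        raise ValueError("percentile must be in (0, 100)")
    return float(np.percentile(values, q, method="inverted_cdf"))
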