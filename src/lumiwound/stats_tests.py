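"""Statistical tests: combined z statistic, t-tests, and linear regression.

The combined z statistic aggregates p-values from k paired one-tailed
t-tests (one per wound) into a single decision:

    Z_i = atanh(P_i),    Z_s = sum_i Z_i / sqrt(k)

with |Z_s| compared against a standard-normal critical bound (±1.96 at 95%
confidence).  This hyperbolic-arctangent transform of the p-values is the
method as originally described; note that it maps small (significant)
p-values to small Z_i, so the conventional Stouffer combination
Z_i = Phi^{-1}(1 - P_i) — under which small p-values push |Z_s| past the
bound — is available via ``method="stouffer"`` and is what the pipeline
uses for its directional decision flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

DEFAULT_Z_CRIT = 1.96


class StatsError(ValueError):
    """Raised for degenerate statistical input."""


@dataclass(frozen=True)
class CombinedZResult:
    """Combined z statistic over k per-wound p-values."""

    z_i: tuple[float, ...]
    z_s: float
    z_crit: float
    significant: bool
    k: int
    method: str


def combined_z_test(
    p_values: Sequence[float],
    alpha: float = 0.05,
    z_crit: float = DEFAULT_Z_CRIT,
    method: str = "atanh",
) -> CombinedZResult:
    """Combine k one-tailed p-values into a single z decision.

    ``method="atanh"`` (default) uses Z_i = atanh(p_i) exactly as described;
    p_i must lie in [0, 1) since atanh diverges at 1.  ``method="stouffer"``
    uses the conventional Z_i = Phi^{-1}(1 - p_i) (p_i clipped away from 0
    and 1 by 1e-300 to keep the quantile finite).  In both cases
    Z_s = sum(Z_i)/sqrt(k) and significance means |Z_s| > z_crit.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise StatsError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    if method == "atanh":
        if np.any(p >= 1):
            raise StatsError("atanh transform diverges at p = 1")
        z_i = np.arctanh(p)
    elif method == "stouffer":
        z_i = stats.norm.isf(np.clip(p, 1e-300, 1 - 1e-16))
    else:
        raise StatsError(f"unknown method {method!r}")
    z_s = float(z_i.sum() / np.sqrt(p.size))
    return CombinedZResult(
        z_i=tuple(float(z) for z in z_i),
        z_s=z_s,
        z_crit=z_crit,
        significant=abs(z_s) > z_crit,
        k=int(p.size),
        method=method,
    )


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test; returns (t, two-sided p).

    Requires equal lengths >= 2 and a nonzero variance of the differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StatsError("paired samples must have equal length")
    if a.size < 2:
        raise StatsError("need at least 2 pairs")
    if np.std(a - b, ddof=1) == 0:
        raise StatsError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def paired_t_one_tailed(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired t-test of H1: mean(a) > mean(b); returns (t, one-tailed p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise StatsError("paired samples must have equal length >= 2")
    if np.std(a - b, ddof=1) == 0:
        raise StatsError("zero variance of paired differences")
    res = stats.ttest_rel(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def unpaired_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance by default); (t, two-sided p).

    Set ``welch=True`` for the unequal-variance variant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each sample needs at least 2 observations")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise StatsError("both samples are constant; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """OLS straight-line fit; returns (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise StatsError("x and y must have equal length >= 2")
    if np.all(x == x[0]):
        raise StatsError("x must contain at least 2 distinct values")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
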