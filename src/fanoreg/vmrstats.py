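"""Sample VMR estimation and the Gamma-null dispersion test.

For a gene without autoregulation the stationary law is Poisson and the
sample VMR (unbiased sample variance divided by sample mean) of ``n`` cells
asymptotically follows ``Gamma(shape=(n-1)/2, scale=2/(n-1))``, whose mean
is exactly 1.  Interval exclusion under this null flags a VMR as
significantly above or below 1.

Also provided: the exact VMR of a mixture of populations given per-component
(weight, mean, VMR), and the decomposition of a pooled VMR into intrinsic
(within-group) and extrinsic (between-group) components by the law of total
variance.  The decomposition uses population moments (divide by ``n``),
which is the convention under which the two components add up exactly; the
test path keeps the unbiased (``n - 1``) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VMRFlag",
    "VMRResult",
    "InsufficientDataError",
    "sample_vmr",
    "vmr_null_interval",
    "vmr_test",
    "mixture_vmr",
    "decompose_vmr",
]

SMALL_SAMPLE_N = 30


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested statistic."""


class VMRFlag(str, Enum):
    BELOW = "significantly_below_1"
    ABOVE = "significantly_above_1"
    NOT_SIGNIFICANT = "not_significant"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class VMRResult:
    """Sample VMR with its Gamma-null interval and significance flag."""

    n: int
    mean: float
    var: float
    vmr: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    flag: VMRFlag = VMRFlag.NOT_SIGNIFICANT


def _validate_samples(samples: Sequence[float]) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 observations, got {x.size}")
    if np.any(x < 0):
        raise ValueError("expression counts must be nonnegative")
    return x


def sample_vmr(samples: Sequence[float]) -> VMRResult:
    """Point estimate: mean, unbiased variance (n-1 denominator) and their ratio.

    A zero mean leaves the VMR undefined (flagged, not raised).
    """
    x = _validate_samples(samples)
    n = int(x.size)
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    if mean == 0.0:
        return VMRResult(n=n, mean=mean, var=var, vmr=float("nan"), flag=VMRFlag.UNDEFINED)
    return VMRResult(n=n, mean=mean, var=var, vmr=var / mean)


def _null(n: int) -> stats.rv_continuous:
    return stats.gamma(a=(n - 1) / 2.0, scale=2.0 / (n - 1))


def vmr_null_interval(n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Equal-tailed null interval for the sample VMR of ``n`` Poisson draws.

    Quantiles ``alpha/2`` and ``1 - alpha/2`` of
    ``Gamma((n-1)/2, 2/(n-1))``; the null mean is exactly 1 so the interval
    always brackets 1.
    """
    if n < 2:
        raise InsufficientDataError(f"need n >= 2, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n < SMALL_SAMPLE_N:
        warnings.warn(
            f"Gamma null is asymptotic; n = {n} < {SMALL_SAMPLE_N} may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    null = _null(n)
    return float(null.ppf(alpha / 2.0)), float(null.ppf(1.0 - alpha / 2.0))


def vmr_test(
    samples: Sequence[float],
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> VMRResult:
    """Test whether the sample VMR differs significantly from 1.

    ``alternative`` is ``"two-sided"`` (default), ``"less"`` (VMR < 1 only)
    or ``"greater"``.  The flag records interval exclusion; values exactly on
    a boundary are not significant.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    res = sample_vmr(samples)
    if res.flag is VMRFlag.UNDEFINED:
        return res
    null = _null(res.n)
    if alternative == "two-sided":
        lo, hi = vmr_null_interval(res.n, alpha)
        p = 2.0 * min(null.cdf(res.vmr), null.sf(res.vmr))
    elif alternative == "less":
        lo, hi = float(null.ppf(alpha)), float("inf")
        p = float(null.cdf(res.vmr))
    else:
        lo, hi = 0.0, float(null.ppf(1.0 - alpha))
        p = float(null.sf(res.vmr))
    p = min(p, 1.0)
    if res.vmr < lo:
        flag = VMRFlag.BELOW
    elif res.vmr > hi:
        flag = VMRFlag.ABOVE
    else:
        flag = VMRFlag.NOT_SIGNIFICANT
    return replace(res, ci_low=lo, ci_high=hi, p_value=p, flag=flag)


def mixture_vmr(components: Iterable[tuple[float, float, float]]) -> float:
    """Exact VMR of a mixture given per-component ``(weight, mean, vmr)``.

    Component variances are recovered as ``vmr * mean``; the mixture VMR is
    assembled from the exact first and second mixture moments.
    """
    comps = list(components)
    if not comps:
        raise ValueError("need at least one component")
    w = np.array([c[0] for c in comps], dtype=float)
    mu = np.array([c[1] for c in comps], dtype=float)
    vmr = np.array([c[2] for c in comps], dtype=float)
    if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be positive and sum to 1")
    if np.any(mu < 0) or np.any(vmr < 0):
        raise ValueError("means and VMRs must be nonnegative")
    e1 = float(w @ mu)
    if e1 <= 0:
        raise ValueError("mixture mean must be positive")
    e2 = float(w @ (vmr * mu + mu**2))
    return (e2 - e1**2) / e1


def decompose_vmr(grouped_samples: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Split the pooled VMR into intrinsic and extrinsic components.

    Groups play the role of the extrinsic (environmental) factor: the
    intrinsic part is the weighted within-group variance over the pooled
    mean, the extrinsic part the variance of group means over the pooled
    mean.  Population moments throughout, so the two add up exactly to the
    pooled population VMR.
    """
    if not grouped_samples:
        raise ValueError("need at least one group")
    arrays = {k: np.asarray(v, dtype=float) for k, v in grouped_samples.items()}
    for k, x in arrays.items():
        if x.size == 0:
            raise ValueError(f"group {k!r} is empty")
    n_total = sum(x.size for x in arrays.values())
    w = np.array([x.size / n_total for x in arrays.values()])
    means = np.array([x.mean() for x in arrays.values()])
    vars_pop = np.array([x.var(ddof=0) for x in arrays.values()])
    pooled_mean = float(w @ means)
    if pooled_mean <= 0:
        raise ValueError("pooled mean must be positive")
    vmr_int = float(w @ vars_pop) / pooled_mean
    vmr_ext = float(w @ (means - pooled_mean) ** 2) / pooled_mean
    return vmr_int, vmr_ext
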