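"""Multiple-synthesis combining rule for inference across m sanitized releases.

When m independent sanitized versions of a dataset are released, an
analysis run separately on each yields estimates b^(1)..b^(m) with
within-set variances w^(1)..w^(m).  Valid inference pools them as

    b_bar = mean of the b^(l)
    B     = sample variance of the b^(l)   (between-set variability)
    W     = mean of the w^(l)              (within-set variability)
    T     = B/m + W                        (total variance)

with reference distribution  (beta - b_bar)/sqrt(T) ~ t_nu,
nu = (m-1)(1 + mW/B)^2.  The sanitization noise enters through B,
the ordinary sampling variability through W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SynthesisEstimates", "CombinedInference", "ms_combine"]


@dataclass(frozen=True)
class SynthesisEstimates:
    """Per-release point estimates and their estimated variances."""

    estimates: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        est = np.atleast_1d(np.asarray(self.estimates, dtype=float))
        var = np.atleast_1d(np.asarray(self.variances, dtype=float))
        if est.shape != var.shape or est.ndim != 1:
            raise ValueError("estimates and variances must be equal-length vectors")
        if est.size < 2:
            raise ValueError("need at least m = 2 releases to combine")
        if not np.all(np.isfinite(est)) or not np.all(np.isfinite(var)):
            raise ValueError("estimates and variances must be finite")
        if np.any(var < 0) or var.sum() == 0:
            raise ValueError("variances must be nonnegative with a positive sum")
        object.__setattr__(self, "estimates", est)
        object.__setattr__(self, "variances", var)

    @property
    def m(self) -> int:
        return self.estimates.size


@dataclass(frozen=True)
class CombinedInference:
    """Pooled point estimate, variance components, and t-based CI."""

    point: float
    between: float
    within: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    level: float
    p_value: float
    m: int


def ms_combine(
    data,
    variances=None,
    level: float = 0.95,
    null_value: float = 0.0,
    alternative: str = "two-sided",
) -> CombinedInference:
    """Combine m >= 2 per-release estimates into a single inference.

    Parameters
    ----------
    data : SynthesisEstimates or array-like
        Either a :class:`SynthesisEstimates`, or the vector of point
        estimates (then ``variances`` must be supplied).
    level : float
        Confidence level for the interval, in (0, 1).
    null_value : float
        Value tested by the reported p-value.
    alternative : {"two-sided", "greater", "less"}

    Notes
    -----
    When all estimates coincide (B = 0) the degrees of freedom are set
    to +inf, i.e. the normal reference — the limit of the nu formula —
    rather than failing on a division by zero.
    """
    if not isinstance(data, SynthesisEstimates):
        data = SynthesisEstimates(np.asarray(data), np.asarray(variances))
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")

    m = data.m
    est = data.estimates
    point = float(est.mean())
    between = float(est.var(ddof=1))
    within = float(data.variances.mean())
    total = between / m + within
    if total <= 0:
        raise ValueError("total variance is zero: nothing to infer from")

    if between > 0:
        df = (m - 1) * (1.0 + m * within / between) ** 2
    else:
        df = np.inf

    se = float(np.sqrt(total))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df))
    z = (point - null_value) / se
    if alternative == "two-sided":
        p = 2.0 * float(stats.t.sf(abs(z), df))
    elif alternative == "greater":
        p = float(stats.t.sf(z, df))
    else:
        p = float(stats.t.cdf(z, df))

    return CombinedInference(
        point=point,
        between=between,
        within=within,
        total_var=total,
        df=float(df),
        ci_low=point - tcrit * se,
        ci_high=point + tcrit * se,
        level=level,
        p_value=p,
        m=m,
    )
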