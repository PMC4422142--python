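"""Distributional estimates of tail proportions and their comparison.

The distributional method estimates the proportion of a population
beyond a clinical cut-point from the fitted distribution's parameters
(mean, SD and optionally a skew-normal shape) instead of counting
observations.  Because the estimate is a smooth function of the sample
mean, the delta method gives it a standard error that inherits the
precision of the comparison of means:

    var(p_hat) = (sigma^2 / n) * p'(mu)^2

where ``p'`` is the derivative of the tail probability with respect to
the mean.  Two groups sharing a pooled SD (and, for the skew-normal
method, a pooled shape alpha) are compared through the difference in
proportions d, the risk ratio rr and the odds ratio or, with

    se(d)^2       = var(p1) + var(p2)
    se(log rr)^2  = var(p1)/p1^2 + var(p2)/p2^2
    se(log or)^2  = var(p1)/(p1(1-p1))^2 + var(p2)/(p2(1-p2))^2

Confidence intervals built from these SEs are called distributional
confidence intervals (DCIs); ratio intervals are symmetric on the log
scale and exponentiated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

from scipy import stats

from . import skewnormal as sn
from .exceptions import ConfigError, DegenerateTailError, DomainError
from .skewnormal import SkewNormalParams, Threshold

__all__ = [
    "GroupSummary",
    "PooledModel",
    "ProportionEstimate",
    "ComparisonEstimate",
    "pooled_sd",
    "dci",
    "distributional_proportion",
    "compare_groups",
]

# Beyond this the cut-point sits ~10 SD into a tail and the delta-method
# SE degenerates; refuse to dichotomise there.
_P_FLOOR = 1e-16


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics for one group on the analysis scale."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise DomainError(f"group {self.label!r}: n must be an integer >= 2, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        if not (math.isfinite(self.mean) and math.isfinite(self.sd)):
            raise DomainError(f"group {self.label!r}: mean/sd must be finite")
        if self.sd <= 0:
            raise DomainError(f"group {self.label!r}: sd must be > 0, got {self.sd}")


@dataclass(frozen=True)
class PooledModel:
    """Two groups under equal variance and (for the skew method) equal shape.

    ``groups[0]`` is the exposed group (minuend / numerator),
    ``groups[1]`` the reference.  Both share ``sd_pooled`` and ``alpha``;
    with ``alpha = 0`` this is the normal distributional method.
    """

    groups: tuple[GroupSummary, GroupSummary]
    sd_pooled: float
    alpha: float = 0.0
    method: str = "normal"

    def __post_init__(self) -> None:
        if len(self.groups) != 2:
            raise ConfigError("exactly two groups are required")
        if self.groups[0].label == self.groups[1].label:
            raise ConfigError(f"group labels must differ, both are {self.groups[0].label!r}")
        if not (math.isfinite(self.sd_pooled) and self.sd_pooled > 0):
            raise DomainError(f"sd_pooled must be > 0, got {self.sd_pooled}")
        if self.method not in ("normal", "skew_normal"):
            raise ConfigError(f"method must be 'normal' or 'skew_normal', got {self.method!r}")
        if self.method == "normal" and self.alpha != 0.0:
            raise ConfigError("the normal method requires alpha = 0")

    @property
    def exposed(self) -> GroupSummary:
        return self.groups[0]

    @property
    def reference(self) -> GroupSummary:
        return self.groups[1]

    def params_for(self, group: GroupSummary) -> SkewNormalParams:
        """Skew-normal parameters implied for one group (pooled sd/alpha)."""
        return SkewNormalParams(mu=group.mean, sigma=self.sd_pooled, alpha=self.alpha)

    def swapped(self) -> "PooledModel":
        return PooledModel(
            groups=(self.groups[1], self.groups[0]),
            sd_pooled=self.sd_pooled,
            alpha=self.alpha,
            method=self.method,
        )


@dataclass(frozen=True)
class ProportionEstimate:
    """Distributional tail-proportion estimate for one group."""

    p: float
    se: float
    group: str

    @property
    def var(self) -> float:
        return self.se**2


@dataclass(frozen=True)
class ComparisonEstimate:
    """Distributional comparison of two groups' tail proportions.

    ``d = p_exposed - p_reference``; ``rr`` and ``or_`` likewise take the
    exposed group as numerator.  ``se_log_rr``/``se_log_or`` are on the
    log scale; ``ci_rr``/``ci_or`` are exponentiated log-scale intervals.
    """

    d: float
    se_d: float
    rr: float
    se_log_rr: float
    or_: float
    se_log_or: float
    ci_d: tuple[float, float]
    ci_rr: tuple[float, float]
    ci_or: tuple[float, float]
    p_exposed: ProportionEstimate
    p_reference: ProportionEstimate
    level: float = 0.95
    direction: str = ""
    threshold: Threshold | None = field(default=None, compare=False)

    def to_dict(self) -> dict[str, Any]:
        """Flat, JSON-serialisable record with a deterministic field order."""
        out: dict[str, Any] = {
            "direction": self.direction,
            "level": self.level,
            "p_exposed": self.p_exposed.p,
            "se_p_exposed": self.p_exposed.se,
            "p_reference": self.p_reference.p,
            "se_p_reference": self.p_reference.se,
            "d": self.d,
            "se_d": self.se_d,
            "ci_d": list(self.ci_d),
            "rr": self.rr,
            "se_log_rr": self.se_log_rr,
            "ci_rr": list(self.ci_rr),
            "or": self.or_,
            "se_log_or": self.se_log_or,
            "ci_or": list(self.ci_or),
        }
        if self.threshold is not None:
            out["cutpoint"] = self.threshold.x0
            out["tail"] = self.threshold.tail
        return out


def pooled_sd(g1: GroupSummary, g2: GroupSummary) -> float:
    """Degrees-of-freedom-weighted pooled SD under equal variance.

    sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2)).
    """
    if g1.n + g2.n <= 2:
        raise DomainError("pooled SD needs n1 + n2 > 2")
    num = (g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2
    return math.sqrt(num / (g1.n + g2.n - 2))


def dci(point: float, se: float, level: float = 0.95, scale: str = "identity") -> tuple[float, float]:
    """Distributional confidence interval: symmetric normal-quantile interval.

    On ``scale="log"`` the interval is built around log(point) and
    exponentiated (for risk and odds ratios).
    """
    if not 0.0 < level < 1.0:
        raise ConfigError(f"confidence level must be in (0, 1), got {level}")
    if se <= 0 or not math.isfinite(se):
        raise DomainError(f"se must be a positive finite number, got {se}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    if scale == "identity":
        return (point - z * se, point + z * se)
    if scale == "log":
        if point <= 0:
            raise DomainError("log-scale interval needs a positive point estimate")
        lo, hi = math.log(point) - z * se, math.log(point) + z * se
        return (math.exp(lo), math.exp(hi))
    raise ConfigError(f"scale must be 'identity' or 'log', got {scale!r}")


def distributional_proportion(
    model: PooledModel, group: GroupSummary, threshold: Threshold
) -> ProportionEstimate:
    """Distributional estimate of one group's tail proportion with its SE.

    The proportion is the fitted skew-normal (or normal, alpha = 0) tail
    probability at the cut-point; the SE comes from the delta method,
    var = (sigma^2/n) * p'(mu)^2, using the pooled SD.
    """
    params = model.params_for(group)
    p_below = sn.cdf(threshold.x0, params)
    p = p_below if threshold.tail == "below" else 1.0 - p_below
    if p < _P_FLOOR or p > 1.0 - _P_FLOOR:
        raise DegenerateTailError(
            f"group {group.label!r}: tail proportion at cut-point {threshold.x0} is "
            f"numerically {'0' if p < 0.5 else '1'} ({p:.3e}); the cut-point is too far "
            "into the tail for a meaningful dichotomisation"
        )
    # |p'| is the same for either tail, so the SE does not depend on direction.
    p_prime = sn.dcdf_dmean(threshold.x0, params)
    var = (model.sd_pooled**2 / group.n) * p_prime**2
    return ProportionEstimate(p=float(p), se=math.sqrt(var), group=group.label)


def compare_groups(
    model: PooledModel, threshold: Threshold, level: float = 0.95
) -> ComparisonEstimate:
    """Distributional comparison (d, rr, or) of the two groups' tail proportions.

    The exposed group (``model.groups[0]``) is the minuend of ``d`` and the
    numerator of ``rr``/``or``.  All SEs are delta-method SEs; ratio DCIs
    are symmetric on the log scale.
    """
    exp_est = distributional_proportion(model, model.exposed, threshold)
    ref_est = distributional_proportion(model, model.reference, threshold)
    p1, p2 = exp_est.p, ref_est.p
    v1, v2 = exp_est.var, ref_est.var

    d = p1 - p2
    se_d = math.sqrt(v1 + v2)
    rr = p1 / p2
    se_log_rr = math.sqrt(v1 / p1**2 + v2 / p2**2)
    or_ = (p1 / (1.0 - p1)) / (p2 / (1.0 - p2))
    se_log_or = math.sqrt(v1 / (p1 * (1.0 - p1)) ** 2 + v2 / (p2 * (1.0 - p2)) ** 2)

    return ComparisonEstimate(
        d=d,
        se_d=se_d,
        rr=rr,
        se_log_rr=se_log_rr,
        or_=or_,
        se_log_or=se_log_or,
        ci_d=dci(d, se_d, level, "identity"),
        ci_rr=dci(rr, se_log_rr, level, "log"),
        ci_or=dci(or_, se_log_or, level, "log"),
        p_exposed=exp_est,
        p_reference=ref_est,
        level=level,
        direction=f"{model.exposed.label} - {model.reference.label}",
        threshold=threshold,
    )
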