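"""Monotone transformations with automatic threshold and tail mapping.

Proportions defined by a threshold are invariant under a continuous
strictly monotone transformation of the outcome: if f is increasing,
``y < Y  iff  f(y) < f(Y)``; if g is decreasing, ``y < Y  iff
g(y) > g(Y)``.  So a lower-tail proportion on the original scale stays
a lower-tail proportion under an increasing transform (log, sqrt,
square on positive values) but becomes an upper-tail proportion under
a decreasing one (inverse 1/x on positive values, negation, or the
reflect-and-log transform log(c - x) used for left-skewed outcomes
such as gestational age).

Empirical counts use the strict convention: "below" counts x < x0 and
"above" counts x > x0.  For the continuous fitted distributions
P(X < x0) = P(X <= x0), so the distributional estimates are unaffected
by the boundary convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import DomainError
from .skewnormal import Threshold

__all__ = ["TransformSpec", "apply", "map_threshold", "invert_threshold",
           "preserve_proportion_check", "TRANSFORM_NAMES"]


@dataclass(frozen=True)
class _Entry:
    func: Callable[[np.ndarray, float | None], np.ndarray]
    inverse: Callable[[np.ndarray, float | None], np.ndarray]
    direction: str  # "increasing" | "decreasing"
    domain: Callable[[np.ndarray, float | None], np.ndarray]  # mask of valid values
    domain_text: str
    needs_c: bool = False


_REGISTRY: dict[str, _Entry] = {
    "identity": _Entry(lambda x, c: x, lambda y, c: y, "increasing",
                       lambda x, c: np.isfinite(x), "finite"),
    "log": _Entry(lambda x, c: np.log(x), lambda y, c: np.exp(y), "increasing",
                  lambda x, c: np.isfinite(x) & (x > 0), "> 0"),
    "sqrt": _Entry(lambda x, c: np.sqrt(x), lambda y, c: np.square(y), "increasing",
                   lambda x, c: np.isfinite(x) & (x > 0), "> 0"),
    "square": _Entry(lambda x, c: np.square(x), lambda y, c: np.sqrt(y), "increasing",
                     lambda x, c: np.isfinite(x) & (x > 0), "> 0"),
    "inverse": _Entry(lambda x, c: 1.0 / x, lambda y, c: 1.0 / y, "decreasing",
                      lambda x, c: np.isfinite(x) & (x > 0), "> 0"),
    "negate": _Entry(lambda x, c: -x, lambda y, c: -y, "decreasing",
                     lambda x, c: np.isfinite(x), "finite"),
    "reflect_log": _Entry(lambda x, c: np.log(c - x), lambda y, c: c - np.exp(y),
                          "decreasing",
                          lambda x, c: np.isfinite(x) & (x < c), "< c",
                          needs_c=True),
}

TRANSFORM_NAMES = tuple(_REGISTRY)


@dataclass(frozen=True)
class TransformSpec:
    """A named monotone transform; ``c`` is the reflection point for
    ``reflect_log`` (e.g. 45 weeks for gestational age)."""

    name: str = "identity"
    c: float | None = None

    def __post_init__(self) -> None:
        if self.name not in _REGISTRY:
            raise DomainError(
                f"unknown transform {self.name!r}; choose from {TRANSFORM_NAMES}"
            )
        entry = _REGISTRY[self.name]
        if entry.needs_c:
            if self.c is None or not math.isfinite(self.c):
                raise DomainError(f"transform {self.name!r} requires a finite constant c")
        elif self.c is not None:
            raise DomainError(f"transform {self.name!r} takes no constant c")

    @property
    def direction(self) -> str:
        return _REGISTRY[self.name].direction

    @property
    def is_decreasing(self) -> bool:
        return self.direction == "decreasing"


def _check_domain(values: np.ndarray, spec: TransformSpec) -> None:
    entry = _REGISTRY[spec.name]
    ok = entry.domain(values, spec.c)
    if not np.all(ok):
        bad = np.asarray(values)[~ok]
        shown = ", ".join(f"{v:g}" for v in bad[:5])
        more = f" (and {bad.size - 5} more)" if bad.size > 5 else ""
        raise DomainError(
            f"transform {spec.name!r} requires values {entry.domain_text}; "
            f"offending value(s): {shown}{more}"
        )


def apply(values, spec: TransformSpec):
    """Apply the transform elementwise after checking its domain."""
    arr = np.asarray(values, dtype=float)
    _check_domain(arr, spec)
    out = _REGISTRY[spec.name].func(arr, spec.c)
    return out if out.ndim else float(out)


def map_threshold(threshold: Threshold, spec: TransformSpec) -> Threshold:
    """Map a cut-point to the transformed scale.

    The new cut-point is the transformed old one; the tail direction is
    preserved by increasing transforms and flipped by decreasing ones.
    """
    x0t = apply(threshold.x0, spec)
    if spec.is_decreasing:
        return Threshold(x0t, "above" if threshold.tail == "below" else "below")
    return Threshold(x0t, threshold.tail)


def invert_threshold(threshold: Threshold, spec: TransformSpec) -> Threshold:
    """Map a cut-point on the transformed scale back to the original one."""
    entry = _REGISTRY[spec.name]
    x0 = float(entry.inverse(np.asarray(threshold.x0, dtype=float), spec.c))
    if spec.is_decreasing:
        return Threshold(x0, "above" if threshold.tail == "below" else "below")
    return Threshold(x0, threshold.tail)


def _count_beyond(values: np.ndarray, threshold: Threshold) -> int:
    if threshold.tail == "below":
        return int(np.sum(values < threshold.x0))
    return int(np.sum(values > threshold.x0))


def preserve_proportion_check(values, threshold: Threshold, spec: TransformSpec) -> dict:
    """Verify that the empirical proportion beyond the threshold is unchanged.

    Counts observations beyond the original threshold and beyond the
    mapped threshold on the transformed data; strict monotonicity makes
    the two counts equal.  A mismatch signals a transform/tail bug and
    raises.
    """
    arr = np.asarray(values, dtype=float)
    _check_domain(arr, spec)
    mapped = map_threshold(threshold, spec)
    n_orig = _count_beyond(arr, threshold)
    n_trans = _count_beyond(np.asarray(apply(arr, spec)), mapped)
    report = {
        "n": int(arr.size),
        "count_original": n_orig,
        "count_transformed": n_trans,
        "threshold_original": {"x0": threshold.x0, "tail": threshold.tail},
        "threshold_transformed": {"x0": mapped.x0, "tail": mapped.tail},
        "preserved": n_orig == n_trans,
    }
    if n_orig != n_trans:
        raise DomainError(
            f"proportion not preserved under {spec.name!r}: {n_orig} vs {n_trans} "
            f"of {arr.size} beyond the threshold"
        )
    return report
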