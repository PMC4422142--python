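"""Model/Results front end for the distributional dichotomisation method.

``DistributionalDichotomy`` is built from data — either per-group
summary statistics (n, mean, SD) or raw samples — together with a
clinical cut-point; ``fit()`` returns a ``DichotomyResults`` carrying
the tail-proportion estimates, their comparison (difference, risk
ratio, odds ratio) with delta-method standard errors and
distributional confidence intervals, and a ``summary()`` table.

Example
-------
>>> from distprop import DistributionalDichotomy, GroupSummary, Threshold
>>> model = DistributionalDichotomy.from_summaries(
...     exposed=GroupSummary("smoker", 494, 3267.0, 441.0),
...     reference=GroupSummary("non-smoker", 983, 3452.0, 435.0),
...     threshold=Threshold(2500.0, "below"))
>>> res = model.fit()
>>> round(res.d, 3), round(res.se_d, 3)
(0.025, 0.004)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from . import estimators, fitting, transforms
from .estimators import ComparisonEstimate, GroupSummary, PooledModel
from .exceptions import ConfigError
from .fitting import FitResult
from .skewnormal import Threshold
from .transforms import TransformSpec

__all__ = ["DistributionalDichotomy", "DichotomyResults"]


class DistributionalDichotomy:
    """Two-group distributional dichotomisation model.

    Construct with :meth:`from_summaries`, :meth:`from_samples` or
    :meth:`from_dataframe`; the threshold is given on the *original*
    outcome scale and, when a transform is supplied, mapped to the
    analysis scale automatically (decreasing transforms flip the tail).
    """

    def __init__(
        self,
        *,
        exposed: GroupSummary | None = None,
        reference: GroupSummary | None = None,
        exposed_values: np.ndarray | None = None,
        reference_values: np.ndarray | None = None,
        labels: tuple[str, str] = ("exposed", "reference"),
        threshold: Threshold,
        method: str = "normal",
        shape: float = 0.0,
        transform: TransformSpec | None = None,
    ) -> None:
        self.threshold_original = threshold
        self.transform = transform or TransformSpec("identity")
        self.threshold = transforms.map_threshold(threshold, self.transform)
        self.method = method
        self.shape = float(shape)
        self.labels = labels
        self._summaries = None
        self._raw = None
        if exposed is not None and reference is not None:
            self._summaries = (exposed, reference)
            self.labels = (exposed.label, reference.label)
        elif exposed_values is not None and reference_values is not None:
            self._raw = (
                transforms.apply(np.asarray(exposed_values, float), self.transform),
                transforms.apply(np.asarray(reference_values, float), self.transform),
            )
        else:
            raise ConfigError("provide either two GroupSummary objects or two raw samples")

    # ------------------------------------------------------------------ #
    @classmethod
    def from_summaries(
        cls,
        exposed: GroupSummary,
        reference: GroupSummary,
        threshold: Threshold,
        shape: float = 0.0,
        transform: TransformSpec | None = None,
    ) -> "DistributionalDichotomy":
        """Build from per-group (n, mean, SD) on the *analysis* scale.

        ``shape`` is an optional shared skew-normal alpha (0 = normal
        method).  When a transform is given it is used only to map the
        threshold: the summaries are assumed to already be on the
        transformed scale (as printed in published tables).
        """
        method = "normal" if shape == 0.0 else "skew_normal"
        return cls(exposed=exposed, reference=reference, threshold=threshold,
                   method=method, shape=shape, transform=transform)

    @classmethod
    def from_samples(
        cls,
        exposed_values,
        reference_values,
        threshold: Threshold,
        labels: tuple[str, str] = ("exposed", "reference"),
        method: str = "auto",
        transform: TransformSpec | None = None,
    ) -> "DistributionalDichotomy":
        """Build from raw per-subject values (original scale)."""
        return cls(exposed_values=exposed_values, reference_values=reference_values,
                   labels=labels, threshold=threshold, method=method,
                   transform=transform)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        value: str,
        group: str,
        threshold: Threshold,
        exposed: str | None = None,
        method: str = "auto",
        transform: TransformSpec | None = None,
    ) -> "DistributionalDichotomy":
        """Build from a tidy DataFrame with a value column and a two-level
        group column; ``exposed`` names the exposed group (default: first
        label in sorted order)."""
        if value not in data.columns or group not in data.columns:
            raise ConfigError(f"columns {value!r} and {group!r} must be present")
        sub = data[[group, value]].dropna()
        labels = sorted(map(str, sub[group].astype(str).unique()))
        if len(labels) != 2:
            raise ConfigError(f"exactly two groups required, found {labels}")
        if exposed is None:
            exposed = labels[0]
        elif exposed not in labels:
            raise ConfigError(f"exposed group {exposed!r} not among {labels}")
        ref = labels[0] if labels[1] == exposed else labels[1]
        vals = pd.to_numeric(sub[value], errors="raise").to_numpy(float)
        grp = sub[group].astype(str).to_numpy()
        return cls.from_samples(vals[grp == exposed], vals[grp == ref], threshold,
                                labels=(exposed, ref), method=method,
                                transform=transform)

    # ------------------------------------------------------------------ #
    def fit(self, level: float = 0.95) -> "DichotomyResults":
        """Estimate proportions and their comparison; returns results."""
        fit_result: FitResult | None = None
        rationale = ""
        if self._summaries is not None:
            g1, g2 = self._summaries
            if self.method == "auto":
                raise ConfigError("method='auto' needs raw data to estimate the shape")
            alpha = self.shape if self.method == "skew_normal" else 0.0
            pooled = PooledModel(
                groups=(g1, g2),
                sd_pooled=estimators.pooled_sd(g1, g2),
                alpha=alpha,
                method=self.method,
            )
            rationale = f"summary mode, {self.method} method"
        else:
            x1, x2 = self._raw
            pooled, fit_result, rationale = fitting.build_pooled_model(
                x1, x2, method=self.method, labels=self.labels
            )
        comparison = estimators.compare_groups(pooled, self.threshold, level=level)
        return DichotomyResults(model=self, pooled=pooled, comparison=comparison,
                                fit_result=fit_result, method_rationale=rationale)


@dataclass
class DichotomyResults:
    """Fitted distributional dichotomisation results."""

    model: DistributionalDichotomy
    pooled: PooledModel
    comparison: ComparisonEstimate
    fit_result: FitResult | None = None
    method_rationale: str = ""

    # convenience accessors ------------------------------------------------
    @property
    def p_exposed(self) -> float:
        return self.comparison.p_exposed.p

    @property
    def p_reference(self) -> float:
        return self.comparison.p_reference.p

    @property
    def d(self) -> float:
        return self.comparison.d

    @property
    def se_d(self) -> float:
        return self.comparison.se_d

    @property
    def rr(self) -> float:
        return self.comparison.rr

    @property
    def or_(self) -> float:
        return self.comparison.or_

    @property
    def se_log_rr(self) -> float:
        return self.comparison.se_log_rr

    @property
    def se_log_or(self) -> float:
        return self.comparison.se_log_or

    def conf_int(self) -> pd.DataFrame:
        c = self.comparison
        return pd.DataFrame(
            {"estimate": [c.d, c.rr, c.or_],
             "lower": [c.ci_d[0], c.ci_rr[0], c.ci_or[0]],
             "upper": [c.ci_d[1], c.ci_rr[1], c.ci_or[1]]},
            index=["d", "rr", "or"],
        )

    def to_dict(self) -> dict[str, Any]:
        out = {
            "method": self.pooled.method,
            "alpha": self.pooled.alpha,
            "sd_pooled": self.pooled.sd_pooled,
            "transform": self.model.transform.name,
            "threshold_original": {"x0": self.model.threshold_original.x0,
                                   "tail": self.model.threshold_original.tail},
            "threshold_analysis": {"x0": self.model.threshold.x0,
                                   "tail": self.model.threshold.tail},
            "groups": [
                {"label": g.label, "n": g.n, "mean": g.mean, "sd": g.sd}
                for g in self.pooled.groups
            ],
        }
        out.update(self.comparison.to_dict())
        out["method_rationale"] = self.method_rationale
        return out

    def summary(self) -> str:
        """Human-readable results table."""
        c = self.comparison
        g1, g2 = self.pooled.groups
        lvl = f"{100 * c.level:g}%"
        lines = [
            "Distributional dichotomisation results",
            "=" * 62,
            f"Method:          {self.pooled.method} (alpha = {self.pooled.alpha:.4g})",
            f"Transform:       {self.model.transform.name}",
            f"Cut-point:       {self.model.threshold.x0:g} "
            f"(tail: {self.model.threshold.tail}, analysis scale)",
            f"Pooled SD:       {self.pooled.sd_pooled:.6g}",
            "-" * 62,
            f"{'group':<16}{'n':>6}{'mean':>12}{'proportion':>14}{'SE':>12}",
            f"{g1.label:<16}{g1.n:>6}{g1.mean:>12.5g}{c.p_exposed.p:>14.4f}"
            f"{c.p_exposed.se:>12.4f}",
            f"{g2.label:<16}{g2.n:>6}{g2.mean:>12.5g}{c.p_reference.p:>14.4f}"
            f"{c.p_reference.se:>12.4f}",
            "-" * 62,
            f"{'estimand':<14}{'estimate':>10}{'SE':>10}{lvl + ' DCI':>24}",
            f"{'diff (d)':<14}{c.d:>10.4f}{c.se_d:>10.4f}"
            f"{'[%.4f, %.4f]' % c.ci_d:>24}",
            f"{'risk ratio':<14}{c.rr:>10.3f}{c.se_log_rr:>10.4f}"
            f"{'[%.3f, %.3f]' % c.ci_rr:>24}",
            f"{'odds ratio':<14}{c.or_:>10.3f}{c.se_log_or:>10.4f}"
            f"{'[%.3f, %.3f]' % c.ci_or:>24}",
            "-" * 62,
            f"Direction: {c.direction}   (ratio SEs on the log scale)",
        ]
        if self.method_rationale:
            lines.append(f"Note: {self.method_rationale}")
        return "\n".join(lines)
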