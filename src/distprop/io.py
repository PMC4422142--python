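"""Reading raw and summary inputs.

Raw data arrive as tidy two-column tables (group label, outcome
value); summary inputs are per-group (label, n, mean, sd) records —
every published worked example is expressible in summary form.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import GroupSummary
from .exceptions import ConfigError, DomainError

__all__ = ["read_raw", "read_summary", "parse_summary_token"]

log = logging.getLogger("distprop")


def read_raw(path, group_col: str = "group", value_col: str = "value"
             ) -> dict[str, np.ndarray]:
    """Read a tidy CSV into exactly two labelled samples.

    Rows with missing values are dropped (and counted in the log);
    non-numeric values or a group count other than two are errors.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    df = pd.read_csv(path)
    for col in (group_col, value_col):
        if col not in df.columns:
            raise ConfigError(f"column {col!r} not found in {path} "
                              f"(columns: {list(df.columns)})")
    values = pd.to_numeric(df[value_col], errors="coerce")
    missing = int(values.isna().sum() + df[group_col].isna().sum())
    keep = values.notna() & df[group_col].notna()
    if missing:
        log.warning("%d row(s) with missing values dropped from %s", missing, path)
    bad = df.loc[df[value_col].notna() & values.isna(), value_col]
    if len(bad):
        raise ConfigError(f"non-numeric value(s) in column {value_col!r}: "
                          f"{list(bad.head(5))}")
    labels = sorted(df.loc[keep, group_col].astype(str).unique())
    if len(labels) != 2:
        raise ConfigError(f"exactly two groups required, found {len(labels)}: {labels}")
    out = {}
    for lab in labels:
        sample = values[keep & (df[group_col].astype(str) == lab)].to_numpy(float)
        if sample.size == 0:
            raise ConfigError(f"group {lab!r} is empty")
        out[lab] = sample
    return out


def parse_summary_token(token: str) -> GroupSummary:
    """Parse a ``label:n:mean:sd`` command-line token."""
    parts = token.split(":")
    if len(parts) != 4:
        raise ConfigError(f"summary must be 'label:n:mean:sd', got {token!r}")
    label, n_s, mean_s, sd_s = parts
    try:
        return GroupSummary(label=label, n=int(n_s), mean=float(mean_s), sd=float(sd_s))
    except (ValueError, DomainError) as exc:
        raise ConfigError(f"bad summary {token!r}: {exc}") from exc


def read_summary(records) -> tuple[GroupSummary, GroupSummary, float]:
    """Validate two per-group summary records (+ optional shared shape).

    ``records`` is an iterable of mappings with keys label/n/mean/sd and
    optionally a shared ``alpha``; alpha defaults to 0 (normal method).
    Returns ``(exposed, reference, alpha)`` in input order.
    """
    records = list(records)
    if len(records) != 2:
        raise ConfigError(f"exactly two summary records required, got {len(records)}")
    alphas = {float(r.get("alpha", 0.0)) for r in records}
    if len(alphas) > 1:
        raise ConfigError("the shared shape alpha must be identical for both groups")
    groups = []
    for r in records:
        try:
            groups.append(GroupSummary(label=str(r["label"]), n=int(r["n"]),
                                       mean=float(r["mean"]), sd=float(r["sd"])))
        except KeyError as exc:
            raise ConfigError(f"summary record missing field {exc}") from exc
    if groups[0].label == groups[1].label:
        raise ConfigError(f"group labels must differ, both are {groups[0].label!r}")
    return groups[0], groups[1], alphas.pop()
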