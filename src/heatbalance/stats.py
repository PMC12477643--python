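"""Cohort summarisation and group comparisons.

Per-condition cells are reported as mean with a Student-t 95% confidence
interval. Wettedness contrasts use an independent-samples t-test between
age groups (Welch by default, pooled on request) and a paired t-test
between metabolic rates within a group, with a Bonferroni-adjusted
significance threshold across the family of environments compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CohortSummary",
    "ComparisonResult",
    "mean_ci",
    "summarize",
    "compare_groups",
    "bonferroni_alpha",
    "format_summary_table",
]

log = logging.getLogger(__name__)

#: metrics summarised per cell, with their display rounding
SUMMARY_METRICS = {
    "t_db": 1,
    "rh": 1,
    "t_wb": 1,
    "p_a": 1,
    "sr": 0,
    "t_sk_bar": 1,
    "rc": 0,
    "e_req": 0,
    "e_max": 0,
    "omega_max": 2,
}


@dataclass(frozen=True)
class ComparisonResult:
    """One t-test contrast with its Bonferroni-adjusted threshold."""

    contrast: str
    t_stat: float
    p_value: float
    alpha: float
    significant: bool
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class CohortSummary:
    """Tidy per-cell summary: one row per (group, activity, condition, metric)."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def bonferroni_alpha(n_comparisons: int, family_alpha: float = 0.05) -> float:
    """Bonferroni-adjusted per-comparison significance threshold."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return family_alpha / n_comparisons


def mean_ci(x: Sequence[float], confidence: float = 0.95) -> tuple[float, float, float]:
    """Sample mean with a Student-t confidence interval.

    With all values identical (zero SD) the interval collapses to the point.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two observations for a confidence interval")
    m = float(np.mean(x))
    sem = float(np.std(x, ddof=1)) / np.sqrt(n)
    if sem == 0.0:
        return m, m, m
    half = sps.t.ppf(0.5 + confidence / 2.0, df=n - 1) * sem
    return m, m - half, m + half


def summarize(
    results: pd.DataFrame,
    group_cols: Sequence[str] = ("age_group", "activity", "condition"),
    metrics: Optional[Iterable[str]] = None,
) -> CohortSummary:
    """Per-cell means and 95% CIs across a table of per-trial results.

    ``results`` has one row per trial with the grouping columns and metric
    columns. Cells with fewer than two trials are omitted with a warning.
    """
    metrics = list(metrics) if metrics is not None else [
        m for m in SUMMARY_METRICS if m in results.columns
    ]
    rows = []
    for key, cell in results.groupby(list(group_cols), sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        if len(cell) < 2:
            log.warning("cell %s has n=%d < 2; omitted from summary", key, len(cell))
            continue
        for metric in metrics:
            vals = cell[metric].dropna()
            if len(vals) < 2:
                log.warning("cell %s metric %s has n<2; omitted", key, metric)
                continue
            m, lo, hi = mean_ci(vals)
            rows.append(
                dict(zip(group_cols, key))
                | {"metric": metric, "mean": m, "ci_low": lo, "ci_high": hi, "n": len(vals)}
            )
    return CohortSummary(table=pd.DataFrame(rows))


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    *,
    paired: bool,
    n_comparisons: int,
    contrast: str = "",
    welch: bool = True,
    family_alpha: float = 0.05,
) -> ComparisonResult:
    """t-test between two wettedness samples with Bonferroni threshold.

    Independent contrasts (e.g. young vs older at one environment) use the
    Welch unequal-variance test by default; ``welch=False`` selects the
    pooled-variance form. Paired contrasts (the same subjects at two
    metabolic rates) require aligned, equal-length samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length, aligned samples")
        t_stat, p = sps.ttest_rel(a, b)
    else:
        t_stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    alpha = bonferroni_alpha(n_comparisons, family_alpha)
    return ComparisonResult(
        contrast=contrast,
        t_stat=float(t_stat),
        p_value=float(p),
        alpha=alpha,
        significant=bool(p <= alpha),
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
    )


def format_summary_table(summary: CohortSummary) -> str:
    """Aligned-text rendering with field-conventional rounding.

    Fluxes print as integers, wettedness to two decimals, temperatures and
    pressures to one.
    """
    if summary.table.empty:
        return "(empty summary)\n"
    lines = []
    df = summary.table
    group_cols = [c for c in df.columns if c not in ("metric", "mean", "ci_low", "ci_high", "n")]
    for key, cell in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        lines.append(" / ".join(str(k) for k in key))
        for _, row in cell.iterrows():
            nd = SUMMARY_METRICS.get(row["metric"], 2)
            fmt = f"{{:.{nd}f}}"
            lines.append(
                f"  {row['metric']:>10}: "
                f"{fmt.format(row['mean'])} "
                f"({fmt.format(row['ci_low'])}, {fmt.format(row['ci_high'])})  n={row['n']}"
            )
    return "\n".join(lines) + "\n"
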