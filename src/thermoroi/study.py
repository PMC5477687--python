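"""Study-level statistics on per-subject heat-output tables.

Covers the subject-level analyses around the imaging pipeline: splitting a
cohort into low-BAT and high-BAT groups by the mean + 1 SE rule on percent
change in heat production, paired t tests between conditions, and Pearson
correlations against metabolic covariates (e.g. fasting glucose, BMR).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ZeroVarianceError

__all__ = [
    "GroupAssignment",
    "TTestResult",
    "CorrelationResult",
    "classify_groups",
    "paired_t_test",
    "correlate",
    "summarize_study",
]

LOW_BAT = "low-BAT"
HIGH_BAT = "high-BAT"


@dataclass
class GroupAssignment:
    """Low/high-BAT split of a cohort by percent change in heat production.

    The cutoff is the cohort mean plus one standard error (sample SD with
    n-1 denominator over sqrt(n)); a subject is high-BAT iff its percent
    change strictly exceeds the cutoff.
    """

    cutoff_pct: float
    labels: list[str]

    @property
    def is_high(self) -> np.ndarray:
        return np.array([lab == HIGH_BAT for lab in self.labels])

    @property
    def n_high(self) -> int:
        return int(self.is_high.sum())

    @property
    def n_low(self) -> int:
        return len(self.labels) - self.n_high


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


class CorrelationResult(NamedTuple):
    r: float
    p: float


def classify_groups(pct_changes: Sequence[float]) -> GroupAssignment:
    """Split subjects into low-BAT / high-BAT by the mean + 1 SE rule."""
    x = np.asarray(pct_changes, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 subjects (SE undefined otherwise)")
    if not np.all(np.isfinite(x)):
        raise ValueError("percent changes must be finite")
    se = x.std(ddof=1) / np.sqrt(x.size)
    cutoff = float(x.mean() + se)
    labels = [HIGH_BAT if v > cutoff else LOW_BAT for v in x]
    return GroupAssignment(cutoff_pct=cutoff, labels=labels)


def paired_t_test(
    a: Sequence[float], b: Sequence[float], paired: bool = True
) -> TTestResult:
    """t test between two condition vectors (paired by default).

    Paired mode tests the per-subject differences against zero with
    df = n - 1. All-zero-variance differences leave the statistic undefined
    and raise :class:`ZeroVarianceError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length vectors")
        if a.size < 2:
            raise ValueError("need at least 2 pairs")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            raise ZeroVarianceError(
                "differences have zero variance; paired t undefined"
            )
        res = stats.ttest_rel(a, b)
        df = a.size - 1
    else:
        if a.size < 2 or b.size < 2:
            raise ValueError("need at least 2 observations per group")
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            raise ZeroVarianceError("both groups have zero variance")
        res = stats.ttest_ind(a, b)
        df = a.size + b.size - 2
    return TTestResult(t=float(res.statistic), df=int(df), p=float(res.pvalue))


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        raise ZeroVarianceError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue))


def summarize_study(table: pd.DataFrame) -> dict:
    """Cohort summary: group split, per-group means ± SE, paired contrast.

    ``table`` needs columns ``baseline_w``, ``stimulated_w`` and either a
    ``pct_change`` column or enough data to derive it.
    """
    df = table.copy()
    if "pct_change" not in df.columns:
        df["pct_change"] = 100.0 * (df["stimulated_w"] - df["baseline_w"]) / df["baseline_w"]
    assignment = classify_groups(df["pct_change"].to_numpy())
    df["group"] = assignment.labels

    def mean_se(v: np.ndarray) -> dict:
        v = np.asarray(v, dtype=float)
        return {
            "mean": float(v.mean()),
            "se": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan"),
            "n": int(v.size),
        }

    groups = {
        name: {
            "pct_change": mean_se(sub["pct_change"]),
            "delta_total_w": mean_se(sub["stimulated_w"] - sub["baseline_w"]),
        }
        for name, sub in df.groupby("group")
    }
    try:
        contrast = paired_t_test(df["stimulated_w"], df["baseline_w"])._asdict()
    except ZeroVarianceError:
        contrast = None
    return {
        "n_subjects": int(len(df)),
        "cutoff_pct": assignment.cutoff_pct,
        "n_high_bat": assignment.n_high,
        "n_low_bat": assignment.n_low,
        "groups": groups,
        "stimulated_vs_baseline_paired_t": contrast,
    }
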