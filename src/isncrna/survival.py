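"""UV-survival statistics for the larval developmental-arrest assay.

L4 larvae are irradiated at increasing UV doses; animals developing
beyond L4 count as survivors, developmentally arrested animals as
non-survivors.  Survival percentage is computed per replicate, averaged
across independent experiments, and RNAi conditions are compared to the
control with a paired t-test pairing replicate-level percentages by
(dose, replicate) across the shared dose range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

COUNT_COLUMNS = ["condition", "dose", "replicate", "n_survived", "n_arrested"]


def survival_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Replicate-level survival percentages.

    Expects columns ``condition, dose, replicate, n_survived,
    n_arrested`` (an optional ``plate`` column marks duplicate plates,
    which are pooled within a replicate before the percentage is taken).
    Raises when a replicate has zero animals.
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table lacks columns {missing}")
    df = counts.copy()
    if (df[["n_survived", "n_arrested"]].to_numpy() < 0).any():
        raise ValueError("negative counts")
    df = (
        df.groupby(["condition", "dose", "replicate"], as_index=False)[
            ["n_survived", "n_arrested"]
        ].sum()
    )
    total = df["n_survived"] + df["n_arrested"]
    if (total == 0).any():
        bad = df.loc[total == 0, ["condition", "dose", "replicate"]].iloc[0]
        raise ValueError(f"zero animals in {tuple(bad)}")
    df["percent"] = 100.0 * df["n_survived"] / total
    return df


@dataclass
class SurvivalCurve:
    """Dose-response summary plus the replicate-level percentages."""

    summary: pd.DataFrame  # condition, dose, mean_percent, sem, n
    replicates: pd.DataFrame  # condition, dose, replicate, percent

    def conditions(self) -> list:
        return sorted(self.summary["condition"].unique())


def survival_curve(counts: pd.DataFrame) -> SurvivalCurve:
    """Mean survival percentage and SEM per condition and dose."""
    reps = survival_percentages(counts)
    grouped = reps.groupby(["condition", "dose"])["percent"]
    summary = grouped.agg(mean_percent="mean", sem="sem", n="count").reset_index()
    return SurvivalCurve(summary=summary, replicates=reps[["condition", "dose", "replicate", "percent"]])


def paired_ttest(
    curve: SurvivalCurve,
    condition: str,
    control: str,
    doses: Optional[Sequence[float]] = None,
) -> float:
    """Two-sided paired t-test of a condition against the control.

    Pairs are replicate-level survival percentages matched by
    (dose, replicate) over the shared dose range (or ``doses`` if given).
    Degenerate all-identical pairs are reported as non-significant
    (p = 1) with a warning rather than NaN.
    """
    reps = curve.replicates
    a = reps[reps["condition"] == condition]
    b = reps[reps["condition"] == control]
    if a.empty or b.empty:
        raise ValueError("condition or control absent from curve")
    merged = a.merge(b, on=["dose", "replicate"], suffixes=("_cond", "_ctrl"))
    if doses is not None:
        merged = merged[merged["dose"].isin(doses)]
    if len(merged) < 2:
        raise ValueError(f"need >= 2 matched (dose, replicate) pairs, got {len(merged)}")
    x = merged["percent_cond"].to_numpy()
    y = merged["percent_ctrl"].to_numpy()
    diff = x - y
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            warnings.warn("zero-variance identical pairs; reporting non-significant")
            return 1.0
        # constant non-zero difference: the t statistic diverges
        warnings.warn("constant non-zero paired difference; reporting p = 0")
        return 0.0
    return float(stats.ttest_rel(x, y).pvalue)


def per_dose_tests(curve: SurvivalCurve, condition: str, control: str) -> Dict[float, float]:
    """Unpaired two-sample t-test per shared dose (complements the pooled
    paired test when single doses are of interest)."""
    reps = curve.replicates
    out: Dict[float, float] = {}
    doses = sorted(
        set(reps.loc[reps["condition"] == condition, "dose"])
        & set(reps.loc[reps["condition"] == control, "dose"])
    )
    for dose in doses:
        x = reps[(reps["condition"] == condition) & (reps["dose"] == dose)]["percent"]
        y = reps[(reps["condition"] == control) & (reps["dose"] == dose)]["percent"]
        if len(x) < 2 or len(y) < 2:
            continue
        if np.allclose(x.std(ddof=1), 0) and np.allclose(y.std(ddof=1), 0):
            out[float(dose)] = 1.0 if np.allclose(x.mean(), y.mean()) else 0.0
            continue
        out[float(dose)] = float(stats.ttest_ind(x, y).pvalue)
    return out
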