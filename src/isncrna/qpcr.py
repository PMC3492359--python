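"""Relative qPCR quantification by the 2^-ddCt method.

Per replicate, dCt = Ct(target) - Ct(reference transcript); per
condition, ddCt = mean dCt(condition) - mean dCt(calibrator), and the
relative quantity is rq = 2^-ddCt (calibrator rq = 1 by construction).
Replicate scatter is propagated by back-transforming each replicate's
dCt against the calibrator mean; significance comes from a two-sided
two-sample t-test on the dCt replicate sets, which are approximately
normal on the cycle scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["target_id", "reference_id", "condition", "replicate", "ct_target", "ct_reference"]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star annotation."""
    if p is None or np.isnan(p):
        return "ns"
    for thr, mark in STAR_THRESHOLDS:
        if p < thr:
            return mark
    return "ns"


@dataclass(slots=True)
class RelativeExpression:
    target_id: str
    condition: str
    n_replicates: int
    rq: float
    sem: float  # NaN when < 2 replicates
    p_value: float  # NaN for the calibrator or < 2 replicates
    stars: str


def ddct(
    ct_table: pd.DataFrame,
    calibrator_condition: str,
    *,
    welch: bool = False,
) -> List[RelativeExpression]:
    """2^-ddCt relative expression for every (target, condition).

    ``ct_table`` needs the columns ``target_id, reference_id, condition,
    replicate, ct_target, ct_reference``.  Raises if a target lacks the
    calibrator condition.  With a single replicate the point estimate is
    still produced but SEM and p-value are reported as NaN.
    """
    missing = [c for c in CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    df = ct_table.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]

    out: List[RelativeExpression] = []
    for target, sub in df.groupby("target_id", sort=True):
        by_cond = {c: g["dct"].to_numpy() for c, g in sub.groupby("condition")}
        if calibrator_condition not in by_cond:
            raise ValueError(f"target {target!r}: calibrator {calibrator_condition!r} missing")
        cal = by_cond[calibrator_condition]
        cal_mean = float(cal.mean())
        for cond in sorted(by_cond):
            dct = by_cond[cond]
            n = len(dct)
            ddct_val = float(dct.mean()) - cal_mean
            rq = float(2.0 ** (-ddct_val))
            if cond == calibrator_condition:
                rq = 1.0  # exact by construction
            rq_reps = 2.0 ** (-(dct - cal_mean))
            sem = float(rq_reps.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
            if cond == calibrator_condition or n < 2 or len(cal) < 2:
                p = float("nan")
            else:
                p = float(stats.ttest_ind(dct, cal, equal_var=not welch).pvalue)
            out.append(
                RelativeExpression(
                    target_id=target,
                    condition=cond,
                    n_replicates=n,
                    rq=rq,
                    sem=sem,
                    p_value=p,
                    stars=significance_stars(p),
                )
            )
    return out


def relative_expression_frame(results: List[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_id": r.target_id,
                "condition": r.condition,
                "n": r.n_replicates,
                "rq": r.rq,
                "sem": r.sem,
                "p_value": r.p_value,
                "stars": r.stars,
            }
            for r in results
        ]
    )
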