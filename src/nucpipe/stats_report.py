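"""Replicate-level summaries and significance testing.

The experimental unit is the biological replicate: per-cell or per-edge
measurements are first reduced to one value per replicate, and conditions
are compared by Student's t-test on those replicate values (paired by
replicate index when the design is paired, pooled-variance unpaired
otherwise; Welch's correction is available behind a flag but is not the
default). Significance stars follow the usual 0.05 / 0.01 / 0.001 ladder.
No multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["TTestResult", "t_test", "stars", "condition_compare"]


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    paired: bool
    degenerate: bool = False  # zero-variance input; t/p reported by convention


def t_test(group_a, group_b, paired: bool = False, welch: bool = False) -> TTestResult:
    """Two-sided Student's t-test.

    Paired: classic one-sample t on the differences. Unpaired: pooled-
    variance two-sample t (``welch=True`` switches to the unequal-variance
    form). Degenerate zero-variance inputs are reported explicitly instead
    of silently propagating NaN: zero mean difference gives t=0, p=1; a
    nonzero difference with zero variance gives infinite t and p=0, both
    flagged ``degenerate``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length groups")
        if a.size < 2:
            raise ValueError("paired test requires n >= 2 pairs")
        d = a - b
        if d.std(ddof=1) == 0.0:
            if d.mean() == 0.0:
                return TTestResult(0.0, float(a.size - 1), 1.0, True, True)
            t = math.copysign(math.inf, d.mean())
            return TTestResult(t, float(a.size - 1), 0.0, True, True)
        res = stats.ttest_rel(a, b)
        return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), True)
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired test requires n >= 2 in each group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0, False, True)
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()), df, 0.0, False, True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), False)


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def condition_compare(
    summaries: pd.DataFrame,
    control: str,
    paired: bool = False,
    welch: bool = False,
) -> pd.DataFrame:
    """Mean ± SD per condition with tests against a control condition.

    ``summaries`` holds one row per (condition, replicate): columns
    ``condition``, ``replicate_id``, ``value``. Every condition needs at
    least two replicates; paired comparisons are matched on
    ``replicate_id``. The control row carries no test columns.
    """
    needed = {"condition", "replicate_id", "value"}
    missing = needed - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    conditions = list(dict.fromkeys(summaries["condition"]))
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not present")
    by_cond = {
        c: summaries[summaries["condition"] == c].set_index("replicate_id")["value"]
        for c in conditions
    }
    for c, vals in by_cond.items():
        if len(vals) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 replicates")
    rows = []
    ctrl = by_cond[control]
    for c in conditions:
        vals = by_cond[c]
        row = {
            "condition": c,
            "n_replicates": int(len(vals)),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "t": np.nan,
            "df": np.nan,
            "p": np.nan,
            "stars": "",
        }
        if c != control:
            if paired:
                common = vals.index.intersection(ctrl.index)
                if len(common) < 2:
                    raise ValueError(
                        f"condition {c!r} shares fewer than 2 replicates with control"
                    )
                res = t_test(vals.loc[common], ctrl.loc[common], paired=True)
            else:
                res = t_test(vals, ctrl, paired=False, welch=welch)
            row.update(t=res.t, df=res.df, p=res.p, stars=stars(res.p))
        rows.append(row)
    return pd.DataFrame(rows)
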