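"""Relative quantification of qPCR data by the comparative-Ct method.

Each well contributes ``dCt = Ct(target) - Ct(reference)``.  For an
experimental group, every replicate's dCt is compared against the *mean*
naive dCt (the standard implementation when replicates are unpaired):

    ddCt_r = dCt_r - mean(dCt_naive);   value_r = 2 ** (-ddCt_r)

assuming doubling efficiency per cycle.  Group values are summarized as
mean ± standard error over replicates.  Group comparisons use the pooled
(equal-variance) one-tailed t-test.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import NAIVE, InputError

__all__ = ["RelativeExpression", "delta_delta_ct", "relative_expression_table",
           "one_tailed_equal_variance_t"]


@dataclass
class RelativeExpression:
    target: str
    group: str
    values: np.ndarray          # one 2^-ddCt per experimental replicate
    mean: float
    se: float


def delta_delta_ct(exp: pd.DataFrame, naive: pd.DataFrame) -> RelativeExpression:
    """Relative expression of one target in one group vs the naive group.

    Both frames need columns ct_target and ct_reference (one row per
    replicate); ``exp`` additionally needs target and group labels on its
    rows (the first row's values are used).
    """
    for name, df in (("experimental", exp), ("naive", naive)):
        if df.empty:
            raise InputError(f"no {name} Ct records")
        missing = {"ct_target", "ct_reference"} - set(df.columns)
        if missing:
            raise InputError(f"{name} table lacks columns {sorted(missing)}")
    dct_exp = exp["ct_target"].to_numpy(float) - exp["ct_reference"].to_numpy(float)
    dct_naive = naive["ct_target"].to_numpy(float) - naive["ct_reference"].to_numpy(float)
    ddct = dct_exp - dct_naive.mean()
    values = np.exp2(-ddct)
    se = (values.std(ddof=1) / math.sqrt(values.size)
          if values.size > 1 else float("nan"))
    return RelativeExpression(
        target=str(exp["target"].iloc[0]) if "target" in exp.columns else "",
        group=str(exp["group"].iloc[0]) if "group" in exp.columns else "",
        values=values,
        mean=float(values.mean()),
        se=float(se),
    )


def relative_expression_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Relative expression for every (target, non-naive group) in a long
    Ct table with columns sample, group, target, ct_target, ct_reference."""
    required = {"sample", "group", "target", "ct_target", "ct_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise InputError(f"Ct table lacks columns {sorted(missing)}")
    rows = []
    for target, sub in ct.groupby("target", sort=True):
        naive = sub[sub["group"] == NAIVE]
        if naive.empty:
            raise InputError(f"no naive Ct records for target {target!r}")
        for group, grp in sub.groupby("group", sort=True):
            if group == NAIVE:
                continue
            rel = delta_delta_ct(grp, naive)
            rows.append((target, group, rel.mean, rel.se, len(rel.values)))
    return pd.DataFrame(rows, columns=["target", "group", "mean_expression",
                                       "se", "n"])


def one_tailed_equal_variance_t(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance t statistic and one-tailed p for H1: mean(a) > mean(b).

    Degrees of freedom are ``n_a + n_b - 2``.  With zero pooled variance
    and equal means the comparison is degenerate and p = 0.5 is returned
    with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance and equal means; degenerate test")
            return 0.0, 0.5
        warnings.warn("zero pooled variance; p collapses to 0 or 1")
        return (math.inf, 0.0) if a.mean() > b.mean() else (-math.inf, 1.0)
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
    return float(t), float(p)
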