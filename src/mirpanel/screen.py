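"""Univariate two-sample t-test screening of candidate miRNAs.

The screen reduces the candidate list to markers whose normalized
expression differs between two cohorts at raw P < alpha, using the pooled
variance (Student) two-sample t-test by default; Welch's unequal-variance
variant is available.  Benjamini-Hochberg q-values are reported for
transparency but are never used for selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix

__all__ = ["ScreenResult", "t_screen"]


@dataclass(eq=False)
class ScreenResult:
    """Per-miRNA screening table plus the selected subset.

    ``table`` columns: t, p, q (Benjamini-Hochberg), mean_a, mean_b, diff
    (mean_a - mean_b), indexed by miRNA.  ``selected`` is exactly
    ``{m : p_m < alpha}`` in table order.
    """

    table: pd.DataFrame
    selected: list[str]
    alpha: float
    group_a: str = "A"
    group_b: str = "B"


def t_screen(
    expr: ExpressionMatrix | pd.DataFrame,
    group_a,
    group_b,
    alpha: float = 0.05,
    welch: bool = False,
) -> ScreenResult:
    """Screen every miRNA between two sample subsets by a two-sample t-test.

    Parameters
    ----------
    expr
        Expression matrix (samples x miRNAs).
    group_a, group_b
        Sample-id subsets for the two cohorts; each needs >= 2 samples.
    alpha
        Selection threshold on the raw two-sided P value (strict <).
    welch
        Use Welch's unequal-variance t instead of the pooled (Student) t.

    Notes
    -----
    If a miRNA has zero pooled variance the t statistic is degenerate:
    P is defined as 1 when the group means agree, else 0 (with a warning).
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    a = values.loc[group_a].to_numpy(dtype=float)
    b = values.loc[group_b].to_numpy(dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite expression values in screening input")
    na, nb = len(group_a), len(group_b)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    var_a, var_b = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    diff = mean_a - mean_b

    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = var_a / na + var_b / nb
            t = diff / np.sqrt(se2)
            df = se2**2 / (
                (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
            )
        else:
            df = np.full(a.shape[1], na + nb - 2.0)
            sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
            t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = ~np.isfinite(t)
    if degenerate.any():
        equal_means = np.isclose(diff, 0.0)
        inf_t = np.where(diff > 0, np.inf, -np.inf)
        t = np.where(degenerate, np.where(equal_means, 0.0, inf_t), t)
        p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
        if (degenerate & ~equal_means).any():
            bad = values.columns[degenerate & ~equal_means][0]
            warnings.warn(
                f"zero within-group variance with unequal means for {bad!r}; "
                "P defined as 0",
                stacklevel=2,
            )

    q = stats.false_discovery_control(np.clip(p, 0.0, 1.0))
    table = pd.DataFrame(
        {"t": t, "p": p, "q": q, "mean_a": mean_a, "mean_b": mean_b, "diff": diff},
        index=values.columns,
    )
    table.index.name = "mirna"
    selected = [m for m, pv in zip(table.index, p) if pv < alpha]
    return ScreenResult(table=table, selected=selected, alpha=alpha)
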