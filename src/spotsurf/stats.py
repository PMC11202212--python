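"""Shared inferential machinery: two-way ANOVA, Šidák adjustment, t-test.

Standard model fits go through statsmodels/scipy; the Šidák adjustment is
computed in closed form because the family size ``m`` must be settable
independently of the number of p-values supplied (the family is the number
of distance bins tested, not the number of finite p-values).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import DomainError

__all__ = ["two_way_anova", "sidak_adjust", "unpaired_t"]


def two_way_anova(
    table: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> dict:
    """Two-way fixed-effects ANOVA with interaction, Type II sums of squares.

    Returns a dict with ``F_a, p_a, F_b, p_b, F_interaction, p_interaction``.
    A constant response yields ``F = 0, p = 1`` for every term.
    """
    for col in (response, factor_a, factor_b):
        if col not in table.columns:
            raise DomainError(f"table lacks required column {col!r}")
    if table[factor_a].nunique() < 2 or table[factor_b].nunique() < 2:
        raise DomainError("both factors need at least 2 levels for an interaction model")
    y = table[response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return {
            "F_a": 0.0, "p_a": 1.0,
            "F_b": 0.0, "p_b": 1.0,
            "F_interaction": 0.0, "p_interaction": 1.0,
        }
    df = table.rename(columns={response: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    if model.df_resid < 1:
        raise DomainError("no residual degrees of freedom (need replicates within cells)")
    aov = sm.stats.anova_lm(model, typ=2)
    def _get(term):
        return float(aov.loc[term, "F"]), float(aov.loc[term, "PR(>F)"])
    F_a, p_a = _get("C(_a)")
    F_b, p_b = _get("C(_b)")
    F_i, p_i = _get("C(_a):C(_b)")
    return {
        "F_a": F_a, "p_a": p_a,
        "F_b": F_b, "p_b": p_b,
        "F_interaction": F_i, "p_interaction": p_i,
    }


def sidak_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Šidák multiplicity adjustment ``p_adj = 1 − (1 − p)^m``, capped at 1.

    ``m`` defaults to ``len(p_values)`` and must be at least that many.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) & np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise DomainError(f"family size m={m} smaller than the number of p-values ({p.size})")
    # -expm1(m·log1p(-p)) is the same closed form but exact for tiny p
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = -np.expm1(m * np.log1p(-p))
    adj = np.where(p >= 1.0, 1.0, adj)
    return np.clip(adj, p, 1.0)


def unpaired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classic pooled-variance unpaired two-tailed Student's t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each group needs at least 2 values")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    if sp2 <= 0:
        raise DomainError("pooled variance is zero; t-test undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
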