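"""ΔCT relative expression and expression–production regressions.

ΔCT(ewe, gene) = mean CT of the target minus mean CT of the reference
gene (technical replicates averaged first), so a *higher* ΔCT means
*lower* relative expression.  The validation stage regresses each
gene's ΔCT on observed daily milk yield and on the BLUP estimated
values, plus yield on estimate, reporting slope signs and R².
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd


def delta_ct(table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Ewe × gene ΔCT matrix from a long CT table.

    ``table`` needs columns ``ewe, gene, replicate, ct``.  Replicates are
    averaged per (ewe, gene) before subtracting the ewe's mean reference
    CT.  Raises when an ewe lacks the reference gene.
    """
    for col in ("ewe", "gene", "ct"):
        if col not in table.columns:
            raise ValueError(f"CT table missing column {col!r}")
    means = table.groupby(["ewe", "gene"])["ct"].mean().unstack()
    if reference_gene not in means.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent")
    missing_ref = means.index[means[reference_gene].isna()]
    if len(missing_ref):
        raise ValueError(
            f"no reference-gene CT for ewe {missing_ref[0]!r}")
    dct = means.sub(means[reference_gene], axis=0)
    return dct.drop(columns=[reference_gene])


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def ols_r2(x, y) -> RegressionResult:
    """Simple ordinary-least-squares fit of y on x with R².

    Closed-form normal equations; a constant y gives R² = 0 with a
    warning (nothing to explain).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0.0:
        raise ValueError("x has zero variance")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0.0:
        warnings.warn("ols_r2: constant response, R^2 defined as 0")
        return RegressionResult(float(slope), float(intercept), 0.0, n)
    sse = np.sum((y - intercept - slope * x) ** 2)
    r2 = 1.0 - sse / sst
    return RegressionResult(float(slope), float(intercept),
                            float(min(max(r2, 0.0), 1.0)), n)


def expression_production_report(
    dct: pd.DataFrame,
    milk_yields: pd.Series,
    estimated_values: pd.Series,
) -> tuple[pd.DataFrame, RegressionResult]:
    """Per-gene ΔCT regressions against yield and estimated values.

    All inputs are indexed by ewe; only ewes present in all three are
    used (>= 3 required).  Returns ``(per-gene table, yield~estimate
    regression)``; the table holds slope and R² of ΔCT on yield and of
    ΔCT on estimate for every gene.
    """
    ewes = dct.index.intersection(milk_yields.index) \
                    .intersection(estimated_values.index)
    if len(ewes) < 3:
        raise ValueError("fewer than 3 ewes aligned across inputs")
    d = dct.loc[ewes]
    yld = milk_yields.loc[ewes].to_numpy(dtype=float)
    est = estimated_values.loc[ewes].to_numpy(dtype=float)

    rows = []
    for gene in d.columns:
        v = d[gene].to_numpy(dtype=float)
        ry = ols_r2(yld, v)
        re = ols_r2(est, v)
        rows.append((gene, ry.slope, ry.r_squared, re.slope, re.r_squared))
    table = pd.DataFrame(rows, columns=[
        "gene", "slope_dct_vs_yield", "r2_dct_vs_yield",
        "slope_dct_vs_estimate", "r2_dct_vs_estimate"])
    yield_vs_estimate = ols_r2(est, yld)
    return table, yield_vs_estimate
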