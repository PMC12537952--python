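"""Two-factor linear model for bioenergetic endpoints.

Endpoints such as respiration states, enzymatic activities and MHI are
analyzed with the saturated 2x2 model

    value ~ genotype + condition + genotype:condition

fit by ordinary least squares with treatment coding (reference levels:
first factor level, conventionally WT and SPF/vehicle), followed by
pairwise cell-mean contrasts with pooled residual variance and
Benjamini-Hochberg adjustment across the requested family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .ranktests import bh_adjust


@dataclass
class FactorialFit:
    model: object  # statsmodels RegressionResults
    cell_means: pd.Series  # indexed by "genotype.condition"
    cell_counts: pd.Series
    residual_df: int
    sigma2: float  # pooled residual variance
    coefficients: pd.DataFrame  # estimate, se per term


def _cell_key(genotype: str, condition: str) -> str:
    return f"{genotype}.{condition}"


def fit_two_factor(
    values: Sequence[float],
    genotype: Sequence[str],
    condition: Sequence[str],
    reference: tuple[str, str] | None = None,
) -> FactorialFit:
    """OLS fit of value ~ genotype * condition with treatment coding.

    Requires every factorial cell to be occupied. ``reference`` pins the
    baseline levels (e.g. ("WT", "SPF")); by default the
    lexicographically first levels are used. Cell means are recoverable
    exactly from the coefficients in this saturated model.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float),
         "genotype": list(genotype), "condition": list(condition)}
    )
    if df["value"].isna().any():
        raise ValueError("values must be finite")
    counts = df.groupby(["genotype", "condition"], observed=True).size()
    g_levels = df["genotype"].unique()
    c_levels = df["condition"].unique()
    for g in g_levels:
        for c in c_levels:
            if (g, c) not in counts.index:
                raise ValueError(f"empty factorial cell: {g}.{c}")
    if reference is not None:
        g_ref, c_ref = reference
        formula = (
            f"value ~ C(genotype, Treatment(reference={g_ref!r})) * "
            f"C(condition, Treatment(reference={c_ref!r}))"
        )
    else:
        formula = "value ~ C(genotype) * C(condition)"
    res = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    if res.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    if res.df_resid < 5:
        import warnings

        warnings.warn("fewer than 5 residual degrees of freedom", stacklevel=2)

    means = df.groupby(["genotype", "condition"], observed=True)["value"].mean()
    cell_means = pd.Series(
        {_cell_key(g, c): m for (g, c), m in means.items()}
    ).sort_index()
    cell_counts = pd.Series(
        {_cell_key(g, c): n for (g, c), n in counts.items()}
    ).sort_index()
    coef = pd.DataFrame({"estimate": res.params, "se": res.bse})
    return FactorialFit(
        model=res,
        cell_means=cell_means,
        cell_counts=cell_counts,
        residual_df=int(res.df_resid),
        sigma2=float(res.mse_resid),
        coefficients=coef,
    )


def pairwise_contrasts(
    fit: FactorialFit, pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Cell-mean differences with pooled-variance t tests and BH column.

    Each pair names two cells as "genotype.condition" keys. The standard
    error uses the single OLS residual variance, so on balanced data the
    contrast t equals the classical pooled two-sample t. BH adjustment
    spans exactly the requested family.
    """
    rows = []
    for a, b in pairs:
        for cell in (a, b):
            if cell not in fit.cell_means.index:
                raise ValueError(f"unknown cell {cell!r}; "
                                 f"known: {list(fit.cell_means.index)}")
        est = fit.cell_means[a] - fit.cell_means[b]
        se = np.sqrt(fit.sigma2 * (1.0 / fit.cell_counts[a] + 1.0 / fit.cell_counts[b]))
        t = est / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(t), df=fit.residual_df))
        rows.append({"group_a": a, "group_b": b, "estimate": float(est),
                     "se": float(se), "t": float(t), "p_raw": p})
    tab = pd.DataFrame(rows)
    tab["p_bh"] = bh_adjust(tab["p_raw"].to_numpy()) if len(tab) else []
    return tab
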