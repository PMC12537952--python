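"""Rank-based group comparisons: Kruskal-Wallis, Conover and Dunn
post-hoc tests, and Benjamini-Hochberg FDR adjustment.

These are implemented from the defining formulas (with mid-rank tie
handling throughout) rather than delegated, because tie-corrected
post-hoc statistics are the quantity of interest here; scipy's
``kruskal`` serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {self.label!r} is empty")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {self.label!r} has non-finite values")
        object.__setattr__(self, "values", v)


@dataclass
class KruskalWallisResult:
    statistic: float
    p_value: float
    tie_corrected: bool
    df: int
    n_total: int
    mean_ranks: dict
    group_sizes: dict
    tie_correction: float


def _ranked(groups: Sequence[GroupSample]):
    """Pool values, mid-rank, and return per-group rank slices + tie sizes."""
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    pooled = np.concatenate([g.values for g in groups])
    ranks = stats.rankdata(pooled, method="average")
    sizes = [g.values.size for g in groups]
    idx = np.cumsum([0, *sizes])
    per_group = {g.label: ranks[idx[i]: idx[i + 1]] for i, g in enumerate(groups)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    return per_group, ranks, tie_counts


def kruskal_wallis(groups: Sequence[GroupSample]) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H test.

    H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from chi-square on k-1 df.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    per_group, ranks, ties = _ranked(groups)
    n = ranks.size
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    k = len(groups)
    grand_mean = (n + 1) / 2.0
    h = 12.0 / (n * (n + 1)) * sum(
        r.size * (r.mean() - grand_mean) ** 2 for r in per_group.values()
    )
    tie_term = float(np.sum(ties**3 - ties)) / (n**3 - n)
    correction = 1.0 - tie_term
    if correction <= 0:  # all values identical
        return KruskalWallisResult(0.0, 1.0, True, k - 1, n,
                                   {g: r.mean() for g, r in per_group.items()},
                                   {g: r.size for g, r in per_group.items()}, correction)
    h /= correction
    p = float(stats.chi2.sf(h, df=k - 1))
    return KruskalWallisResult(
        statistic=float(h),
        p_value=p,
        tie_corrected=tie_term > 0,
        df=k - 1,
        n_total=n,
        mean_ranks={g: float(r.mean()) for g, r in per_group.items()},
        group_sizes={g: int(r.size) for g, r in per_group.items()},
        tie_correction=correction,
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (m/j) p_(j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _posthoc_table(rows: list[dict]) -> pd.DataFrame:
    tab = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_raw"])
    tab["p_adjusted"] = bh_adjust(tab["p_raw"].to_numpy()) if len(tab) else []
    return tab


def conover_posthoc(
    groups: Sequence[GroupSample],
    kw: KruskalWallisResult | None = None,
) -> pd.DataFrame:
    """Conover-Iman pairwise comparisons after Kruskal-Wallis.

    t = (Rbar_a - Rbar_b) / sqrt(S^2 * (N-1-H)/(N-k) * (1/n_a + 1/n_b))
    with pooled rank variance S^2 = (sum R_i^2 - N(N+1)^2/4)/(N-1); the
    tie-corrected H from the omnibus test enters the scale factor.
    Two-sided p from Student t on N-k df; BH-adjusted column included.
    """
    if kw is None:
        kw = kruskal_wallis(groups)
    per_group, ranks, _ = _ranked(groups)
    n, k = ranks.size, len(groups)
    if n - k <= 0:
        raise ValueError("insufficient residual degrees of freedom")
    s2 = (float(np.sum(ranks**2)) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    scale = s2 * (n - 1 - kw.statistic) / (n - k)
    scale = max(scale, 0.0)  # H can slightly exceed N-1 under heavy ties
    rows = []
    for (la, ra), (lb, rb) in combinations(per_group.items(), 2):
        se = np.sqrt(scale * (1.0 / ra.size + 1.0 / rb.size))
        diff = ra.mean() - rb.mean()
        if se == 0:
            t = 0.0 if diff == 0 else np.sign(diff) * np.inf
        else:
            t = diff / se
        p = float(2 * stats.t.sf(abs(t), df=n - k))
        rows.append({"group_a": la, "group_b": lb, "statistic": float(t), "p_raw": p})
    return _posthoc_table(rows)


def dunn_posthoc(groups: Sequence[GroupSample]) -> pd.DataFrame:
    """Dunn's pairwise z tests on mean ranks with tie correction.

    z = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - sum(t^3-t)/(12(N-1)))
                                 * (1/n_a + 1/n_b))
    Two-sided normal p with a BH-adjusted column.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    per_group, ranks, ties = _ranked(groups)
    n = ranks.size
    var = n * (n + 1) / 12.0 - float(np.sum(ties**3 - ties)) / (12.0 * (n - 1))
    rows = []
    for (la, ra), (lb, rb) in combinations(per_group.items(), 2):
        se = np.sqrt(var * (1.0 / ra.size + 1.0 / rb.size))
        diff = ra.mean() - rb.mean()
        if se == 0:
            z = 0.0 if diff == 0 else np.sign(diff) * np.inf
        else:
            z = diff / se
        p = float(2 * stats.norm.sf(abs(z)))
        rows.append({"group_a": la, "group_b": lb, "statistic": float(z), "p_raw": p})
    return _posthoc_table(rows)
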