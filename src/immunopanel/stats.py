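"""Statistical primitives: two-sided Wilcoxon rank-sum, Pearson correlation,
and stratified group-comparison / correlation tables.

The Wilcoxon rank-sum test is exact (full enumeration of group assignments
of the pooled sample, which handles ties naturally through average ranks)
for small combined sample sizes, and otherwise uses the normal approximation
with tie and continuity corrections.  All p-values are two-sided, and the
flat p < 0.05 threshold is the default significance rule, with optional
Benjamini-Hochberg adjustment for the stratified tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

#: combined-sample-size bound under which the exact enumeration runs
EXACT_CUTOFF = 12

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample rank test."""

    statistic: float  # Mann-Whitney U for the first sample
    p_value: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def wilcoxon_rank_sum(x, y, exact_cutoff: int = EXACT_CUTOFF) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    With n1 + n2 <= ``exact_cutoff`` the null is enumerated exactly over all
    C(n1+n2, n1) assignments of the pooled values (ties included via average
    ranks); the two-sided p is the fraction of assignments whose rank-sum
    deviates from its null mean at least as much as observed.  Larger
    samples use the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("wilcoxon_rank_sum requires non-empty groups")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled, method="average")
    w_obs = ranks[:n1].sum()
    u_obs = w_obs - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    if n <= exact_cutoff:
        mean_w = n1 * (n + 1) / 2.0
        dev = abs(w_obs - mean_w)
        hits = 0
        for idx in combinations(range(n), n1):
            if abs(ranks[list(idx)].sum() - mean_w) >= dev - 1e-9:
                hits += 1
        p = hits / comb(n, n1)
        return TestResult(float(u_obs), float(p), "exact", n1, n2)
    # tie-corrected variance is zero when every pooled value is identical
    if np.all(pooled == pooled[0]):
        return TestResult(float(u_obs), 1.0, "normal_approx", n1, n2)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(float(res.statistic), float(res.pvalue), "normal_approx", n1, n2)


def pearson(x, y) -> PearsonResult:
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("pearson requires paired inputs")
    if len(x) < 3:
        raise ValidationError("pearson requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson undefined for constant input")
    res = sps.pearsonr(x, y)
    return PearsonResult(float(res.statistic), float(res.pvalue), len(x))


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_i in range(m, 0, -1):
        i = order[rank_i - 1]
        running = min(running, p[i] * m / rank_i)
        adj[i] = running
    return adj


def groupwise_compare(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    group_key: str = "condition",
    strata: str = "tissue",
    groups: tuple[str, str] = ("tumor", "normal"),
    value_columns: list[str] | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Two-group Wilcoxon comparison of each score, within each stratum.

    Returns one row per (stratum, score) with group sizes, medians, the
    direction of the median difference, the two-sided p and an "ns" flag at
    p >= 0.05.  Strata missing either group are reported not-testable.
    """
    for col in (group_key, strata):
        if col not in meta.columns:
            raise ValidationError(f"metadata lacks column {col!r}")
    value_columns = value_columns or list(scores.columns)
    merged = scores.join(meta.set_index("sample_id")[[group_key, strata]], how="inner")
    rows = []
    for stratum, chunk in merged.groupby(strata, sort=True):
        g1 = chunk[chunk[group_key] == groups[0]]
        g2 = chunk[chunk[group_key] == groups[1]]
        for col in value_columns:
            row = {
                "stratum": stratum,
                "score": col,
                "n_" + groups[0]: len(g1),
                "n_" + groups[1]: len(g2),
            }
            if len(g1) == 0 or len(g2) == 0:
                row.update(
                    testable=False, median_diff=np.nan, direction="not-testable",
                    statistic=np.nan, p_value=np.nan, significant=False,
                )
            else:
                m1, m2 = g1[col].median(), g2[col].median()
                test = wilcoxon_rank_sum(g1[col].to_numpy(), g2[col].to_numpy())
                row.update(
                    testable=True,
                    **{"median_" + groups[0]: m1, "median_" + groups[1]: m2},
                    median_diff=m1 - m2,
                    direction=(
                        f"{groups[0]}>{groups[1]}" if m1 > m2
                        else f"{groups[0]}<{groups[1]}" if m1 < m2 else "equal"
                    ),
                    statistic=test.statistic,
                    p_value=test.p_value,
                    significant=test.significant,
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    if bh_adjust and table["testable"].any():
        mask = table["testable"].to_numpy()
        adj = np.full(len(table), np.nan)
        adj[mask] = benjamini_hochberg(table.loc[mask, "p_value"].to_numpy())
        table["p_adjusted"] = adj
        table.loc[mask, "significant"] = table.loc[mask, "p_adjusted"] < ALPHA
    table["ns"] = ~table["significant"].astype(bool)
    return table


def correlation_by_stratum(
    a: pd.Series,
    b: pd.Series,
    strata: pd.Series,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson r and two-sided p between two per-sample quantities, per stratum.

    Pairs with a missing value in either input are dropped; strata with
    fewer than ``min_n`` complete pairs (or a constant input) are flagged
    not-testable.
    """
    df = pd.DataFrame({"a": a, "b": b, "stratum": strata}).dropna()
    rows = []
    for stratum, chunk in df.groupby("stratum", sort=True):
        row = {"stratum": stratum, "n": len(chunk)}
        if len(chunk) < min_n or chunk["a"].nunique() < 2 or chunk["b"].nunique() < 2:
            row.update(testable=False, r=np.nan, p_value=np.nan, significant=False)
        else:
            res = pearson(chunk["a"].to_numpy(), chunk["b"].to_numpy())
            row.update(
                testable=True, r=res.r, p_value=res.p_value,
                significant=res.significant,
            )
        rows.append(row)
    return pd.DataFrame(rows)
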