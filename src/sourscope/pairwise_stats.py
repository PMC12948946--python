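"""Pairwise tests and effect sizes: chi-square / Cramer's V, Mann-Whitney /
rank-biserial, t-test / Cohen's d, Benjamini-Hochberg FDR, and the signed
(directional) Cramer's V used for clustering association profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateTableError,
    InsufficientDataError,
    UndefinedEffectError,
)


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: Sequence[str] | None = None
    col_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise DegenerateTableError("contingency table must be 2-D")
        if (self.counts < 0).any():
            raise DegenerateTableError("negative cell count")
        if self.counts.sum() <= 0:
            raise DegenerateTableError("empty contingency table")

    def drop_empty_margins(self) -> "ContingencyTable":
        keep_r = self.counts.sum(axis=1) > 0
        keep_c = self.counts.sum(axis=0) > 0
        rl = list(np.asarray(self.row_labels)[keep_r]) if self.row_labels is not None else None
        cl = list(np.asarray(self.col_labels)[keep_c]) if self.col_labels is not None else None
        return ContingencyTable(self.counts[np.ix_(keep_r, keep_c)], rl, cl)


@dataclass
class AssociationResult:
    statistic: float
    p: float
    effect_size: float
    effect_kind: str
    direction: int = 0
    q: float | None = None
    test: str | None = None

    def stars(self) -> str:
        """Significance stars following the * <0.05, ** <0.01, *** <0.001 convention."""
        p = self.q if self.q is not None else self.p
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return "ns"


def _cramers_v(chi2: float, n: float, r: int, c: int) -> float:
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def chi_square_cramers_v(table: ContingencyTable) -> AssociationResult:
    """Pearson chi-square (no continuity correction) with Cramer's V.

    V = sqrt(chi2 / (n * (min(r, c) - 1))), in [0, 1].  Empty margins are
    dropped first; a table smaller than 2x2 afterwards is degenerate.
    """
    t = table.drop_empty_margins()
    r, c = t.counts.shape
    if r < 2 or c < 2:
        raise DegenerateTableError(f"table is {r}x{c} after dropping empty margins")
    chi2, p, _, _ = stats.chi2_contingency(t.counts, correction=False)
    n = t.counts.sum()
    v = _cramers_v(chi2, n, r, c)
    return AssociationResult(float(chi2), float(p), v, "cramers_v", test="chi_square")


def directional_cramers_v(
    table: ContingencyTable, focal_row: int, focal_col: int
) -> AssociationResult:
    """Cramer's V signed by the focal cell's observed-vs-expected direction.

    Positive when the focal cell is over-represented relative to its expected
    count under independence, negative when under-represented, zero at equality.
    """
    res = chi_square_cramers_v(table)
    t = table.drop_empty_margins()
    expected = np.outer(t.counts.sum(axis=1), t.counts.sum(axis=0)) / t.counts.sum()
    diff = t.counts[focal_row, focal_col] - expected[focal_row, focal_col]
    sign = int(np.sign(diff))
    res.direction = sign
    res.effect_size = sign * res.effect_size if sign != 0 else 0.0
    return res


def mann_whitney_rank_biserial(x, y) -> AssociationResult:
    """Two-sided Mann-Whitney U with a rank-biserial effect size.

    The effect equals the mean of sign(x_i - y_j) over all pairs: +1 when
    every x exceeds every y, 0 under exchangeability.  Exact enumeration is
    used automatically for small tie-free samples (n1*n2 <= 10 000).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("a group is empty after missing-data exclusion")
    n1, n2 = len(x), len(y)
    ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (n1 * n2 <= 10_000 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    effect = 2.0 * u1 / (n1 * n2) - 1.0  # == mean pairwise sign
    return AssociationResult(
        u1, float(res.pvalue), effect, "rank_biserial",
        direction=int(np.sign(effect)), test=f"mann_whitney_{method}",
    )


def cohens_d(x, y) -> AssociationResult:
    """Two-sample pooled t-test p with pooled-SD Cohen's d ((n-1) denominators)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("need >= 2 values per group for Cohen's d")
    n1, n2 = len(x), len(y)
    pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    if pooled == 0:
        raise UndefinedEffectError("zero pooled standard deviation")
    d = float((x.mean() - y.mean()) / pooled)
    t, p = stats.ttest_ind(x, y)
    return AssociationResult(float(t), float(p), d, "cohens_d",
                             direction=int(np.sign(d)), test="t_test")


def compare_groups(x, y, gate_alpha: float = 0.05) -> AssociationResult:
    """Choose t-test vs Mann-Whitney from normality and homoscedasticity.

    Gate: Shapiro-Wilk per group and Levene's test, each at ``gate_alpha``;
    all three passing selects the t-test / Cohen's d route, otherwise the
    Mann-Whitney / rank-biserial route.  The chosen test is recorded on the
    result so decisions stay auditable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 3 or len(y) < 3:
        return mann_whitney_rank_biserial(x, y)
    normal = all(stats.shapiro(g).pvalue > gate_alpha for g in (x, y) if len(np.unique(g)) > 1)
    homosc = stats.levene(x, y).pvalue > gate_alpha
    if normal and homosc:
        try:
            return cohens_d(x, y)
        except UndefinedEffectError:
            pass
    return mann_whitney_rank_biserial(x, y)


def kruskal_epsilon_squared(groups: Sequence[np.ndarray]) -> AssociationResult:
    """Kruskal-Wallis H with epsilon-squared effect size in [0, 1]."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise InsufficientDataError("Kruskal-Wallis needs >= 2 non-empty groups")
    n = sum(len(g) for g in groups)
    h, p = stats.kruskal(*groups)
    eps2 = float(h * (n + 1) / (n**2 - 1)) if n > 1 else np.nan
    return AssociationResult(float(h), float(p), float(np.clip(eps2, 0.0, 1.0)),
                             "epsilon_squared", test="kruskal_wallis")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries are excluded from the family and restored as NaN; adjusted
    values are monotone in the sorted order and capped at 1.  Applying the
    adjustment twice is idempotent.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out
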