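"""Sensory check-all-that-apply pipeline: Jaccard distances over the binary
descriptor matrix, principal-coordinates ordination, PERMANOVA against
categorical metadata, Mantel tests against numeric metadata, and extraction of
the descriptors most correlated with the leading coordinates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedCorrelationError

logger = logging.getLogger(__name__)


@dataclass
class CataMatrix:
    """Samples x descriptors binary matrix with a descriptor -> category map."""

    data: pd.DataFrame
    category_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        ok = np.isin(vals[~pd.isna(vals)], [0, 1, 0.0, 1.0, True, False])
        if not ok.all():
            raise ValueError("CATA matrix entries must be binary")
        unmapped = [d for d in self.data.columns if self.category_map and d not in self.category_map]
        if unmapped:
            raise ValueError(f"descriptors without category: {unmapped[:5]}")

    @property
    def samples(self) -> list:
        return list(self.data.index)


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        assert v.ndim == 2 and v.shape[0] == v.shape[1]
        assert np.allclose(v, v.T, atol=1e-12), "distance matrix must be symmetric"
        assert np.allclose(np.diag(v), 0.0), "diagonal must be zero"
        self.values = v

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), 1)
        return self.values[iu]


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # n x k, columns PC1..PCk
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only
    negative_eigenvalue_report: dict


def jaccard_matrix(cata: CataMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances d = 1 - |i AND j| / |i OR j|.

    A pair of all-zero rows has an undefined Jaccard ratio; by convention the
    distance is 0 (identical emptiness) and the event is logged.
    """
    X = cata.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("CATA matrix contains missing entries; drop incomplete samples first")
    n = X.shape[0]
    if n < 2:
        raise InsufficientDataError("need >= 2 samples for a distance matrix")
    inter = X @ X.T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - inter / union
    empty_pairs = union == 0
    if empty_pairs.sum() > n:  # more than the diagonal
        logger.info("all-zero descriptor pairs found; distance set to 0 by convention")
    d[empty_pairs] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, cata.samples)


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Metric principal coordinates via Gower double-centring.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues; the proportion explained uses the positive-eigenvalue sum as
    denominator.  Negative eigenvalues are reported, not corrected.
    """
    n = len(dist.ids)
    if n < 3:
        raise InsufficientDataError("PCoA needs >= 3 samples")
    d2 = dist.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    prop = eigvals[pos] / eigvals[pos].sum()
    neg = eigvals[eigvals < -tol]
    report = {
        "n_negative": int(len(neg)),
        "most_negative": float(neg.min()) if len(neg) else 0.0,
        "negative_sum": float(neg.sum()) if len(neg) else 0.0,
    }
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        pd.DataFrame(coords, index=dist.ids, columns=cols), eigvals, prop, report
    )


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group codes."""
    n = len(codes)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    f = (ss_between / df_between) / (ss_within / df_within) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else np.nan
    return f, r2


def permanova(
    dist: DistanceMatrix,
    grouping: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    min_level_size: int = 3,
):
    """One-way PERMANOVA with a permutation null.

    Levels with fewer than ``min_level_size`` samples are dropped first; with
    fewer than two usable levels the test is skipped (returns None) so batch
    runs over many variables keep going.  p uses the add-one rule
    (1 + #{F_perm >= F_obs}) / (1 + n_perm); ``n_perm="exact"`` enumerates all
    label permutations instead.
    """
    grouping = grouping.reindex(dist.ids)
    mask = grouping.notna().to_numpy()
    labels = grouping[mask].astype(str)
    counts = labels.value_counts()
    keep_levels = counts[counts >= min_level_size].index
    lvl_mask = labels.isin(keep_levels).to_numpy()
    idx = np.flatnonzero(mask)[lvl_mask]
    labels = labels[lvl_mask]
    if labels.nunique() < 2:
        logger.warning("permanova: <2 usable levels after filtering; skipped")
        return None
    d2 = dist.values[np.ix_(idx, idx)] ** 2
    codes = pd.Categorical(labels).codes.astype(int)
    n_groups = int(codes.max()) + 1
    f_obs, r2 = _permanova_f(d2, codes, n_groups)

    if n_perm == "exact":
        perms = list(itertools.permutations(codes))
        f_perm = np.array([_permanova_f(d2, np.array(p), n_groups)[0] for p in perms])
        p = float((f_perm >= f_obs - 1e-12).sum() / len(perms))
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_perm)):
            perm = rng.permutation(codes)
            if _permanova_f(d2, perm, n_groups)[0] >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + int(n_perm))
    return float(f_obs), float(r2), float(p)


def mantel(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same samples.

    ``method`` is "pearson" or "spearman".  The permutation p (two-sided on
    |r|) co-permutes rows and columns of the second matrix; ``n_perm="exact"``
    enumerates all n! orderings.
    """
    if list(dist_a.ids) != list(dist_b.ids):
        common = [i for i in dist_a.ids if i in set(dist_b.ids)]
        if len(common) < 3:
            raise InsufficientDataError("fewer than 3 shared samples")
        ia = [dist_a.ids.index(i) for i in common]
        ib = [dist_b.ids.index(i) for i in common]
        dist_a = DistanceMatrix(dist_a.values[np.ix_(ia, ia)], common)
        dist_b = DistanceMatrix(dist_b.values[np.ix_(ib, ib)], common)
    n = len(dist_a.ids)
    va = dist_a.condensed()
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")

    def _r(bmat: np.ndarray) -> float:
        vb = bmat[np.triu_indices(n, 1)]
        return float(corr(va, vb)[0])

    if np.ptp(va) == 0 or np.ptp(dist_b.condensed()) == 0:
        raise UndefinedCorrelationError("zero variance in off-diagonal distances")
    r_obs = _r(dist_b.values)

    if n_perm == "exact":
        count = total = 0
        for perm in itertools.permutations(range(n)):
            rp = _r(dist_b.values[np.ix_(perm, perm)])
            total += 1
            if abs(rp) >= abs(r_obs) - 1e-12:
                count += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_perm)):
            perm = rng.permutation(n)
            if abs(_r(dist_b.values[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12:
                count += 1
        p = (1 + count) / (1 + int(n_perm))
    return float(r_obs), float(p)


def numeric_predictor_distance(values: pd.Series) -> DistanceMatrix:
    """Euclidean distances of a z-scored numeric predictor (for Mantel tests).

    Samples with missing values are dropped first (dynamic exclusion).
    """
    v = pd.to_numeric(values, errors="coerce").dropna()
    if v.std(ddof=0) == 0:
        raise UndefinedCorrelationError(f"predictor {values.name!r} has zero variance")
    z = ((v - v.mean()) / v.std(ddof=0)).to_numpy()
    d = np.abs(z[:, None] - z[None, :])
    return DistanceMatrix(d, list(v.index))


def top_features(
    cata: CataMatrix, ordination: OrdinationResult, k: int = 10
) -> pd.DataFrame:
    """Descriptors most correlated with the first two principal coordinates.

    Each descriptor's Pearson r against PC1 and PC2 is computed; descriptors
    are ranked by max(|r_PC1|, |r_PC2|) and the top ``k`` returned with signed
    loadings.  Constant descriptors are excluded with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    coords = ordination.coordinates
    axes = [c for c in ("PC1", "PC2") if c in coords.columns]
    X = cata.data.loc[coords.index]
    rows = []
    for desc in X.columns:
        col = X[desc].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            logger.warning("descriptor %r constant; excluded from feature ranking", desc)
            continue
        rs = {ax: float(stats.pearsonr(col, coords[ax].to_numpy())[0]) for ax in axes}
        rows.append({"descriptor": desc, **{f"r_{ax}": rs[ax] for ax in axes},
                     "max_abs_r": max(abs(v) for v in rs.values())})
    ranked = pd.DataFrame(rows).sort_values(
        ["max_abs_r", "descriptor"], ascending=[False, True]
    ).reset_index(drop=True)
    return ranked.head(k)
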