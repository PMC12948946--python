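"""Mixed-type association matrix and representative-variable selection.

Numeric pairs use max(|Pearson|, |Spearman|, centred cosine); categorical
pairs use Cramer's V; mixed pairs use Kruskal-Wallis epsilon-squared.  The
matrix is clustered (average linkage on 1 - association) and one
representative per cluster is kept, with every exclusion logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DegenerateTableError, InsufficientDataError
from .pairwise_stats import (
    ContingencyTable,
    bh_fdr,
    chi_square_cramers_v,
    kruskal_epsilon_squared,
)

logger = logging.getLogger(__name__)


@dataclass
class AssociationMatrix:
    variables: list[str]
    types: dict[str, str]  # variable -> "numeric" | "categorical"
    values: pd.DataFrame  # association strengths in [0, 1]
    p: pd.DataFrame
    q: pd.DataFrame
    method: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        assert np.allclose(np.diag(v), 1.0), "diagonal must be 1"
        assert np.allclose(v, v.T, equal_nan=True, atol=1e-12), "matrix must be symmetric"


def _centred_cosine(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(abs(a @ b) / (na * nb))


def _numeric_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float, str]:
    pr, pp = stats.pearsonr(a, b)
    sr, sp = stats.spearmanr(a, b)
    cos = _centred_cosine(a, b)
    cands = {"pearson": abs(pr), "spearman": abs(sr), "cosine": cos}
    best = max(cands, key=lambda k: (-1 if np.isnan(cands[k]) else cands[k]))
    return cands[best], float(min(pp, sp)), best


def _categorical_pair(a: pd.Series, b: pd.Series) -> tuple[float, float, str]:
    tab = pd.crosstab(a.astype(str), b.astype(str)).to_numpy(dtype=float)
    res = chi_square_cramers_v(ContingencyTable(tab))
    return res.effect_size, res.p, "cramers_v"


def _mixed_pair(num: np.ndarray, cat: pd.Series) -> tuple[float, float, str]:
    groups = [num[(cat.astype(str) == lv).to_numpy()] for lv in cat.astype(str).unique()]
    res = kruskal_epsilon_squared(groups)
    return res.effect_size, res.p, "kruskal_epsilon_squared"


def association_matrix(
    table: pd.DataFrame, variable_spec: Mapping[str, str], min_complete: int = 3
) -> AssociationMatrix:
    """Pairwise mixed-type associations on per-pair complete cases.

    ``variable_spec`` maps each variable to ``"numeric"`` or ``"categorical"``.
    Constant variables get missing cells with a warning; p-values are BH-FDR
    corrected across the upper triangle.
    """
    variables = list(variable_spec)
    if len(variables) < 2:
        raise InsufficientDataError("need at least two variables")
    k = len(variables)
    vals = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    meth = np.full((k, k), None, dtype=object)
    np.fill_diagonal(vals, 1.0)
    np.fill_diagonal(pmat, 0.0)

    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = variables[i], variables[j]
            sub = table[[vi, vj]].dropna()
            if len(sub) < min_complete:
                logger.warning("pair (%s, %s): <%d complete cases", vi, vj, min_complete)
                continue
            ti, tj = variable_spec[vi], variable_spec[vj]
            try:
                if ti == "numeric" and tj == "numeric":
                    a = sub[vi].to_numpy(dtype=float)
                    b = sub[vj].to_numpy(dtype=float)
                    if np.ptp(a) == 0 or np.ptp(b) == 0:
                        raise InsufficientDataError("constant variable")
                    v, p, m = _numeric_pair(a, b)
                elif ti == "categorical" and tj == "categorical":
                    v, p, m = _categorical_pair(sub[vi], sub[vj])
                else:
                    num_col, cat_col = (vi, vj) if ti == "numeric" else (vj, vi)
                    v, p, m = _mixed_pair(sub[num_col].to_numpy(dtype=float), sub[cat_col])
            except (DegenerateTableError, InsufficientDataError, ValueError) as exc:
                logger.warning("pair (%s, %s) not testable: %s", vi, vj, exc)
                continue
            vals[i, j] = vals[j, i] = float(np.clip(v, 0.0, 1.0))
            pmat[i, j] = pmat[j, i] = p
            meth[i, j] = meth[j, i] = m

    iu = np.triu_indices(k, 1)
    qflat = bh_fdr(pmat[iu])
    qmat = np.full((k, k), np.nan)
    qmat[iu] = qflat
    qmat.T[iu] = qflat
    np.fill_diagonal(qmat, 0.0)
    as_df = lambda m: pd.DataFrame(m, index=variables, columns=variables)
    return AssociationMatrix(
        variables, dict(variable_spec), as_df(vals), as_df(pmat), as_df(qmat), as_df(meth)
    )


def select_representatives(
    matrix: AssociationMatrix, threshold: float = 0.7
) -> tuple[list[str], dict]:
    """Keep one representative per collinear cluster of variables.

    Variables are clustered by average linkage on distance 1 - association
    (missing associations treated as 0, i.e. distance 1) and the tree is cut
    so variables closer than ``1 - threshold`` merge — raising the association
    threshold therefore never decreases the number of kept variables.  The
    representative is the member with the highest mean association to its
    cluster, ties broken lexicographically.  Returns (kept, decision_log).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    vars_ = matrix.variables
    assoc = matrix.values.to_numpy(dtype=float).copy()
    assoc = np.where(np.isnan(assoc), 0.0, assoc)
    np.fill_diagonal(assoc, 1.0)
    dist = 1.0 - assoc
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    if len(vars_) == 1:
        return list(vars_), {"clusters": {vars_[0]: [vars_[0]]}}
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=1.0 - threshold, criterion="distance")
    kept: list[str] = []
    log: dict = {"threshold": threshold, "clusters": {}}
    for cl in sorted(set(labels)):
        members = sorted(v for v, l in zip(vars_, labels) if l == cl)
        if len(members) == 1:
            rep = members[0]
        else:
            idx = [vars_.index(m) for m in members]
            sub = assoc[np.ix_(idx, idx)]
            mean_assoc = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
            top = mean_assoc.max()
            # lexicographic tie-break among maxima
            rep = min(m for m, s in zip(members, mean_assoc) if s >= top - 1e-12)
        kept.append(rep)
        log["clusters"][rep] = members
        for m in members:
            if m != rep:
                logger.info("excluding %r as collinear with representative %r", m, rep)
    kept.sort()
    log["kept"] = kept
    return kept, log
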