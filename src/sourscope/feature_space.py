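"""PCA of non-collinear numeric metadata with group confidence ellipses.

Two study variants are shipped: a "geographic" space (feeding parameters,
home results, TTA, latitude; substrate excluded) and a "substrate" space
(feeding parameters, home results, TTA, flour proportions; geography
excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

FEEDING_VARIABLES = [
    "backslop_frequency", "ferment_temp_C", "storage_temp_C",
    "ferment_time_h", "sourdough_age_y", "dough_yield",
]
HOME_RESULT_VARIABLES = ["ph_home", "ph_bread_home", "bread_density"]

VARIANTS = {
    "geographic": FEEDING_VARIABLES + HOME_RESULT_VARIABLES + ["tta", "latitude"],
    "substrate": FEEDING_VARIABLES + HOME_RESULT_VARIABLES + ["tta"]
    + ["flour_prop_wheat", "flour_prop_rye", "flour_prop_spelt"],
}


@dataclass
class PcaResult:
    scores: pd.DataFrame  # n x k, columns PC1..PCk
    loadings: pd.DataFrame  # variables x k
    explained_variance_ratio: np.ndarray
    dropped_samples: list


@dataclass
class EllipseSpec:
    group: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float  # radians, leading eigenvector vs x-axis
    level: float
    n_group: int

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


def pca(table: pd.DataFrame, variables: Sequence[str], n_components: int | None = None) -> PcaResult:
    """Standardised PCA over the selected (pre-screened) variables.

    Samples with any missing value among ``variables`` are excluded and
    reported.  Each variable is z-scored, so the decomposition is of the
    correlation structure.  A deterministic sign convention is applied: the
    largest-|loading| entry of every component is positive.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise KeyError(f"variables not in table: {missing}")
    sub = table[list(variables)].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    dropped = [i for i in sub.index if i not in complete.index]
    if len(complete) < 3:
        raise ValueError("fewer than 3 complete samples")
    for v in variables:
        if complete[v].std(ddof=0) == 0:
            raise ValueError(f"variable {v!r} is constant on the complete cases")
    Z = StandardScaler().fit_transform(complete.to_numpy(dtype=float))
    k = n_components or min(Z.shape)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(Z)
    loadings = model.components_.T  # variables x k
    for j in range(loadings.shape[1]):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PcaResult(
        pd.DataFrame(scores, index=complete.index, columns=cols),
        pd.DataFrame(loadings, index=list(variables), columns=cols),
        model.explained_variance_ratio_,
        dropped,
    )


def confidence_ellipse(
    scores_2d: pd.DataFrame,
    groups: pd.Series,
    level: float = 0.95,
    min_group_size: int = 5,
) -> list[EllipseSpec]:
    """Per-group data ellipses at a chi-square(2) confidence level.

    The ellipse comes from the group's 2x2 score covariance: semi-axes are
    sqrt(eigenvalue x chi2_2.ppf(level)) and the angle is that of the leading
    eigenvector.  Groups smaller than ``min_group_size`` are dropped (logged);
    groups with a singular covariance are skipped with a warning.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    groups = groups.reindex(scores_2d.index)
    out: list[EllipseSpec] = []
    quantile = stats.chi2.ppf(level, df=2)
    for g, idx in groups.dropna().groupby(groups).groups.items():
        pts = scores_2d.loc[idx].to_numpy(dtype=float)[:, :2]
        if len(pts) < min_group_size:
            logger.info("group %r has %d < %d samples; ellipse skipped", g, len(pts), min_group_size)
            continue
        cov = np.cov(pts, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        if eigvals.min() <= 1e-12:
            logger.warning("group %r has singular covariance; ellipse skipped", g)
            continue
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        semi = tuple(float(np.sqrt(ev * quantile)) for ev in eigvals)
        angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
        out.append(EllipseSpec(str(g), (float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                               semi, angle, level, int(len(pts))))
    return out


def variant_variables(variant: str, table: pd.DataFrame | None = None) -> list[str]:
    """Variable list for a shipped PCA variant, limited to available columns."""
    if variant not in VARIANTS:
        raise KeyError(f"unknown PCA variant {variant!r}; options: {sorted(VARIANTS)}")
    cols = VARIANTS[variant]
    if table is not None:
        cols = [c for c in cols if c in table.columns]
    return list(cols)
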