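"""Fold-enrichment scoring of features across cluster partitions.

Categorical scores are observed-over-expected share ratios
(count-in-cluster / cluster-size) / (category-total / overall-total) with a
2x2 chi-square per (category, cluster) pair; numeric scores are
epsilon-guarded mean ratios, log2-normalised, with Mann-Whitney cluster-vs-rest
p-values.  BH-FDR is applied within one partition analysis, and significant
features are flagged PE/NE and U/M.  Includes the inclusive European
bounding-box sample filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import InsufficientDataError
from .pairwise_stats import (
    ContingencyTable,
    bh_fdr,
    directional_cramers_v,
    mann_whitney_rank_biserial,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeoBounds:
    lon_min: float = -50.0
    lon_max: float = 70.0
    lat_min: float = 0.0
    lat_max: float = 70.0


@dataclass
class EnrichmentConfig:
    epsilon: float = 1e-4
    alpha: float = 0.05
    log2_numeric: bool = True
    geo_bounds: GeoBounds = field(default_factory=GeoBounds)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ClusterPartition:
    """Assignment of samples to mutually exclusive clusters of one variable."""

    variable: str
    assignment: pd.Series  # index: sample identifiers, values: cluster labels
    min_cluster_size: int = 1

    def clusters(self) -> list[str]:
        counts = self.assignment.dropna().value_counts()
        kept = counts[counts >= self.min_cluster_size]
        dropped = set(counts.index) - set(kept.index)
        if dropped:
            logger.warning("partition %s: dropping small clusters %s", self.variable, sorted(dropped))
        return sorted(kept.index.astype(str))


@dataclass
class EnrichmentRecord:
    feature: str
    cluster: str
    score: float
    log2_score: float
    p: float
    q: float | None = None
    effect_size: float | None = None  # Cramer's V, categorical only
    flag_direction: str | None = None  # PE / NE
    flag_multiplicity: str | None = None  # U / M
    kind: str = "categorical"


def geo_filter(
    table: pd.DataFrame, bounds: GeoBounds = GeoBounds(),
    lat_col: str = "latitude", lon_col: str = "longitude",
) -> pd.DataFrame:
    """Retain samples inside the (inclusive) geographic bounding box.

    Rows with missing coordinates are excluded with a warning.
    """
    lat = pd.to_numeric(table[lat_col], errors="coerce")
    lon = pd.to_numeric(table[lon_col], errors="coerce")
    missing = lat.isna() | lon.isna()
    if missing.any():
        logger.warning("geo_filter: %d samples with missing coordinates excluded", missing.sum())
    keep = (
        ~missing
        & lon.between(bounds.lon_min, bounds.lon_max)
        & lat.between(bounds.lat_min, bounds.lat_max)
    )
    return table[keep].copy()


def _assign_direction(rec: EnrichmentRecord) -> EnrichmentRecord:
    if rec.score > 1:
        rec.flag_direction = "PE"
    elif rec.score < 1:
        rec.flag_direction = "NE"
    return rec


def category_enrichment(
    labels: pd.Series,
    partition: ClusterPartition,
    config: EnrichmentConfig = EnrichmentConfig(),
    feature_prefix: str | None = None,
) -> list[EnrichmentRecord]:
    """Score every (category level, cluster) pair of one categorical variable.

    score = (count_in_cluster / cluster_total) / (category_total / overall_total).
    The per-pair p-value comes from the 2x2 collapse (category vs rest x
    cluster vs rest) without continuity correction; Cramer's V of the same 2x2
    is attached.  q-values are BH-FDR over all pairs produced by this call.
    """
    prefix = feature_prefix if feature_prefix is not None else (labels.name or "feature")
    aligned = pd.DataFrame({"label": labels, "cluster": partition.assignment}).dropna()
    clusters = [c for c in partition.clusters() if c in set(aligned["cluster"].astype(str))]
    levels = sorted(aligned["label"].astype(str).unique())
    if len(clusters) < 2 or len(levels) < 2:
        raise InsufficientDataError("need >= 2 clusters and >= 2 category levels")
    total = len(aligned)
    records: list[EnrichmentRecord] = []
    for level in levels:
        in_level = (aligned["label"].astype(str) == level).to_numpy()
        k_total = int(in_level.sum())
        if k_total == 0:  # guarded; unreachable after binning
            continue
        for cl in clusters:
            in_cl = (aligned["cluster"].astype(str) == cl).to_numpy()
            n_c = int(in_cl.sum())
            if n_c == 0:
                logger.warning("empty cluster %r excluded", cl)
                continue
            k_c = int((in_level & in_cl).sum())
            score = (k_c / n_c) / (k_total / total)
            table22 = np.array([
                [k_c, n_c - k_c],
                [k_total - k_c, (total - n_c) - (k_total - k_c)],
            ], dtype=float)
            try:
                assoc = directional_cramers_v(ContingencyTable(table22), 0, 0)
                p, v = assoc.p, assoc.effect_size
            except Exception:
                p, v = np.nan, np.nan
            guarded = (k_c / n_c + config.epsilon) / (k_total / total + config.epsilon)
            rec = EnrichmentRecord(
                feature=f"{prefix}={level}", cluster=cl, score=score,
                log2_score=float(np.log2(guarded)), p=float(p),
                effect_size=v, kind="categorical",
            )
            records.append(_assign_direction(rec))
    _apply_fdr(records)
    return flag_multiplicity(records, alpha=config.alpha)


def numeric_enrichment(
    values: pd.Series,
    partition: ClusterPartition,
    config: EnrichmentConfig = EnrichmentConfig(),
    feature_name: str | None = None,
) -> list[EnrichmentRecord]:
    """Score a numeric feature in every cluster against the overall mean.

    score = (mean_in_cluster + eps) / (mean_overall + eps); log2_score is its
    log2.  The p-value is a two-sided Mann-Whitney of cluster values against
    all other clusters.  Variables with negative values are shifted by their
    global minimum before scoring (logged), since a ratio of signed means is
    not interpretable.
    """
    name = feature_name if feature_name is not None else (values.name or "feature")
    aligned = pd.DataFrame({"value": pd.to_numeric(values, errors="coerce"),
                            "cluster": partition.assignment}).dropna()
    clusters = [c for c in partition.clusters() if c in set(aligned["cluster"].astype(str))]
    if len(clusters) < 2:
        raise InsufficientDataError("need >= 2 clusters with non-missing values")
    vals = aligned["value"].to_numpy(dtype=float)
    if vals.min() < 0:
        logger.info("numeric feature %r has negative values; shifting by %g", name, vals.min())
        vals = vals - vals.min()
    overall_mean = vals.mean()
    records: list[EnrichmentRecord] = []
    for cl in clusters:
        in_cl = (aligned["cluster"].astype(str) == cl).to_numpy()
        if in_cl.sum() == 0 or (~in_cl).sum() == 0:
            logger.warning("cluster %r skipped (no usable values)", cl)
            continue
        score = (vals[in_cl].mean() + config.epsilon) / (overall_mean + config.epsilon)
        try:
            p = mann_whitney_rank_biserial(vals[in_cl], vals[~in_cl]).p
        except InsufficientDataError:
            logger.warning("cluster %r skipped (insufficient data for test)", cl)
            continue
        rec = EnrichmentRecord(
            feature=name, cluster=cl, score=float(score),
            log2_score=float(np.log2(score)), p=float(p), kind="numeric",
        )
        records.append(_assign_direction(rec))
    _apply_fdr(records)
    return flag_multiplicity(records, alpha=config.alpha)


def _apply_fdr(records: list[EnrichmentRecord]) -> None:
    q = bh_fdr([r.p for r in records])
    for rec, qv in zip(records, q):
        rec.q = float(qv) if not np.isnan(qv) else None


def flag_multiplicity(
    records: list[EnrichmentRecord], alpha: float = 0.05
) -> list[EnrichmentRecord]:
    """Flag each feature U (significant in exactly one cluster) or M (>= 2).

    Features with no significant cluster stay unflagged.  Significance means
    q < alpha within the partition family the records came from.
    """
    sig_counts: dict[str, int] = {}
    for rec in records:
        if rec.q is not None and rec.q < alpha:
            sig_counts[rec.feature] = sig_counts.get(rec.feature, 0) + 1
    for rec in records:
        n_sig = sig_counts.get(rec.feature, 0)
        rec.flag_multiplicity = None if n_sig == 0 else ("U" if n_sig == 1 else "M")
    return records


def records_to_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    """Tidy one-row-per-(feature, cluster) table of the enrichment results."""
    rows = [{
        "feature": r.feature, "cluster": r.cluster, "score": r.score,
        "log2_score": r.log2_score, "p": r.p, "q": r.q, "V": r.effect_size,
        "direction": r.flag_direction, "multiplicity": r.flag_multiplicity,
        "kind": r.kind,
    } for r in records]
    return pd.DataFrame(rows)


def directional_v_matrix(
    records: Sequence[EnrichmentRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Feature x cluster matrix of directional Cramer's V, 0 where non-significant."""
    frame = records_to_frame(records)
    frame["signed_v"] = 0.0
    sig = frame["q"].notna() & (frame["q"] < alpha) & frame["V"].notna()
    frame.loc[sig, "signed_v"] = frame.loc[sig, "V"]
    mat = frame.pivot_table(index="feature", columns="cluster", values="signed_v",
                            aggfunc="first", fill_value=0.0)
    return mat


def cluster_enrichment_profiles(
    records: Sequence[EnrichmentRecord], alpha: float = 0.05
) -> dict[str, list[str]]:
    """Order clusters and features by average-linkage clustering of V profiles.

    Distances are Euclidean over the signed-V matrix (zeros where
    non-significant).  With fewer than two clusters (or features) the identity
    ordering is returned.
    """
    mat = directional_v_matrix(records, alpha=alpha)
    out: dict[str, list[str]] = {}
    for axis, labels in (("features", list(mat.index)), ("clusters", list(mat.columns))):
        data = mat.to_numpy() if axis == "features" else mat.to_numpy().T
        if len(labels) < 2:
            out[axis] = labels
            continue
        link = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
        order = hierarchy.leaves_list(link)
        out[axis] = [labels[i] for i in order]
    return out
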