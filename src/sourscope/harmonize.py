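"""Merge and curate the three survey tables into one analysis-ready table.

Implements the linkage (5-character sample codes + person IDs), registration
back-filling of missing result variables, dough-yield derivation, flour-label
decomposition, rare-level binning, bread-density QC and lower-inclusive
numeric binning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources as _ilres
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DoughYieldError, MergeError, VocabularyError

logger = logging.getLogger(__name__)

#: result-phase fields that may be back-filled from registration when missing
BACKFILL_FIELDS = ("backslop_frequency", "ferment_time_h")

#: the five optional home experiments tracked for completion reporting
HOME_EXPERIMENT_FIELDS = ("ph_home", "ph_bread_home", "bread_density", "cata", "bread_aromas")


@lru_cache(maxsize=1)
def load_flour_vocabulary() -> dict[str, list[str]]:
    with _ilres.files("sourscope.resources").joinpath("flour_vocabulary.json").open() as fh:
        return json.load(fh)


@dataclass
class IntegratedTable:
    """One row per sourdough sample with per-field provenance and QC counters.

    ``provenance`` has the same index as ``data`` and one column per
    back-fillable field, valued in {"results", "registration_backfill", "missing"}.
    """

    data: pd.DataFrame
    provenance: pd.DataFrame
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = self.data["sample_code"]
        if codes.duplicated().any():
            raise MergeError("duplicate sample codes in integrated table")
        per_code = self.data.groupby("sample_code")["person_id"].nunique()
        if (per_code > 1).any():
            raise MergeError("a sample code maps to more than one person")


def merge_tables(
    registration: pd.DataFrame,
    results: pd.DataFrame,
    lab: pd.DataFrame,
    backfill_fields: Sequence[str] = BACKFILL_FIELDS,
) -> IntegratedTable:
    """Link the three tables on ``sample_code`` into an :class:`IntegratedTable`.

    Registration defines the sample universe (left basis).  Result-phase
    fields that are missing in ``results`` but present in registration are
    back-filled and flagged ``registration_backfill``.  Results rows whose
    code is absent from registration are quarantined (kept in ``qc``), and
    lab rows without registration are reported — neither is silently dropped.

    Raises
    ------
    MergeError
        If any input table contains a duplicated sample code.
    """
    for name, tbl in (("registration", registration), ("results", results), ("lab", lab)):
        if tbl["sample_code"].duplicated().any():
            dups = tbl.loc[tbl["sample_code"].duplicated(), "sample_code"].tolist()
            raise MergeError(f"duplicate sample_code in {name} table: {dups[:5]}")

    reg_codes = set(registration["sample_code"])
    orphan_results = results[~results["sample_code"].isin(reg_codes)]
    orphan_lab = lab[~lab["sample_code"].isin(reg_codes)]
    if len(orphan_results):
        logger.warning("%d results rows have no registration; quarantined", len(orphan_results))
    if len(orphan_lab):
        logger.warning("%d lab rows have no registration; reported", len(orphan_lab))

    res = results[results["sample_code"].isin(reg_codes)].drop(columns=["person_id"], errors="ignore")
    merged = registration.merge(res, on="sample_code", how="left", suffixes=("", "__res"))
    merged = merged.merge(
        lab[lab["sample_code"].isin(reg_codes)], on="sample_code", how="left",
        suffixes=("", "__lab"),
    )

    # back-fill: the results-phase copy wins when present, else registration
    prov = pd.DataFrame(index=merged.index)
    for fld in backfill_fields:
        res_col = f"{fld}__res"
        if res_col not in merged.columns:
            if fld in merged.columns:
                prov[fld] = np.where(merged[fld].notna(), "results", "missing")
            continue
        from_results = merged[res_col].notna()
        from_reg = ~from_results & merged[fld].notna()
        filled = merged[res_col].where(from_results, merged[fld])
        merged[fld] = filled
        merged.drop(columns=[res_col], inplace=True)
        prov[fld] = np.select(
            [from_results, from_reg], ["results", "registration_backfill"], default="missing"
        )

    qc = {
        "n_registration": int(len(registration)),
        "n_results": int(len(results)),
        "n_lab": int(len(lab)),
        "n_orphan_results": int(len(orphan_results)),
        "n_orphan_lab": int(len(orphan_lab)),
        "orphan_results": orphan_results,
        "orphan_lab": orphan_lab,
        "n_backfilled": {
            fld: int((prov[fld] == "registration_backfill").sum())
            for fld in prov.columns
        },
    }
    return IntegratedTable(merged, prov, qc)


def compute_dough_yield(flour_g, water_g):
    """Dough yield = (flour + water) / flour x 100.

    Accepts scalars or arrays.  Scalar ``flour_g <= 0`` raises
    :class:`DoughYieldError`; in arrays such entries become NaN and are
    counted in a warning, so one bad record does not abort a pipeline run.
    """
    flour = np.asarray(flour_g, dtype=float)
    water = np.asarray(water_g, dtype=float)
    if flour.ndim == 0:
        if flour <= 0:
            raise DoughYieldError(f"dough yield undefined for flour_g={float(flour)}")
        return float((flour + water) / flour * 100.0)
    bad = (flour <= 0) & ~np.isnan(flour)
    if bad.any():
        logger.warning("%d records with non-positive flour mass; dough yield set NaN", bad.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        dy = (flour + water) / flour * 100.0
    dy = np.where(flour > 0, dy, np.nan)
    return dy


def decompose_flour(label: str, grouped: bool = False) -> tuple[str, str]:
    """Split a flour label into (grain_base, milling_grade).

    ``grouped=True`` applies the chi-square grouping view in which
    semi-wholemeal is merged into wholemeal; the default view keeps them
    distinct for numeric / feature-space use.  Labels without a milling
    qualifier get grade ``unspecified``.
    """
    vocab = load_flour_vocabulary()
    grains, grades = set(vocab["grains"]), set(vocab["milling_grades"])
    lab = str(label).strip().lower()
    if lab in set(vocab.get("special", [])):
        return lab, "unspecified"
    parts = lab.split()
    if len(parts) >= 2 and parts[0] in grades:
        grade, grain = parts[0], " ".join(parts[1:])
    else:
        grade, grain = "unspecified", lab
    if grain not in grains:
        raise VocabularyError(f"unknown flour label {label!r} (grain {grain!r} not in vocabulary)")
    if grouped and grade == "semi-wholemeal":
        grade = "wholemeal"
    return grain, grade


def bin_rare_levels(column: pd.Series, threshold: float = 0.01, other: str = "Other") -> pd.Series:
    """Relabel levels at <= ``threshold`` prevalence among non-missing entries.

    The threshold is inclusive (exactly 1% is binned).  Missing entries are
    untouched and excluded from the denominator.  Never increases the number
    of distinct levels.
    """
    non_missing = column.dropna()
    if non_missing.empty:
        return column.copy()
    freqs = non_missing.value_counts() / len(non_missing)
    rare = set(freqs[freqs <= threshold].index)
    if not rare:
        return column.copy()
    out = column.copy().astype(object)
    out[column.isin(rare)] = other
    return out


def filter_bread_density(values) -> tuple[np.ndarray, dict]:
    """Drop erroneous densities (> 1 g/cm3); boundary 1.0 is retained.

    Returns the retained values and a QC dict with the exclusion count.
    """
    arr = np.asarray(values, dtype=float)
    keep = ~(arr > 1.0)  # NaNs retained here; excluded per-variable downstream
    report = {"n_in": int(arr.size), "n_excluded_gt1": int((arr > 1.0).sum())}
    return arr[keep], report


def categorize_numeric(values, bin_edges: Sequence[float]) -> pd.Categorical:
    """Bin values into lower-inclusive, upper-exclusive ordered categories.

    Values below the first edge go to an open bottom bin ``<first``; values at
    or above the last edge go to ``>=last``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 entries")
    labels = [f"<{_fmt(edges[0])}"]
    labels += [f"[{_fmt(a)},{_fmt(b)})" for a, b in zip(edges[:-1], edges[1:])]
    labels += [f">={_fmt(edges[-1])}"]
    arr = np.asarray(values, dtype=float)
    idx = np.searchsorted(edges, arr, side="right")  # lower-inclusive
    codes = np.where(np.isnan(arr), -1, idx).astype(int)
    return pd.Categorical.from_codes(codes, categories=labels, ordered=True)


def _fmt(x: float) -> str:
    return f"{x:g}"


def home_experiment_completion(
    table: pd.DataFrame, experiments: Iterable[str] = HOME_EXPERIMENT_FIELDS
) -> pd.Series:
    """Boolean per sample: all tracked home experiments completed.

    The ``cata`` experiment counts as done when any ``cata_*`` descriptor
    column is non-missing for the row.
    """
    done = pd.Series(True, index=table.index)
    for exp in experiments:
        if exp == "cata":
            cata_cols = [c for c in table.columns if c.startswith("cata_")]
            if cata_cols:
                done &= table[cata_cols].notna().any(axis=1)
            else:
                done &= False
        elif exp in table.columns:
            done &= table[exp].notna()
        else:
            done &= False
    return done


def integrate(
    registration: pd.DataFrame,
    results: pd.DataFrame,
    lab: pd.DataFrame,
    density_filter: bool = True,
) -> IntegratedTable:
    """Full harmonisation: merge, derive dough yield, decompose flour, QC density.

    Adds ``dough_yield``, ``grain_base``, ``milling_grade`` (distinct view) and
    ``milling_grade_grouped`` (semi-wholemeal folded into wholemeal).  Bread
    densities > 1 are set to missing and counted, mirroring their exclusion
    from analysis.
    """
    it = merge_tables(registration, results, lab)
    df = it.data
    if {"flour_g", "water_g"}.issubset(df.columns):
        df["dough_yield"] = compute_dough_yield(df["flour_g"].to_numpy(), df["water_g"].to_numpy())

    if "flour_type" in df.columns:
        bases, grades, grouped = [], [], []
        bad: list[str] = []
        for lab_ in df["flour_type"]:
            if pd.isna(lab_):
                bases.append(np.nan); grades.append(np.nan); grouped.append(np.nan)
                continue
            try:
                g, m = decompose_flour(lab_)
            except VocabularyError:
                bad.append(str(lab_))
                bases.append(np.nan); grades.append(np.nan); grouped.append(np.nan)
                continue
            bases.append(g)
            grades.append(m)
            grouped.append("wholemeal" if m == "semi-wholemeal" else m)
        if bad:
            logger.warning("%d flour labels outside vocabulary: %s", len(bad), sorted(set(bad))[:5])
        df["grain_base"] = bases
        df["milling_grade"] = grades
        df["milling_grade_grouped"] = grouped
        it.qc["n_unrecognised_flour"] = len(bad)

    if density_filter and "bread_density" in df.columns:
        too_dense = df["bread_density"] > 1.0
        it.qc["n_density_excluded"] = int(too_dense.sum())
        df.loc[too_dense, "bread_density"] = np.nan

    it.qc["home_experiments_complete"] = int(home_experiment_completion(df).sum())
    return it


def source_contrast_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for household-vs-bakery contrasts.

    Drops unknown sources and the (rare) industrial samples, which are
    excluded from the bakery aggregate.
    """
    keep = table["source"].isin(["household", "bakery"])
    return table[keep].copy()
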