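"""Desk-scale validation scenarios: self-contained simulation studies that
check the pipeline's statistical behaviour (calibration, recovery,
conservation) without any external data.

These are used both by the acceptance test suite and by the standalone
acceptance script, so the scenario definitions live in one place.
"""

from __future__ import annotations

import numpy as np

from .enrichment import ClusterPartition, category_enrichment, numeric_enrichment
from .harmonize import bin_rare_levels, integrate
from .synthetic_data import GeneratorConfig, PlantedEffect, generate_study

#: cluster layout for the categorical-recovery scenario: the planted country
#: is deliberately small so its positive enrichment dominates the mirrored
#: negative enrichments induced in the remaining clusters
RECOVERY_COUNTRIES = [
    ("CH", 46.8, 8.2, 0.28),
    ("FI", 61.9, 25.7, 0.28),
    ("BE", 50.5, 4.5, 0.28),
    ("DE", 51.2, 10.4, 0.16),
]

#: coarse flour profile (two grains, two milling grades, no mixtures) keeps
#: every category level common enough that small-count noise cannot produce
#: spurious extreme fold changes
RECOVERY_FLOUR_PROFILE = {
    c[0]: {
        "grain": {"wheat": 0.76, "rye": 0.24},
        "milling": {"wholemeal": 0.5, "unspecified": 0.5},
    }
    for c in RECOVERY_COUNTRIES
}


def _country_enrichment_records(reg, lab=None):
    """Category + numeric enrichment of a study's registration table by country."""
    meta = reg.set_index("sample_code")
    part = ClusterPartition("country", meta["country"])
    labels = bin_rare_levels(meta["flour_type"])
    records = category_enrichment(labels, part, feature_prefix="flour_type")
    for v in ("backslop_frequency", "ferment_temp_C"):
        records += numeric_enrichment(meta[v], part, feature_name=v)
    if lab is not None and len(lab):
        tta = lab.set_index("sample_code")["tta"].reindex(meta.index)
        records += numeric_enrichment(tta, part, feature_name="tta")
    return records


def null_calibration(
    n_replicates: int = 200, n_participants: int = 500, seed: int = 0
) -> dict:
    """No planted effects: fraction of enrichment records called at q < 0.05.

    Returns the pooled false-positive fraction over all replicates together
    with the binomial bound 0.05 + 3*SE it must stay under.
    """
    n_sig = n_records = 0
    for rep in range(n_replicates):
        cfg = GeneratorConfig(n_participants=n_participants, seed=seed + rep)
        reg, res, lab, _ = generate_study(cfg)
        for r in _country_enrichment_records(reg, lab):
            n_records += 1
            if r.q is not None and r.q < 0.05:
                n_sig += 1
    frac = n_sig / n_records
    bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_records)
    return {"fraction_q_lt_alpha": frac, "bound": float(bound), "n_records": n_records,
            "n_significant": n_sig, "pass": bool(frac <= bound)}


def recovery_config(seed: int) -> GeneratorConfig:
    """Study config planting a 4x odds enrichment of wholemeal rye in DE."""
    effect = PlantedEffect(
        "categorical_enrichment", "flour_type", "country", "DE", 4.0,
        target_level="wholemeal rye",
    )
    return GeneratorConfig(
        n_participants=1000, seed=seed, effect_registry=[effect],
        countries=RECOVERY_COUNTRIES, flour_profile_by_country=RECOVERY_FLOUR_PROFILE,
        p_mixture=0.0,
    )


def recovery_rate(n_replicates: int = 100, seed: int = 0) -> dict:
    """Fraction of replicates where the planted (feature, cluster) is the
    top-|log2 score| significant enrichment record with q < 0.05."""
    hits = 0
    for rep in range(n_replicates):
        reg, *_ = generate_study(recovery_config(seed + rep))
        meta = reg.set_index("sample_code")
        part = ClusterPartition("country", meta["country"])
        labels = bin_rare_levels(meta["flour_type"])
        records = category_enrichment(labels, part, feature_prefix="flour_type")
        significant = [r for r in records if r.q is not None and r.q < 0.05]
        if not significant:
            continue
        top = max(significant, key=lambda r: abs(r.log2_score))
        if top.feature == "flour_type=wholemeal rye" and top.cluster == "DE":
            hits += 1
    return {"rate": hits / n_replicates, "hits": hits, "n_replicates": n_replicates,
            "pass": hits / n_replicates >= 0.95}


def mean_shift_recovery_rate(
    n_replicates: int = 20, n_participants: int = 500, shift_sd: float = 1.0,
    seed: int = 0,
) -> dict:
    """Detection rate (q < 0.05) of a planted per-SD mean shift."""
    hits = 0
    for rep in range(n_replicates):
        effect = PlantedEffect("mean_shift", "tta", "country", "DE", shift_sd)
        cfg = GeneratorConfig(n_participants=n_participants, seed=seed + rep,
                              effect_registry=[effect])
        reg, res, lab, _ = generate_study(cfg)
        meta = reg.set_index("sample_code")
        part = ClusterPartition("country", meta["country"])
        tta = lab.set_index("sample_code")["tta"].reindex(meta.index)
        records = numeric_enrichment(tta, part, feature_name="tta")
        rec = next((r for r in records if r.cluster == "DE"), None)
        if rec is not None and rec.q is not None and rec.q < 0.05:
            hits += 1
    return {"rate": hits / n_replicates, "n_replicates": n_replicates,
            "pass": hits / n_replicates >= 0.9}


def ph_offset_estimate(n_participants: int = 500, seed: int = 0) -> dict:
    """Paired home-minus-lab pH mean difference recovered through the pipeline."""
    cfg = GeneratorConfig(n_participants=n_participants, seed=seed)
    reg, res, lab, _ = generate_study(cfg)
    table = integrate(reg, res, lab).data
    paired = table[["ph_home", "ph_lab"]].dropna()
    est = float((paired["ph_home"] - paired["ph_lab"]).mean())
    return {"estimate": est, "true_offset": -cfg.ph_lab_offset, "n_pairs": len(paired),
            "pass": abs(est - (-cfg.ph_lab_offset)) <= 0.03}


def conservation_check(n_participants: int = 400, seed: int = 0) -> dict:
    """Cluster-size-weighted mean of category enrichment scores must be 1."""
    cfg = GeneratorConfig(n_participants=n_participants, seed=seed)
    reg, *_ = generate_study(cfg)
    meta = reg.set_index("sample_code")
    part = ClusterPartition("country", meta["country"])
    labels = bin_rare_levels(meta["flour_type"])
    records = category_enrichment(labels, part, feature_prefix="flour_type")
    aligned = labels.dropna()
    sizes = meta.loc[aligned.index, "country"].value_counts()
    total = int(sizes.sum())
    worst = 0.0
    by_feature: dict[str, list] = {}
    for r in records:
        by_feature.setdefault(r.feature, []).append(r)
    for feature, recs in by_feature.items():
        w = np.array([sizes[r.cluster] / total for r in recs])
        s = np.array([r.score for r in recs])
        worst = max(worst, abs(float(np.sum(w * s)) - 1.0))
    return {"max_abs_deviation": worst, "n_features": len(by_feature),
            "pass": worst <= 1e-9}
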