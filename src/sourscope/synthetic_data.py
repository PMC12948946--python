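"""Synthetic citizen-science study generator with planted, recoverable effects.

Produces the three raw tables the harmonisation stage expects (registration,
results, laboratory) together with a :class:`SyntheticTruth` registry of the
effects that were planted, so statistical recovery can be asserted without any
external data.  All randomness flows from a single :func:`numpy.random.default_rng`
stream seeded from the config, which makes regenerated tables byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources as _ilres
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError

logger = logging.getLogger(__name__)

_CODE_ALPHABET = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"))

#: numeric survey fields: name -> (mean, sd, lower clip or None)
NUMERIC_FIELDS: dict[str, tuple[float, float, float | None]] = {
    "backslop_frequency": (3.0, 2.0, 0.05),
    "ferment_temp_C": (22.0, 3.0, 4.0),
    "storage_temp_C": (8.0, 5.0, -20.0),
    "ferment_time_h": (12.0, 6.0, 0.5),
    "sourdough_age_y": (4.0, 4.5, 0.02),
    "flour_g": (100.0, 30.0, 10.0),
    "n_maintained": (1.6, 0.9, 1.0),
    "tta": (12.0, 3.0, 1.0),
    "bread_density": (0.55, 0.15, 0.15),
    "ph_home": (3.9, 0.35, 2.5),
    "ph_bread_home": (5.1, 0.4, 3.0),
}

MOTIVATION_OPTIONS = {
    "taste": 0.82,
    "enjoyment": 0.72,
    "health": 0.45,
    "sustainability": 0.25,
    "tradition": 0.09,
    "cost": 0.12,
}

BENEFIT_OPTIONS = {
    "gastrointestinal": 0.55,
    "digestibility": 0.45,
    "gut health": 0.40,
    "glucose control": 0.15,
    "mineral bioavailability": 0.10,
    "fewer intolerances": 0.20,
}

SKILL_LEVELS = ["beginner", "intermediate", "advanced", "professional"]

DEFAULT_COUNTRIES = [
    ("CH", 46.8, 8.2, 0.20),
    ("FI", 61.9, 25.7, 0.15),
    ("BE", 50.5, 4.5, 0.15),
    ("IT", 42.8, 12.8, 0.12),
    ("RO", 45.9, 24.9, 0.12),
    ("DE", 51.2, 10.4, 0.26),
]

_DEFAULT_GRAIN_P = {"wheat": 0.53, "rye": 0.27, "spelt": 0.12, "barley": 0.05, "oat": 0.03}
_DEFAULT_MILLING_P = {"wholemeal": 0.40, "semi-wholemeal": 0.12, "endosperm": 0.28, "unspecified": 0.20}


@lru_cache(maxsize=1)
def load_aroma_inventory() -> dict[str, list[str]]:
    """Return the descriptor inventory as an ordered {category: [descriptor, ...]} map."""
    with _ilres.files("sourscope.resources").joinpath("aroma_inventory.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class PlantedEffect:
    """One effect deliberately built into a generated dataset.

    ``magnitude`` is on the feature's natural scale: an odds multiplier for
    ``categorical_enrichment``, a standardised (per-SD) shift for ``mean_shift``,
    a probability delta for ``aroma_association`` and a target Pearson r for
    ``correlation``.
    """

    kind: str
    target_feature: str
    cluster_variable: str
    cluster_level: str
    magnitude: float
    target_level: str | None = None  # categorical_enrichment only

    _KINDS = ("categorical_enrichment", "mean_shift", "aroma_association", "correlation")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise InvalidConfigError(f"unknown effect kind {self.kind!r}")
        if not np.isfinite(self.magnitude):
            raise InvalidConfigError("effect magnitude must be finite")


@dataclass(frozen=True)
class SyntheticTruth:
    """Registry of planted effects plus the fields generated with no effect."""

    effects: tuple[PlantedEffect, ...]
    null_features: tuple[str, ...]

    def __post_init__(self) -> None:
        targeted = {e.target_feature for e in self.effects}
        overlap = targeted & set(self.null_features)
        if overlap:
            raise InvalidConfigError(f"features both targeted and null: {sorted(overlap)}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effects": [dataclasses.asdict(e) for e in self.effects],
            "null_features": list(self.null_features),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class GeneratorConfig:
    """Validated configuration for :func:`generate_study`."""

    n_participants: int = 500
    countries: Sequence[tuple[str, float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_COUNTRIES)
    )
    p_bakery: float = 0.125
    p_industrial: float = 0.001
    p_unknown_source: float = 0.004
    flour_profile_by_country: Mapping[str, Mapping[str, Mapping[str, float]]] | None = None
    effect_registry: Sequence[PlantedEffect] = field(default_factory=list)
    missingness: Mapping[str, float] = field(default_factory=dict)
    ph_lab_offset: float = -0.73
    ph_lab_noise_sd: float = 0.05
    ph_strip_step: float = 0.25
    n_aroma_descriptors: int = 56
    n_aroma_categories: int = 13
    aroma_prevalence_range: tuple[float, float] = (0.05, 0.50)
    p_extra_sample: float = 0.08
    p_mixture: float = 0.10
    p_results: float = 1.0
    p_lab: float = 1.0
    p_density_error: float = 0.02
    p_organic: float = 0.60
    p_healthier: float = 0.84
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_participants) <= 0:
            raise InvalidConfigError("n_participants must be positive")
        self.n_participants = int(self.n_participants)
        weights = np.array([c[3] for c in self.countries], dtype=float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise InvalidConfigError(f"country weights sum to {weights.sum()!r}, expected 1")
        for name in (
            "p_bakery", "p_industrial", "p_unknown_source", "p_extra_sample",
            "p_mixture", "p_results", "p_lab", "p_density_error", "p_organic",
            "p_healthier",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        for fname, p in self.missingness.items():
            if not 0.0 <= p < 1.0:
                raise InvalidConfigError(f"missingness[{fname!r}]={p} outside [0, 1)")
        if self.n_aroma_categories > self.n_aroma_descriptors:
            raise InvalidConfigError("more aroma categories than descriptors")
        lo, hi = self.aroma_prevalence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidConfigError("aroma_prevalence_range must satisfy 0 <= lo <= hi <= 1")
        self._validate_effects()

    def _validate_effects(self) -> None:
        known = set(NUMERIC_FIELDS) | {
            "flour_type", "grain_base", "milling_grade", "organic_flour",
            "source", "country", "skill", "healthier_than_yeast", "water_g",
            "dough_yield", "ph_lab",
        } | set(MOTIVATION_OPTIONS) | set(BENEFIT_OPTIONS)
        descriptors = set(self.aroma_descriptors())
        for eff in self.effect_registry:
            if eff.kind == "aroma_association":
                if eff.target_feature not in descriptors:
                    raise InvalidConfigError(
                        f"aroma effect targets unknown descriptor {eff.target_feature!r}"
                    )
            elif eff.target_feature not in known:
                raise InvalidConfigError(f"effect targets unknown field {eff.target_feature!r}")
            if eff.cluster_variable not in known:
                raise InvalidConfigError(
                    f"effect clusters on unknown field {eff.cluster_variable!r}"
                )
            if eff.kind == "categorical_enrichment" and eff.target_level is None:
                raise InvalidConfigError("categorical_enrichment requires target_level")

    # -- descriptor inventory ------------------------------------------------
    def aroma_descriptors(self) -> list[str]:
        """Descriptor names, truncated/padded to ``n_aroma_descriptors``."""
        inventory = load_aroma_inventory()
        names = [d for cat in inventory.values() for d in cat]
        if self.n_aroma_descriptors <= len(names):
            return names[: self.n_aroma_descriptors]
        extra = [f"descriptor_{i:02d}" for i in range(len(names), self.n_aroma_descriptors)]
        return names + extra

    def aroma_category_map(self) -> dict[str, str]:
        """Map each generated descriptor to a category.

        Uses the shipped inventory where descriptor names come from it;
        any padded descriptors fall into the last category (remainder rule).
        """
        inventory = load_aroma_inventory()
        lookup = {d: cat for cat, ds in inventory.items() for d in ds}
        cats = list(inventory)[: self.n_aroma_categories]
        last = cats[-1]
        out: dict[str, str] = {}
        for d in self.aroma_descriptors():
            cat = lookup.get(d, last)
            out[d] = cat if cat in cats else last
        return out

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None) -> "GeneratorConfig":
        """Load a config from YAML/JSON; ``seed`` overrides the file value."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        effects = [PlantedEffect(**e) for e in raw.pop("effect_registry", [])]
        raw["countries"] = [tuple(c) for c in raw.get("countries", DEFAULT_COUNTRIES)]
        if "aroma_prevalence_range" in raw:
            raw["aroma_prevalence_range"] = tuple(raw["aroma_prevalence_range"])
        cfg = cls(effect_registry=effects, **raw)
        if seed is not None:
            cfg.seed = seed
        return cfg


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _draw_codes(n: int, rng: np.random.Generator) -> np.ndarray:
    """n unique 5-character codes over [A-Z0-9]; rejection-sampled, collision-free."""
    seen: set[int] = set()
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        cand = rng.integers(0, 36**5, size=n - filled)
        for c in cand:
            if int(c) not in seen:
                seen.add(int(c))
                out[filled] = c
                filled += 1
    codes = []
    for v in out:
        chars = []
        for _ in range(5):
            v, r = divmod(int(v), 36)
            chars.append(_CODE_ALPHABET[r])
        codes.append("".join(reversed(chars)))
    return np.array(codes)


def _boosted_probs(base: np.ndarray, idx: int, odds_multiplier: float) -> np.ndarray:
    """Apply an odds multiplier to one level of a probability vector."""
    p = base[idx]
    p_new = odds_multiplier * p / (1.0 - p + odds_multiplier * p)
    out = base.copy()
    rest = 1.0 - p
    if rest > 0:
        out *= (1.0 - p_new) / rest
    out[idx] = p_new
    return out / out.sum()


def _quantise(values: np.ndarray, step: float) -> np.ndarray:
    return np.round(values / step) * step


def _flour_label_distribution(
    grain_p: Mapping[str, float], milling_p: Mapping[str, float], p_mixture: float
) -> tuple[list[str], np.ndarray]:
    """Joint distribution over flour labels; semi-wholemeal mass restricted to wheat."""
    labels, probs = [], []
    for grain, gp in grain_p.items():
        mp = dict(milling_p)
        if grain != "wheat" and "semi-wholemeal" in mp:
            mp["wholemeal"] = mp.get("wholemeal", 0.0) + mp.pop("semi-wholemeal")
        tot = sum(mp.values())
        for grade, q in mp.items():
            label = grain if grade == "unspecified" else f"{grade} {grain}"
            labels.append(label)
            probs.append(gp * q / tot)
    arr = np.array(probs)
    arr = arr / arr.sum() * (1.0 - p_mixture)
    labels.append("mixed")
    arr = np.append(arr, p_mixture)
    return labels, arr


def sample_cata(
    row_attrs: Mapping[str, object],
    base_prevalence: Mapping[str, float],
    effect_registry: Sequence[PlantedEffect],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one binary CATA descriptor vector for a sample.

    ``row_attrs`` supplies the sample's cluster-variable values so
    ``aroma_association`` effects can shift the Bernoulli probability of their
    target descriptor; probabilities are clipped to [0, 1] with a log entry
    when a shift leaves the unit interval.
    """
    descriptors = list(base_prevalence)
    p = np.array([base_prevalence[d] for d in descriptors], dtype=float)
    for eff in effect_registry:
        if eff.kind != "aroma_association":
            continue
        if str(row_attrs.get(eff.cluster_variable)) != str(eff.cluster_level):
            continue
        j = descriptors.index(eff.target_feature)
        shifted = p[j] + eff.magnitude
        if shifted < 0.0 or shifted > 1.0:
            logger.info(
                "aroma probability for %r shifted to %.3f; clipping", eff.target_feature, shifted
            )
        p[j] = np.clip(shifted, 0.0, 1.0)
    return (rng.random(len(p)) < p).astype(np.int64)


def _cata_block(
    df: pd.DataFrame,
    descriptors: list[str],
    base_prev: np.ndarray,
    effects: Sequence[PlantedEffect],
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised CATA matrix draw; same model as :func:`sample_cata`."""
    n = len(df)
    P = np.tile(base_prev, (n, 1))
    for eff in effects:
        if eff.kind != "aroma_association":
            continue
        mask = df[eff.cluster_variable].astype(str).to_numpy() == str(eff.cluster_level)
        j = descriptors.index(eff.target_feature)
        shifted = P[mask, j] + eff.magnitude
        n_out = int(((shifted < 0) | (shifted > 1)).sum())
        if n_out:
            logger.info("clipping %d shifted aroma probabilities for %r", n_out, eff.target_feature)
        P[mask, j] = np.clip(shifted, 0.0, 1.0)
    return (rng.random(P.shape) < P).astype(np.int64)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_study(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (registration, results, laboratory, truth) for one synthetic study.

    The three tables share unique 5-character sample codes; person IDs carry
    1–5 samples each.  Laboratory pH equals home pH plus ``ph_lab_offset`` plus
    Gaussian noise.  Missingness is injected MCAR per field according to
    ``config.missingness``.  Identical configs (same seed) yield identical
    tables.
    """
    rng = np.random.default_rng(config.seed)

    # persons -> samples
    n_persons = config.n_participants
    extra = rng.random(n_persons) < config.p_extra_sample
    per_person = np.where(extra, rng.integers(2, 6, size=n_persons), 1)
    person_ids = np.repeat([f"P{i:05d}" for i in range(n_persons)], per_person)
    n = int(per_person.sum())
    codes = _draw_codes(n, rng)

    # geography (per person so one baker stays in one country)
    names = [c[0] for c in config.countries]
    lat0 = {c[0]: c[1] for c in config.countries}
    lon0 = {c[0]: c[2] for c in config.countries}
    weights = np.array([c[3] for c in config.countries], dtype=float)
    person_country = rng.choice(names, size=n_persons, p=weights / weights.sum())
    country = np.repeat(person_country, per_person)
    lat = np.round(np.array([lat0[c] for c in country]) + rng.normal(0, 1.2, n), 2)
    lon = np.round(np.array([lon0[c] for c in country]) + rng.normal(0, 1.8, n), 2)

    src_p = np.array([
        1.0 - config.p_bakery - config.p_industrial - config.p_unknown_source,
        config.p_bakery, config.p_industrial, config.p_unknown_source,
    ])
    source = rng.choice(["household", "bakery", "industrial", "unknown"], size=n, p=src_p)

    df = pd.DataFrame({
        "person_id": person_ids, "sample_code": codes, "country": country,
        "latitude": lat, "longitude": lon, "source": source,
    })

    # flour labels per country profile, with categorical_enrichment boosts
    profiles = config.flour_profile_by_country or {}
    flour = np.empty(n, dtype=object)
    cat_effects = [e for e in config.effect_registry if e.kind == "categorical_enrichment"]
    for ctry in names:
        prof = profiles.get(ctry, {})
        labels, probs = _flour_label_distribution(
            prof.get("grain", _DEFAULT_GRAIN_P), prof.get("milling", _DEFAULT_MILLING_P),
            config.p_mixture,
        )
        mask = df["country"].to_numpy() == ctry
        base = probs
        for eff in cat_effects:
            if eff.target_feature == "flour_type" and eff.cluster_variable == "country" \
                    and eff.cluster_level == ctry and eff.target_level in labels:
                base = _boosted_probs(base, labels.index(eff.target_level), eff.magnitude)
        flour[mask] = rng.choice(labels, size=int(mask.sum()), p=base)
    df["flour_type"] = flour

    # internal decomposition (harmonize re-derives these from the label)
    grain_base = np.empty(n, dtype=object)
    milling = np.empty(n, dtype=object)
    for i, lab_ in enumerate(flour):
        if lab_ == "mixed":
            grain_base[i], milling[i] = "mixed", "unspecified"
        else:
            parts = lab_.rsplit(" ", 1)
            if len(parts) == 2 and parts[0] in ("wholemeal", "semi-wholemeal", "endosperm"):
                milling[i], grain_base[i] = parts
            else:
                grain_base[i], milling[i] = lab_, "unspecified"
    df["grain_base"] = grain_base
    df["milling_grade"] = milling

    # flour proportions: pure -> 1.0; mixtures -> Dirichlet over two grains
    prop = {g: np.zeros(n) for g in ("wheat", "rye", "spelt")}
    other_prop = np.zeros(n)
    mix_mask = grain_base == "mixed"
    main_grains = np.array(["wheat", "rye", "spelt"])
    for i in range(n):
        if mix_mask[i]:
            pair = rng.choice(main_grains, size=2, replace=False)
            w = rng.dirichlet([2.0, 2.0])
            for g, share in zip(pair, w):
                prop[g][i] = share
        elif grain_base[i] in prop:
            prop[grain_base[i]][i] = 1.0
        else:
            other_prop[i] = 1.0
    for g in prop:
        df[f"flour_prop_{g}"] = np.round(prop[g], 4)
    df["flour_prop_other"] = np.round(other_prop, 4)

    df["organic_flour"] = np.where(rng.random(n) < config.p_organic, "yes", "no")
    df["healthier_than_yeast"] = np.where(rng.random(n) < config.p_healthier, "yes", "no")
    df["skill"] = rng.choice(SKILL_LEVELS, size=n, p=[0.25, 0.40, 0.25, 0.10])

    # numeric fields
    for name_, (mu, sd, lo) in NUMERIC_FIELDS.items():
        vals = rng.normal(mu, sd, n)
        if lo is not None:
            vals = np.clip(vals, lo, None)
        df[name_] = vals
    df["n_maintained"] = np.round(df["n_maintained"]).clip(lower=1).astype(float)
    hydration = np.clip(rng.normal(1.0, 0.3, n), 0.0, None)
    df["water_g"] = df["flour_g"] * hydration

    # deliberate density errors > 1 (exercises the QC filter downstream)
    err = rng.random(n) < config.p_density_error
    df.loc[err, "bread_density"] = rng.uniform(1.05, 1.6, int(err.sum()))

    # planted numeric effects
    for eff in config.effect_registry:
        if eff.kind == "mean_shift":
            if eff.target_feature not in df.columns:
                raise InvalidConfigError(f"mean_shift target {eff.target_feature!r} not generated")
            sd = NUMERIC_FIELDS.get(eff.target_feature, (0, df[eff.target_feature].std(), None))[1]
            mask = df[eff.cluster_variable].astype(str) == str(eff.cluster_level)
            df.loc[mask, eff.target_feature] += eff.magnitude * sd
        elif eff.kind == "correlation":
            rho = float(np.clip(eff.magnitude, -0.999, 0.999))
            drv = df[eff.cluster_variable].to_numpy(dtype=float)
            z = (drv - drv.mean()) / (drv.std() or 1.0)
            mu, sd, lo = NUMERIC_FIELDS[eff.target_feature]
            noise = rng.normal(0.0, 1.0, n)
            vals = mu + sd * (rho * z + np.sqrt(1 - rho**2) * noise)
            if lo is not None:
                vals = np.clip(vals, lo, None)
            df[eff.target_feature] = vals

    # multi-select fields as pipe-joined strings
    for col, options in (("motivations", MOTIVATION_OPTIONS), ("benefits", BENEFIT_OPTIONS)):
        picks = rng.random((n, len(options))) < np.array(list(options.values()))
        opt_names = np.array(list(options))
        df[col] = ["|".join(opt_names[row]) for row in picks]

    # pH block: strip-quantised at home, continuous in the lab
    df["ph_home"] = _quantise(df["ph_home"].to_numpy(), config.ph_strip_step)
    df["ph_bread_home"] = _quantise(df["ph_bread_home"].to_numpy(), config.ph_strip_step)
    df["ph_lab"] = (
        df["ph_home"].to_numpy() + config.ph_lab_offset + rng.normal(0, config.ph_lab_noise_sd, n)
    )

    # CATA matrix: per-descriptor base prevalence drawn once per study
    descriptors = config.aroma_descriptors()
    lo_p, hi_p = config.aroma_prevalence_range
    base_prev = rng.uniform(lo_p, hi_p, len(descriptors))
    cata = _cata_block(df, descriptors, base_prev, config.effect_registry, rng)
    cata_cols = [f"cata_{d.replace(' ', '_')}" for d in descriptors]
    cata_df = pd.DataFrame(cata, columns=cata_cols, index=df.index)

    # bread aromas: light multiselect from the same inventory
    bread_pick = rng.random((n, len(descriptors))) < base_prev * 0.6
    darr = np.array(descriptors)
    df["bread_aromas"] = ["|".join(darr[row]) for row in bread_pick]

    # results / lab membership
    has_results = rng.random(n) < config.p_results
    has_lab = has_results & (rng.random(n) < config.p_lab)

    registration = df[[
        "person_id", "sample_code", "country", "latitude", "longitude", "source",
        "flour_type", "flour_prop_wheat", "flour_prop_rye", "flour_prop_spelt",
        "flour_prop_other", "organic_flour", "flour_g", "water_g",
        "backslop_frequency", "ferment_temp_C", "storage_temp_C", "ferment_time_h",
        "sourdough_age_y", "n_maintained", "skill", "motivations", "benefits",
        "healthier_than_yeast",
    ]].copy()

    results = pd.concat(
        [
            df.loc[has_results, ["sample_code", "person_id", "ph_home", "ph_bread_home",
                                 "bread_density", "backslop_frequency", "ferment_time_h",
                                 "bread_aromas"]],
            cata_df.loc[has_results],
        ],
        axis=1,
    ).reset_index(drop=True)
    lab = df.loc[has_lab, ["sample_code", "ph_lab", "tta"]].reset_index(drop=True)

    _inject_missing(registration, config.missingness, rng)
    _inject_missing(results, config.missingness, rng, cata_cols=cata_cols)
    _inject_missing(lab, config.missingness, rng)

    targeted = {e.target_feature for e in config.effect_registry}
    null_features = tuple(
        c for c in list(NUMERIC_FIELDS) + ["flour_type", "organic_flour", "water_g"]
        if c not in targeted
    )
    truth = SyntheticTruth(tuple(config.effect_registry), null_features)
    return registration, results, lab, truth


def _inject_missing(
    table: pd.DataFrame,
    missingness: Mapping[str, float],
    rng: np.random.Generator,
    cata_cols: Sequence[str] = (),
) -> None:
    """MCAR missingness in place; the key ``cata`` blanks the whole descriptor block."""
    for col, p in missingness.items():
        if p <= 0:
            continue
        if col == "cata" and cata_cols and cata_cols[0] in table.columns:
            mask = rng.random(len(table)) < p
            table.loc[mask, list(cata_cols)] = np.nan
        elif col in table.columns:
            mask = rng.random(len(table)) < p
            table.loc[mask, col] = np.nan


def write_study(
    config: GeneratorConfig, outdir: str | Path
) -> tuple[Path, Path, Path, Path]:
    """Generate a study and write the three CSVs plus ``truth.json`` to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registration, results, lab, truth = generate_study(config)
    paths = (
        outdir / "registration.csv", outdir / "results.csv",
        outdir / "laboratory.csv", outdir / "truth.json",
    )
    registration.to_csv(paths[0], index=False)
    results.to_csv(paths[1], index=False)
    lab.to_csv(paths[2], index=False)
    truth.to_json(paths[3])
    return paths
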