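# sourscope

Analysis toolkit for citizen-science sourdough survey studies: harmonises
multi-table survey + laboratory metadata, scores fold enrichments of
categorical and numeric features across cluster partitions (countries,
sources, flour types), runs pairwise effect-size testing with BH-FDR,
screens mixed-type collinearity, ordinates check-all-that-apply (CATA)
sensory profiles (Jaccard / PCoA / PERMANOVA / Mantel), and analyses the
numeric feature space with PCA and group confidence ellipses.

A first-class synthetic study generator (`sourscope.synthetic_data`) emulates
the statistical structure of such a study — multi-country participants,
household/bakery sources, flour compositions, feeding parameters, strip-scale
home pH vs continuous lab pH with a systematic offset, TTA, bread density,
56 binary aroma descriptors in 13 categories, multi-select motivation fields
and per-field missingness — and plants effects with a ground-truth registry so
every downstream stage is testable without external data.

## Package layout

| module | contents |
| --- | --- |
| `synthetic_data` | `GeneratorConfig`, `PlantedEffect`, `generate_study`, `sample_cata`, `write_study` |
| `harmonize` | `merge_tables` / `integrate`, `compute_dough_yield`, `decompose_flour`, `bin_rare_levels`, `filter_bread_density`, `categorize_numeric` |
| `pairwise_stats` | `chi_square_cramers_v`, `directional_cramers_v`, `mann_whitney_rank_biserial`, `cohens_d`, `compare_groups` (normality/homoscedasticity gate), `bh_fdr` |
| `enrichment` | `geo_filter`, `category_enrichment`, `numeric_enrichment`, `flag_multiplicity`, `cluster_enrichment_profiles` |
| `collinearity` | `association_matrix` (mixed-type), `select_representatives` |
| `cata_aroma` | `jaccard_matrix`, `pcoa`, `permanova`, `mantel`, `top_features` |
| `feature_space` | `pca` (geographic / substrate variants), `confidence_ellipse` |
| `cli_report` | `run_pipeline`, reproduction report, the `sourscope` CLI |
| `validation` | desk-scale simulation scenarios (null calibration, planted-effect recovery, pH-offset recovery, conservation) |

## CLI

```bash
# generate a synthetic study (three CSVs + truth.json)
sourscope generate --n 500 --seed 1 --outdir study/

# merge + curate the three tables into one integrated CSV (+ QC JSON)
sourscope harmonize --registration study/registration.csv \
    --results study/results.csv --lab study/laboratory.csv --out integrated.csv

# full pipeline (synthetic input by default); writes per-stage CSV/JSON
# plus a manifest with seeds, thresholds, QC counts and content hashes
sourscope analyze --seed 1 --outdir run/
sourscope report --outdir run/

# recompute headline descriptive numbers from an integrated metadata CSV
# and compare them against the stored expectations
sourscope reproduce --integrated integrated.csv --out reproduction_report.json
```

Exit codes: 0 on success, 2 on validation failure. Each pipeline stage draws
its seed deterministically from the master seed and the stage name, so
toggling one stage never shifts another stage's random stream; identical
config + seed gives byte-identical outputs.

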