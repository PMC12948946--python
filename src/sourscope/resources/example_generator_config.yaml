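# Example synthetic-study generator configuration.
# All fields are optional; anything omitted falls back to package defaults.
n_participants: 500
seed: 0
p_bakery: 0.125
ph_lab_offset: -0.73
ph_strip_step: 0.25
p_mixture: 0.10
countries:
  - [CH, 46.8, 8.2, 0.20]
  - [FI, 61.9, 25.7, 0.15]
  - [BE, 50.5, 4.5, 0.15]
  - [IT, 42.8, 12.8, 0.12]
  - [RO, 45.9, 24.9, 0.12]
  - [DE, 51.2, 10.4, 0.26]
missingness:
  ph_home: 0.10
  bread_density: 0.15
  backslop_frequency: 0.20
  cata: 0.10
effect_registry:
  - kind: mean_shift
    target_feature: tta
    cluster_variable: grain_base
    cluster_level: rye
    magnitude: 0.8
  - kind: aroma_association
    target_feature: sour
    cluster_variable: grain_base
    cluster_level: rye
    magnitude: 0.25
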