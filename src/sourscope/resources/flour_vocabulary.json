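{
  "grains": [
    "wheat", "rye", "spelt", "einkorn", "emmer", "barley",
    "oat", "buckwheat", "corn", "rice", "millet"
  ],
  "milling_grades": ["wholemeal", "semi-wholemeal", "endosperm"],
  "special": ["mixed"]
}
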