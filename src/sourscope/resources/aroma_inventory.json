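{
  "fermented": ["fermented", "yeasty", "alcoholic", "beer", "wine"],
  "sour": ["sour", "vinegar", "lactic acid", "tangy"],
  "grain_cereal": ["grain", "cereal", "wholegrain", "porridge", "bread", "flour"],
  "fermented_dairy": ["yoghurt", "buttermilk", "cheese", "butter", "kefir"],
  "fruity": ["apple", "citrus", "berry", "banana", "dried fruit", "tropical"],
  "floral": ["floral", "honey", "perfume", "rose"],
  "vegetal": ["grassy", "hay", "cucumber", "green", "herbal"],
  "nutty": ["nutty", "almond", "roasted", "toasted"],
  "sweet": ["sweet", "caramel", "vanilla", "malty"],
  "earthy": ["earthy", "musty", "mushroom", "soil"],
  "chemical": ["chemical", "solvent", "nail polish", "sulphur"],
  "animal": ["animal", "barnyard", "leather"],
  "other": ["ocean", "body odour"]
}
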