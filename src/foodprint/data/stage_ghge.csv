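food_type,processing,storage,transportation,package,preparation_at_home,printed_total
Vegetables and fungi,,0.005,0.040,0.023,0.005,0.081
Cereals,0.007,0.005,0.040,0.023,0.109,0.184
Fruits and nuts,,0.004,0.040,0.023,0.0003,0.075
Legumes,0.156,0.005,0.040,0.023,0.006,0.230
"Tubers, starches",,0.002,0.025,,0.005,0.032
Aquatic products,,0.026,0.010,0.023,0.082,0.350
Meat,,0.015,0.087,0.023,0.175,0.603
Dairy,0.045,0.015,0.087,0.023,0.016,0.186
Poultry,,0.015,0.044,0.023,0.136,0.521
Eggs,,0.015,0.087,0.023,0.055,0.180
Beverages,,0.002,0.022,0.064,,0.049
Sugars and preserves,0.133,0.005,0.040,0.023,0.005,0.081
Liquor and alcohol,,0.002,0.022,0.064,,0.049
Fats and oils,0.034,,0.040,,0.654,0.728
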