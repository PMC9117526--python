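key,parent_group,production,postharvest,storage,processing,transportation,printed_total
Vegetables and fungi,,12.15,19.40,15.00,,5.13,51.67
Rice,Cereals,3.47,2.66,6.17,2.18,0.74,15.22
Wheat,Cereals,3.12,0.77,6.91,2.38,0.24,13.42
Corn,Cereals,2.17,1.12,6.49,2.27,0.19,12.23
Fruits and nuts,,9.58,0.92,5.36,,5.50,21.36
Legumes,,6.00,3.00,,5.00,1.00,15.00
"Tubers, starches",,4.41,,17.13,0.04,0.01,21.59
Aquatic products,,2.00,,4.00,4.00,3.20,13.2
Pork,Meat,11.00,2.33,0.89,0.40,0.24,14.86
Beef,Meat,10.18,4.45,1.04,0.40,0.86,16.93
Mutton,Meat,4.15,2.28,0.35,0.40,0.83,8.01
Dairy,,3.50,1.00,,1.20,0.50,6.20
Poultry,,8.75,2.86,3.24,0.40,0.62,15.87
Eggs,,,,,,,10.5
Beverages,,,,,,,5.00
Sugars and preserves,,12.15,19.40,15.00,,5.13,51.67
Liquor and alcohol,,,,,,,5.00
Fats and oils,,6.00,3.00,,5.00,1.00,15.00
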