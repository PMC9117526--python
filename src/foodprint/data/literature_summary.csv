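group,indicator,n_items,n_studies,n_values,mean,stdev
Vegetables,GHGE,20,22,133,0.266,0.292
Cereals,GHGE,15,60,490,1.016,0.806
Fast foods,GHGE,2,2,3,1.334,1.616
Aquatic products,GHGE,6,10,16,7.029,6.358
Fruits,GHGE,9,18,64,0.353,0.246
Legumes,GHGE,4,7,14,0.832,0.681
Meat,GHGE,4,23,122,5.134,2.350
Sugars and preserves,GHGE,2,3,4,0.689,0.479
Beverages,GHGE,4,3,4,0.931,0.815
Liquor and alcohol,GHGE,2,3,4,0.726,0.454
Poultry,GHGE,2,11,21,3.784,2.128
Dairy,GHGE,3,21,67,1.297,0.404
Eggs,GHGE,1,13,22,2.890,1.215
Nuts and seeds,GHGE,1,2,2,0.695,0.290
"Tubers, starches",GHGE,3,6,7,0.291,0.367
Fungi and algae,GHGE,1,1,1,0.930,
Fats and oils,GHGE,1,3,5,1.822,1.404
Vegetables,WU,23,26,111,0.491,0.775
Cereals,WU,8,39,468,1.290,0.856
Fast foods,WU,2,2,3,0.813,0.076
Aquatic products,WU,17,16,41,3.235,1.881
Fruits,WU,8,18,53,0.574,0.445
Legumes,WU,4,15,49,2.512,0.944
Meat,WU,7,28,61,8.970,6.204
Sugars and preserves,WU,1,6,7,0.797,0.559
Beverages,WU,3,3,4,5.228,4.735
Liquor and alcohol,WU,2,6,9,0.803,0.998
Poultry,WU,5,15,19,3.030,1.105
Dairy,WU,1,13,14,1.609,0.614
Eggs,WU,1,15,17,3.257,0.176
Nuts and seeds,WU,2,7,23,1.400,0.345
"Tubers, starches",WU,4,13,41,0.926,0.516
Fungi and algae,WU,1,1,1,0.270,
Fats and oils,WU,3,12,19,4.475,1.626
Vegetables,LU,4,4,8,0.402,0.552
Cereals,LU,8,6,33,1.538,0.950
Fast foods,LU,4,1,3,1.920,1.106
Aquatic products,LU,5,1,10,2.356,2.317
Fruits,LU,1,1,1,0.640,
Legumes,LU,4,1,1,0.810,
Meat,LU,8,3,12,13.179,10.197
Sugars and preserves,LU,3,1,2,1.615,0.955
Beverages,LU,1,1,1,1.480,
Liquor and alcohol,LU,2,1,2,1.075,1.223
Poultry,LU,4,1,4,2.035,0.595
Dairy,LU,4,2,12,2.911,2.945
Eggs,LU,1,1,2,1.360,0.156
Fats and oils,LU,1,1,3,5.210,0.292
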