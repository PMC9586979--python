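name,ec_et_pct,ec_et_sd,n,et_mm,area_ha
Tropical rainforest,70,14,8,1076,11233190
Temperate deciduous forest,67,14,9,549,84468
Tropical grassland,62,19,5,583,1474088
Temperate grassland,57,19,8,332,518259
Temperate coniferous forest,55,15,13,458,32410
Desert,54,18,14,209,324492
Mediterranean shrubland,47,10,4,302,17020
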