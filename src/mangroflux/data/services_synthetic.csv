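ecosystem,service,value_usd_ha_yr
Mangrove,food production,1111.0
Mangrove,raw materials,330.0
Tropical rainforest,food production,200.0
Tropical rainforest,raw materials,84.0
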