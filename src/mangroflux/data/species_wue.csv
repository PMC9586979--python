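species,wue_ins_mmol_mol,se
Avicennia germinans,3.82,0.3
Laguncularia racemosa,4.57,0.3
Rhizophora mangle,5.15,0.4
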