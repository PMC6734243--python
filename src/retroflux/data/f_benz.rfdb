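# retroflux database v1
[compounds]
4-aminobenzoate	4-aminobenzoate	
benzene	benzene	
phenylamine	phenylamine	
[reactions]
R_abz_decarb	biological	4.1.1.24		1 4-aminobenzoate -> 1 phenylamine
R_chem_deamination	chemical			1 phenylamine -> 1 benzene
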