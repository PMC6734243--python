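# retroflux database v1
[compounds]
2-ketobutyrate	2-ketobutyrate	
2-oxovalerate	2-oxovalerate	
butanal	butanal	
butanol	butanol	
[reactions]
R_adh_buoh	biological	1.1.1.1		1 butanal -> 1 butanol
R_kdc_butanal	biological	4.1.1.72		1 2-oxovalerate -> 1 butanal
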