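# retroflux database v1
[compounds]
2-keto-4-methylpentanoate	2-keto-4-methylpentanoate	
3-methylbutanal	3-methylbutanal	
3-methylbutanol	3-methylbutanol	
[reactions]
R_adh_3mbol	biological	1.1.1.1		1 3-methylbutanal -> 1 3-methylbutanol
R_kdc_3mbal	biological	4.1.1.72		1 2-keto-4-methylpentanoate -> 1 3-methylbutanal
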