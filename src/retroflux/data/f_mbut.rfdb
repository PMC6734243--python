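# retroflux database v1
[compounds]
2-methylbutanal	2-methylbutanal	
2-methylbutanoate	2-methylbutanoate	
2-methylbutanol	2-methylbutanol	
2-methylbutanoyl_CoA	2-methylbutanoyl CoA	
3-methyl-2-oxobutanoate	3-methyl-2-oxobutanoate	
3-methyl-2-oxopentanoate	3-methyl-2-oxopentanoate	
isoleucine	isoleucine	
[reactions]
R_3m2ob_3m2op	biological			1 3-methyl-2-oxobutanoate -> 1 3-methyl-2-oxopentanoate
R_3m2op_mbal	biological	4.1.1.72		1 3-methyl-2-oxopentanoate -> 1 2-methylbutanal
R_ile_3m2op	biological	2.6.1.42		1 isoleucine -> 1 3-methyl-2-oxopentanoate
R_mbac_mbol	biological			1 2-methylbutanoate -> 1 2-methylbutanol
R_mbal_mbac	biological			1 2-methylbutanal -> 1 2-methylbutanoate
R_mbcoa_3m2op	biological			1 2-methylbutanoyl_CoA -> 1 3-methyl-2-oxopentanoate
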