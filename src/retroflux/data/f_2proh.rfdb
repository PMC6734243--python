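# retroflux database v1
[compounds]
2-propanol	2-propanol	
acetoacetate	acetoacetate	
acetol	acetol	
acetone	acetone	
farnesyl_diphosphate	farnesyl diphosphate	
fpp_acetone_intermediate	fpp acetone intermediate	
methylglyoxal	methylglyoxal	
[reactions]
R_adc	biological	4.1.1.4		1 acetoacetate -> 1 acetone
R_adh_2p	biological	1.1.1.80		1 acetone -> 1 2-propanol
R_fpp_1	biological			1 farnesyl_diphosphate -> 1 fpp_acetone_intermediate
R_fpp_2	biological			1 fpp_acetone_intermediate -> 1 acetone
R_mgx_1	biological			1 methylglyoxal -> 1 acetol
R_mgx_2	biological			1 acetol -> 1 acetone
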