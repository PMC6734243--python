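# retroflux database v1
[compounds]
2-methylpropanal_oxime	2-methylpropanal oxime	
acetoacetate	acetoacetate	
acetol	acetol	
acetone	acetone	
farnesyl_diphosphate	farnesyl diphosphate	
fpp_acetone_intermediate	fpp acetone intermediate	
methyl_acetate	methyl acetate	
methylglyoxal	methylglyoxal	
valine	valine	
valine_acetone_intermediate_1	valine acetone intermediate 1	
valine_acetone_intermediate_2	valine acetone intermediate 2	
[reactions]
R_adc	biological	4.1.1.4		1 acetoacetate -> 1 acetone
R_bvmo	biological	1.14.13.x		1 acetone -> 1 methyl_acetate
R_fpp_1	biological			1 farnesyl_diphosphate -> 1 fpp_acetone_intermediate
R_fpp_2	biological			1 fpp_acetone_intermediate -> 1 acetone
R_mgx_1	biological			1 methylglyoxal -> 1 acetol
R_mgx_2	biological			1 acetol -> 1 acetone
R_vox	biological	1.14.14.36		1 valine -> 1 2-methylpropanal_oxime
R_vx_1	biological			1 2-methylpropanal_oxime -> 1 valine_acetone_intermediate_1
R_vx_2	biological			1 valine_acetone_intermediate_1 -> 1 valine_acetone_intermediate_2
R_vx_3	biological			1 valine_acetone_intermediate_2 -> 1 acetone
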