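# retroflux database v1
[compounds]
3-methyl-2-oxobutanoate	3-methyl-2-oxobutanoate	
isobutanal	isobutanal	
isobutanol	isobutanol	
isobutanoyl_CoA	isobutanoyl CoA	
valine	valine	
valine_isobutanal_intermediate	valine isobutanal intermediate	
[reactions]
R_adh_ibol	biological	1.1.1.1		1 isobutanal -> 1 isobutanol
R_coa_1	biological			1 3-methyl-2-oxobutanoate -> 1 isobutanoyl_CoA
R_coa_2	biological	1.2.1.10		1 isobutanoyl_CoA -> 1 isobutanal
R_kdc_ibal	biological	4.1.1.72		1 3-methyl-2-oxobutanoate -> 1 isobutanal
R_val_1	biological			1 valine -> 1 valine_isobutanal_intermediate
R_val_2	biological			1 valine_isobutanal_intermediate -> 1 isobutanal
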