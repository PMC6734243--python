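# retroflux database v1
[compounds]
cinnamate	cinnamate	
coumarate	coumarate	
coumaroyl_CoA	coumaroyl CoA	
phenylalanine	phenylalanine	
pterostilbene	pterostilbene	
resveratrol	resveratrol	
tyrosine	tyrosine	
[reactions]
R_4cl	biological	6.2.1.12		1 coumarate -> 1 coumaroyl_CoA
R_c4h	biological	1.14.14.91		1 cinnamate -> 1 coumarate
R_pal	biological	4.3.1.24		1 phenylalanine -> 1 cinnamate
R_romt	biological	2.1.1.240		1 resveratrol -> 1 pterostilbene
R_sts	biological	2.3.1.95		1 coumaroyl_CoA -> 1 resveratrol
R_tal	biological	4.3.1.23		1 tyrosine -> 1 coumarate
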