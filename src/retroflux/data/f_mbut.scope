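# retroflux scope v1
organism	eco-k12
compound	2-methylbutanoyl_CoA
compound	3-methyl-2-oxobutanoate
compound	isoleucine
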