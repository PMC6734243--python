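# retroflux scope v1
organism	eco-k12
compound	acetoacetate
compound	farnesyl_diphosphate
compound	methylglyoxal
compound	valine
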