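cross	n_wild	n_mutant
dw_x_Zp661	97	31
dw_x_JD12	231	92
dw_x_Zh13	146	53
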