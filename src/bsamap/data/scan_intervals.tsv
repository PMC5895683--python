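name	chrom	start_bp	stop_bp
locus7-1	Gm07	513840	606834
locus8-1	Gm08	8716986	14491037
locus14-1	Gm14	8075271	9355387
locus14-2	Gm14	24821398	27119121
locus15-1	Gm15	21601429	22103288
locus15-2	Gm15	35344325	36214614
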