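marker_id	chrom	position_mb	n_recombinant_plants
SNP08-1	Gm08	12.61	1
SNP08-2	Gm08	12.69	0
SNP08-3	Gm08	12.85	0
SNP08-4	Gm08	12.90	0
SNP08-5	Gm08	13.01	0
08-0716	Gm08	13.07	1
SNP08-6	Gm08	13.08	1
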