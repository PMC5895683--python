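marker_id	chrom	position_mb
08-0556	Gm08	10.19
08-0687	Gm08	12.38
08-0692	Gm08	12.57
08-0706	Gm08	12.89
08-0716	Gm08	13.07
08-0762	Gm08	13.95
08-0777	Gm08	14.17
08-0818	Gm08	14.73
08-0935	Gm08	16.85
08-0941	Gm08	16.91
SNP08-1	Gm08	12.61
SNP08-2	Gm08	12.69
SNP08-3	Gm08	12.85
SNP08-4	Gm08	12.90
SNP08-5	Gm08	13.01
SNP08-6	Gm08	13.08
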