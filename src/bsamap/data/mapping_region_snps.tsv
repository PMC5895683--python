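chrom	pos	ref	alt	wt_ref	wt_alt	mut_ref	mut_alt	effect	gene	marker
Gm08	12598498	G	A	24	15	28	0	intergenic	.	.
Gm08	12613790	C	T	18	5	0	26	nonsynonymous	Glyma.08G162100	SNP08-1
Gm08	12686354	G	T	26	0	9	6	upstream	.	SNP08-2
Gm08	12847120	T	A	50	6	0	63	upstream	.	SNP08-3
Gm08	12903104	T	A	43	0	0	41	nonsynonymous	Glyma.08G163900	SNP08-4
Gm08	12969978	G	A	10	3	13	0	downstream	.	.
Gm08	13012790	C	A	37	3	26	5	nonsynonymous	Glyma.08G165100	SNP08-5
Gm08	13055558	G	A	32	18	24	0	upstream	.	.
Gm08	13077287	C	T	34	0	0	37	nonsynonymous	Glyma.08G165800	SNP08-6
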