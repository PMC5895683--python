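gene_id	annotation
Glyma.08G162200	Methylated RNA-binding protein 1
Glyma.08G162300	Nucleoprotein TPR-related
Glyma.08G162400	Aspartic protease CDR1-related
Glyma.08G162500	DNA-3-methyladenine glycosylase I
Glyma.08G162600	39S ribosomal protein L15, mitochondrial
Glyma.08G162700	Peroxidase/Lactoperoxidase
Glyma.08G162800	Zinc finger CCCH domain-containing protein 5
Glyma.08G162900	Metacaspase-5-like
Glyma.08G163000	E3 ubiquitin-protein ligase RGLG2-like
Glyma.08G163100	NAC domain-containing protein 20-related
Glyma.08G163200	MYB-like DNA-binding protein
Glyma.08G163300	Uncharacterized protein
Glyma.08G163400	Uncharacterized protein
Glyma.08G163500	MYB family transcription factor APL-like
Glyma.08G163600	Uncharacterized protein
Glyma.08G163700	Succinate-semialdehyde dehydrogenase, mitochondrial-like
Glyma.08G163800	Cell cycle control protein 50
Glyma.08G163900	Ent-kaurene synthase, chloroplastic-like
Glyma.08G164000	50S ribosomal protein L7/L12-like, mitochondrial
Glyma.08G164100	IMP dehydrogenase/Inosinic acid dehydrogenase
Glyma.08G164200	Carbohydrate-binding X8 domain-containing protein
Glyma.08G164300	Uncharacterized protein
Glyma.08G164400	Zinc transporter 1-like
Glyma.08G164500	G-protein coupled receptor
Glyma.08G164600	Bifunctional L-3-cyanoalanine synthase/cysteine synthase D1-related
Glyma.08G164700	Metal tolerance protein 10-like
Glyma.08G164800	Metal tolerance protein 10-like
Glyma.08G164900	Cullin binding/UBA-like domain
Glyma.08G165000	Defense-like protein 1-related
Glyma.08G165100	Transglycosylase SLT domain
Glyma.08G165200	Uncharacterized protein
Glyma.08G165300	Uncharacterized protein
Glyma.08G165400	Phosphoglycerate kinase, cytosolic-like
Glyma.08G165500	Phosphoglycerate kinase 1, chloroplastic-like
Glyma.08G165600	DEAD-box ATP-dependent RNA helicase 36-like
Glyma.08G165700	Histone-like transcription factor CCAAT-related
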