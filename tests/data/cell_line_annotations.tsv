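cell_line	gene_a	defect	is_control
HCC1500	BRCA1	MUT	0
HCC1500	BRCA1	DOWN	0
HCC1419	ATM	DOWN	0
HCC1419	TP53	MUT	0
HCC1395	ATM	DOWN	0
HCC1395	BRCA1	MUT	0
HCC1395	BRCA1	DOWN	0
HCC1395	BRCA2	MUT	0
HCC1395	BRCA2	DOWN	0
HCC1395	TP53	MUT	0
HCC1806	PTEN	DOWN	0
HCC1143	TP53	MUT	0
HCC38	ATM	DOWN	0
HCC38	BRCA2	DOWN	0
HCC38	PTEN	MUT	0
HCC38	PTEN	HOMDEL	0
HCC1187	BRCA1	DOWN	0
HCC1187	BRCA2	DOWN	0
HCC1954	BRCA1	DOWN	0
HCC1954	TP53	MUT	0
MCF7			1
HCC1428	BRCA2	DOWN	0
HCC1428	PTEN	HOMDEL	0
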