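disease	gene_symbol	ensembl_gene_id	classification
Amyotrophic lateral sclerosis	SETX	ENSG00000107290	Definitive
Amyotrophic lateral sclerosis	SOD1	ENSG00000142168	Definitive
Amyotrophic lateral sclerosis	C9orf72	ENSG00000147894	Definitive
Amyotrophic lateral sclerosis	FUS	ENSG00000089280	Definitive
Amyotrophic lateral sclerosis	TARDBP	ENSG00000120948	Definitive
Charcot-Marie-Tooth	SETX	ENSG00000107290	Definitive
Charcot-Marie-Tooth	PMP22	ENSG00000109099	Definitive
Charcot-Marie-Tooth	MFN2	ENSG00000116688	Definitive
Charcot-Marie-Tooth	GJB1	ENSG00000169562	Definitive
Charcot-Marie-Tooth	MPZ	ENSG00000158887	Definitive
Alzheimer disease	APP	ENSG00000142192	Definitive
Alzheimer disease	PSEN1	ENSG00000080815	Definitive
Alzheimer disease	PSEN2	ENSG00000143801	Definitive
Alzheimer disease	APOE	ENSG00000130203	Strong
Parkinson disease	SNCA	ENSG00000145335	Definitive
Parkinson disease	LRRK2	ENSG00000188906	Definitive
Parkinson disease	PRKN	ENSG00000185345	Definitive
Parkinson disease	PINK1	ENSG00000158828	Definitive
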