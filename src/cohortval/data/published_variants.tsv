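donor_id	gene	dna_change	protein_change	zygosity	variant_type	population_frequency_pct	deleteriousness_score
6033	KCNJ11	c.868G>A	Val209Met	Het	missense	0.002	23.5
6166	LMNA	c.898G>A	Asp300Asn	Het	missense	0	28.8
6176	HNF1A	c.29C>T	Thr10Met	Het	missense	0.002	22.2
6243	GLIS3	c.1863C>G	His621Gln	Het	missense	0.001	20.4
6264	INSR	c.3034G>A	Val1012Met	Het	missense	0.80	26.1
6320	GATA6	c.1366C>T	Arg456Cys	Het	missense	0	31
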