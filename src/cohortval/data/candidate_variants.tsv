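donor_id	gene	dna_change	protein_change	zygosity	variant_type	population_frequency_pct	deleteriousness_score
6205	HNF1A	c.142G>A	p.E48K	Het	missense	0.009	22.1
6261	STAT1	c.77_80dupACAG	p.S27fs*26	Het	frameshift	0.003	24.9
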