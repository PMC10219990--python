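# Synthetic example risk-score model exercising the full engine schema:
# weighted SNP terms, an HLA diplotype interaction table with per-haplotype
# additive weights, a proxy substitution map, an imputation-R2 filter, and
# affine normalization. Weights are illustrative, not published values.
name: example_t1d_grs_synthetic
r2_min: 0.97
normalization: {a: 0.0, b: 0.1}
snp_terms:
  - {variant_id: rsA1, effect_allele: G, weight: 1.10}
  - {variant_id: rsA2, effect_allele: A, weight: 0.76}
  - {variant_id: rsA3, effect_allele: G, weight: 0.55}
  - {variant_id: rsA4, effect_allele: T, weight: 0.45}
  - {variant_id: rsA5, effect_allele: G, weight: 0.38}
  - {variant_id: rsA6, effect_allele: A, weight: -0.30}
  - {variant_id: rsA7, effect_allele: G, weight: 0.25}
proxy_map:
  rsA7: rsA7proxy
interaction_terms:
  - {haplotypes: [DR3, DR4], weight: 3.87}
  - {haplotypes: [DR3], weight: 3.11}
  - {haplotypes: [DR4], weight: 3.42}
haplotype_weights:
  DRX: 0.20
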