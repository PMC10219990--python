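# Diabetes gene panels used for coding-variant prioritization.
- name: autoimmune_diabetes
  category: autoimmune
  genes: [AIRE, FOXP3, IL2RA, ITCH, LRBA, SKAP2, STAT1, STAT3]
- name: mody_neonatal_diabetes
  category: mody_neonatal
  genes: [GCK, HNF1A, HNF4A, HNF1B, ABCC8, KCNJ11, INS]
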