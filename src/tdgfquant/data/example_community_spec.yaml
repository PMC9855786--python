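# Example community spec for `tdgfquant simulate --spec ...`.
# These values reproduce the default design: the 14-species community,
# 13 mice (3 F / 4 R / 6 FR) with 16S profiles, RNA-seq for 3 mice per
# diet, ortholog identity 0.85, lognormal noise sigma 0.2.
tdgf_identity: 0.85
n_decoy_contigs: 3
lognormal_sigma: 0.2
dirichlet_alpha: 10.0
n_rnaseq_mice_per_diet: 3
mice_per_diet: {F: 3, R: 4, FR: 6}
diet_multipliers:
  mucin_degraders: {F: 1.0, FR: 1.0, R: 0.3}
  sulfate_reducers: {F: 1.0, FR: 1.0, R: 0.4}
  butyrate_producers: {F: 1.0, FR: 0.8, R: 0.5}
  acetogens: {F: 0.5, FR: 0.8, R: 1.0}
group_assignment:
  Akkermansia muciniphila: [mucin_degraders]
  Bacteroides caccae: [mucin_degraders]
  Bacteroides ovatus: []
  Bacteroides thetaiotaomicron: [mucin_degraders]
  Bacteroides uniformis: []
  Barnesiella intestinihominis: [mucin_degraders]
  Clostridium symbiosum: [butyrate_producers]
  Collinsella aerofaciens: [acetogens]
  Desulfovibrio piger: [sulfate_reducers]
  Escherichia coli HS: []
  Eubacterium rectale: [butyrate_producers]
  Faecalibacterium prausnitzii: [butyrate_producers]
  Marvinbryantia formatexigens: [acetogens]
  Roseburia intestinalis: [butyrate_producers]
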