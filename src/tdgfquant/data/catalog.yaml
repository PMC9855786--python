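# Default marker catalog: four gut functional groups, eight markers.
# The four per-group analysis markers are acet1, sulfat1, but1 and muc2;
# the remaining markers illustrate multi-marker groups.  Protein sequences
# live in tdgf_proteins.synthetic.fasta (synthetic placeholders — supply
# real enzyme sequences for actual communities).
groups:
  - group_id: butyrate_producers
    display_name: Butyrate producers
    member_taxa:
      - Clostridium symbiosum
      - Eubacterium rectale
      - Faecalibacterium prausnitzii
      - Roseburia intestinalis
  - group_id: acetogens
    display_name: Acetogens
    member_taxa:
      - Collinsella aerofaciens
      - Marvinbryantia formatexigens
  - group_id: sulfate_reducers
    display_name: Sulfate reducers
    member_taxa:
      - Desulfovibrio piger
  - group_id: mucin_degraders
    display_name: Mucin degraders
    member_taxa:
      - Akkermansia muciniphila
      - Bacteroides caccae
      - Bacteroides thetaiotaomicron
      - Barnesiella intestinihominis

tdgfs:
  - tdgf_id: acet1
    group_id: acetogens
    enzyme_name: carbon monoxide dehydrogenase
    ec: 1.2.7.4
  - tdgf_id: acet2
    group_id: acetogens
    enzyme_name: acetyl-CoA synthetase
    ec: 2.3.1.169
  - tdgf_id: acet3
    group_id: acetogens
    enzyme_name: corrinoid iron-sulfur protein, small subunit
  - tdgf_id: acet4
    group_id: acetogens
    enzyme_name: corrinoid iron-sulfur protein, large subunit
  - tdgf_id: sulfat1
    group_id: sulfate_reducers
    enzyme_name: dissimilatory sulfite reductase
    ec: 1.8.99.5
  - tdgf_id: but1
    group_id: butyrate_producers
    enzyme_name: butyryl-CoA dehydrogenase
    ec: 1.3.8.1
  - tdgf_id: muc1
    group_id: mucin_degraders
    enzyme_name: sulfatase
    ec: 3.1.6.1
  - tdgf_id: muc2
    group_id: mucin_degraders
    enzyme_name: alpha-N-acetylgalactosaminidase
    ec: 3.2.1.49
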