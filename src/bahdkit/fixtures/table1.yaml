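# Seven-clade reference fixture: per-clade gene totals, whole-genome
# (salicoid) duplication pairs, tandem-array cluster sizes and
# retroelement flank categories for a 100-gene acyltransferase family.
# Cluster compositions follow the published per-clade descriptions
# (pairs/triplets/quadruplet); cross_pairs are salicoid pairs whose
# second member sits inside a tandem array (lone-survivor cases), which
# produce genes counted in both duplication types.  Clade II members
# genuinely lack the DFGWG motif and enter the curation exemption list.
taxon: Populus
protein_length: 460
clades:
  Ia:
    n_genes: 18
    salicoid_pairs: 0
    local_clusters: [3, 3]
    retro_both: 5
    retro_one: 2
  Ib:
    n_genes: 11
    salicoid_pairs: 3
    local_clusters: [2, 3]
    retro_both: 1
    retro_one: 3
  II:
    n_genes: 5
    dfgwg_free: true
    retro_both: 1
    retro_one: 0
  IIIa:
    n_genes: 24
    salicoid_pairs: 3
    local_clusters: [2, 2, 2, 2]
    retro_both: 2
    retro_one: 2
  IIIb:
    n_genes: 2
    retro_both: 0
    retro_one: 1
  Va:
    n_genes: 31
    salicoid_pairs: 5
    cross_pairs: 2
    local_clusters: [3, 4, 2, 2, 2]
    retro_both: 3
    retro_one: 13
  Vb:
    n_genes: 9
    salicoid_pairs: 2
    local_clusters: [2, 2]
    retro_both: 1
    retro_one: 1
decoys:
  no_hxxxd: 3
  low_dfgwg: 3
  too_short: 3
  scaffold_redundant: 2
expression:
  n_groups: 9
  n_replicates: 2
  rho_local: 0.8
  rho_salicoid: 0.8
  rho_other: 0.0
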