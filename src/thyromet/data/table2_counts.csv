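pathway,group_number,sig_count,notsig_count
Carbohydrate metabolism,1,1,21
Amino acid metabolism,2,9,97
Lipid metabolism,3,16,58
Nucleotide metabolism,4,0,7
Xenobiotic/drug metabolism,5,17,91
Bile acid metabolism,6,0,5
Eicosanoid metabolism,7,0,8
Hormone/steroid metabolism,8,2,4
Other/unknown/microbial or plant secondary pathways,9,4,49
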