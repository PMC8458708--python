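{
  "description": "Per-characteristic cancer lists from the published pan-cancer analyses of ICB plus lenvatinib target genes. Each list names the TCGA cancer codes satisfying one criterion; build_evidence combines them into the >=2-characteristics candidate call.",
  "expression_high": ["CHOL", "GBM", "HNSC", "KIRC", "LIHC", "STAD"],
  "top_mutational_load": ["SKCM", "UCEC", "LUSC", "BLCA", "LUAD", "STAD", "UCS", "COAD", "READ", "SARC", "ESCA", "OV", "GBM", "HNSC", "CESC", "CHOL"],
  "lenvatinib_driver_high": ["LUSC", "BLCA", "GBM", "CHOL", "TGCT", "UCEC", "SARC", "BRCA", "ESCA", "UCS", "SKCM", "LGG", "OV", "LUAD", "KIRC", "HNSC", "STAD"],
  "pdl1_driver_high": ["DLBC", "HNSC", "SARC", "BLCA", "CESC", "ESCA", "LUSC", "OV", "STAD", "UCS"],
  "cd8_negative": ["ACC", "CESC", "COAD", "DLBC", "KIRC", "LIHC", "LUAD", "PRAD", "SKCM", "UCEC"]
}
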