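# Many-to-many compatibility between a patient's presenting clinical
# diagnosis and gene phenotype groups.  The default is deliberately
# permissive within the photoreceptor-disease and macular-disease families:
# RP presentations are additionally compatible with choroideraemia, Bietti
# crystalline dystrophy, Usher and CSNB genes, which clinically mimic RP.
# Editable config; labels not listed here are compatible only with
# themselves.
compatible:
  RP: [RP, Usher, choroideraemia, Bietti, CSNB, LCA, CORD, BBS, Joubert, MD]
  CORD: [CORD, RP, STGD, MD, LCA, CSNB]
  STGD: [STGD, CORD, MD, RP]
  VMD: [VMD, MD, STGD, CORD, RP]
  MD: [MD, STGD, CORD, VMD, NCMD, RP]
  NCMD: [NCMD, MD, STGD, CORD]
  LCA: [LCA, RP, CORD, Joubert]
  CSNB: [CSNB, RP, CORD]
  Usher: [Usher, RP]
  BBS: [BBS, RP, Joubert]
  Joubert: [Joubert, LCA, BBS, RP]
  Bietti: [Bietti, RP]
  choroideraemia: [choroideraemia, RP]

# Phenotype labels from most to least specific; used when a diagnostic gene
# forces revision of the clinical diagnosis (pick the gene's most specific
# group).
specificity:
  - choroideraemia
  - Bietti
  - Joubert
  - BBS
  - Usher
  - NCMD
  - LCA
  - CSNB
  - STGD
  - CORD
  - VMD
  - MD
  - RP
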