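# Hierarchical marker reference for lung tumor-microenvironment annotation.
#
# Levels:
#   major - 13 major cell types of the NSCLC single-cell atlas
#   mp    - 5 mononuclear-phagocyte subtypes
#   macro - six-gene macrophage classification (one anchor gene per state,
#           extended with canonical companions)
#
# Markers are canonical lung-TME genes; each gene belongs to exactly one
# type within its level.
major:
  CancerCells: [EPCAM, KRT19, SAA1, APP]
  AT2: [SFTPC, SFTPB, SFTPA1]
  ClubCells: [SCGB1A1, SCGB3A1, BPIFB1]
  CiliatedCells: [FOXJ1, TPPP3, PIFO]
  ECs: [PECAM1, CLDN5, VWF]
  Fibroblasts: [COL1A1, COL1A2, DCN, CXCL14]
  PlasmaCells: [MZB1, IGHG1, JCHAIN]
  BCells: [MS4A1, CD79A, CD19]
  TCells: [CD3D, CD3E, TRAC]
  Neutrophils: [FCGR3B, CSF3R, S100A8]
  MastCells: [TPSAB1, TPSB2, CPA3]
  MPs: [LYZ, CD68, AIF1, FPR2]
  pDCs: [LILRA4, CLEC4C, IRF7]
mp:
  Macrophages: [MARCO, APOE, C1QA, TREM2]
  Monocytes: [FCN1, VCAN, S100A12]
  MatureDCs: [LAMP3, CCR7, FSCN1]
  cDC1: [CLEC9A, XCR1, BATF3]
  cDC2: [CD1C, FCER1A, CLEC10A]
macro:
  Macrophages_AZU1: [AZU1, ELANE, MPO]
  Macrophages_CXCL10: [CXCL10, CXCL9, IL1B, TNF]
  Macrophages_FABP4: [FABP4, MRC1, CD163, MSR1]
  Macrophages_SELENOP: [SELENOP, SLC40A1, STAB1]
  Macrophages_SPP1: [SPP1, MMP9, CSTB]
  Macrophages_STMN1: [STMN1, MKI67, TOP2A]
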