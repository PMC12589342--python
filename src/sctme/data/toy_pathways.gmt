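TOY_ANTIGEN_PRESENTATION	MHC-II-style antigen processing stand-in	CD74	HLA-DRA	HLA-DRB1	HLA-DPA1	LYZ	AIF1	BG0001	BG0002
TOY_INFLAMMATORY_RESPONSE	acute inflammation stand-in	IL1B	TNF	IL6	CXCL9	CXCL10	S100A8	S100A12	SAA1	FPR2
TOY_CHEMOKINE_SIGNALING	chemokine-receptor stand-in	CXCL9	CXCL10	CXCL14	CXCR4	CCR7	CCL22	BG0003
TOY_COMPLEMENT_CASCADE	complement stand-in	C1QA	C1QB	C1QC	CFD	BG0004	BG0005	BG0006
TOY_PHAGOCYTOSIS	phagocytic machinery stand-in	MARCO	MSR1	MRC1	CD68	TREM2	BG0007	BG0008
TOY_SURFACTANT_METABOLISM	alveolar surfactant stand-in	SFTPC	SFTPB	SFTPA1	BG0009	BG0010
TOY_CILIUM_ASSEMBLY	motile cilium stand-in	FOXJ1	TPPP3	PIFO	BG0011	BG0012	BG0013
TOY_ECM_ORGANIZATION	extracellular matrix stand-in	COL1A1	COL1A2	DCN	MMP9	BG0014	BG0015
TOY_ANGIOGENESIS	vascular development stand-in	PECAM1	CLDN5	VWF	BG0016	BG0017	BG0018
TOY_BCR_SIGNALING	B-cell receptor stand-in	MS4A1	CD79A	CD19	BG0019	BG0020
TOY_TCR_SIGNALING	T-cell receptor stand-in	CD3D	CD3E	TRAC	BG0021	BG0022
TOY_IMMUNOGLOBULIN_PRODUCTION	plasma-cell program stand-in	MZB1	IGHG1	JCHAIN	BG0023	BG0024
TOY_GRANULOCYTE_ACTIVATION	neutrophil degranulation stand-in	FCGR3B	CSF3R	AZU1	ELANE	MPO	BG0025
TOY_MAST_CELL_DEGRANULATION	mast-cell granule stand-in	TPSAB1	TPSB2	CPA3	BG0026	BG0027
TOY_TYPE_I_IFN_RESPONSE	interferon response stand-in	IRF7	LILRA4	CLEC4C	CXCL10	BG0028
TOY_DC_MATURATION	dendritic-cell maturation stand-in	LAMP3	CCR7	FSCN1	CD1C	FCER1A	CLEC9A
TOY_MONOCYTE_RECRUITMENT	monocyte chemotaxis stand-in	FCN1	VCAN	S100A12	S100A8	BG0029
TOY_LIPID_HANDLING	lipid-laden macrophage stand-in	FABP4	APOE	MSR1	BG0030	BG0031
TOY_IRON_RECYCLING	iron-handling macrophage stand-in	SELENOP	SLC40A1	STAB1	BG0032	BG0033
TOY_CELL_CYCLE	proliferation stand-in	STMN1	MKI67	TOP2A	BG0034	BG0035	BG0036
TOY_EPITHELIAL_IDENTITY	epithelial program stand-in	EPCAM	KRT19	SCGB1A1	SCGB3A1	BPIFB1
TOY_WOUND_HEALING	tissue remodeling stand-in	SPP1	MMP9	CSTB	COL1A1	BG0037
TOY_CHROMATIN_ORGANIZATION	nuclear regulation stand-in	BG0038	BG0039	BG0040	BG0041	BG0042
TOY_RNA_SPLICING	spliceosome stand-in	BG0043	BG0044	BG0045	BG0046	BG0047
TOY_PROTEASOME_DEGRADATION	ubiquitin-proteasome stand-in	BG0048	BG0049	BG0050	BG0051
TOY_ER_PROTEIN_PROCESSING	endoplasmic-reticulum stand-in	BG0052	BG0053	BG0054	BG0055	BG0056
TOY_OXIDATIVE_PHOSPHORYLATION	mitochondrial respiration stand-in	BG0057	BG0058	BG0059	BG0060
TOY_GLYCOLYSIS	glycolytic metabolism stand-in	BG0061	BG0062	BG0063	BG0064
TOY_APOPTOSIS	programmed cell death stand-in	BG0065	BG0066	BG0067	BG0068	BG0069
TOY_EPH_EPHRIN_SIGNALING	ephrin guidance stand-in	EFNA1	EPHA2	EPHB2	BG0070	BG0071
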