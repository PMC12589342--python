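# Mini ligand-receptor database for tumor-cell -> mononuclear-phagocyte screening.
# Complex members are comma-separated; a complex scores by its least-expressed member.
# NOTE: PGE2 is a lipid metabolite and has no transcript; the PGE2-PTGER axis is
# represented by the synthase proxy pair PTGES-PTGER4.
pair	ligand_genes	receptor_genes
EFNA1_EPHA2	EFNA1	EPHA2
EFNA1_EPHB2	EFNA1	EPHB2
SAA1_FPR2	SAA1	FPR2
APP_FPR2	APP	FPR2
CXCL14_CXCR4	CXCL14	CXCR4
APP_TREM2	APP	TREM2
HLAF_VSIR	HLA-F	VSIR
PTGES_PTGER4	PTGES	PTGER4
SPP1_CD44	SPP1	CD44
IL1B_IL1R1	IL1B	IL1R1,IL1RAP
CXCL9_CXCR3	CXCL9	CXCR3
CXCL10_CXCR3	CXCL10	CXCR3
CSF1_CSF1R	CSF1	CSF1R
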