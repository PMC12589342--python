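# Methods

## Scope and data model

`sctme` implements a compositional TME analysis for single-cell RNA-seq
cohorts stratified into three tissue groups (`NOR` adjacent-normal,
`RUNX3_Neg` and `RUNX3_Pos` tumor tissue, assigned per specimen by the
composite IHC score). Counts travel as 10x-style MatrixMarket triplets
and live in memory as `AnnData` (cells × genes); per-cell annotations
are plain data frames with the columns `cell_id, sample_id, group,
cluster_id, major_type, mp_subtype, macro_subtype`, where
`mp_subtype` is non-null only for MPs and `macro_subtype` only for
macrophages.

## IHC composite score

Two 0–2 point components are summed: percentage of positive cells
(<10% → 0, 10–50% → 1, >50% → 2; the bin edges 10 and 50 both score 1,
i.e. the middle bin is the closed interval [10, 50]) and staining
intensity (none/weak → 0, moderate → 1, strong → 2; the scheme gives no
computational criterion separating "none" from "weak", so both map to
0). Composite 0–2 → `RUNX3_Neg`, 3–4 → `RUNX3_Pos`. Reader
adjudication is out of scope: one consensus record per specimen.

## Hierarchical annotation

Per level (major → MP → macrophage state):

1. **Normalization** — per-cell scaling to `target_sum` (default 10⁴)
   followed by log1p. All-zero cells cannot be scaled and are dropped
   with a warning.
2. **Clustering** — selection of the `n_hvg` most highly variable genes
   (default 200; skipped when the matrix is smaller), PCA to
   `n_components` (default 15), a 15-nearest-neighbor graph, Leiden
   community detection at resolution 2.0 (k-means available as a
   fallback). The resolution errs deliberately on the fine side:
   several clusters may map to one type, and over-clustering costs
   nothing downstream while under-clustering silently merges rare
   types. Z-scaling before PCA is available but off by default —
   with marker-driven structure, variance weighting helps the signal.
   All stochastic steps take one seed; repeated runs are identical.
3. **Marker scoring** — genes are z-scored across cells (a
   zero-variance gene is defined to score 0); score(cluster, type) is
   the mean over the type's markers of the marker's mean z-score in the
   cluster. Markers absent from the matrix are dropped with a warning;
   a type losing all markers is an error.
4. **Assignment** — each cluster takes the argmax type; exact ties
   break lexicographically and are flagged.

The three packaged references hold 13 major types, 5 MP subtypes and
the 6 macrophage states anchored by AZU1, CXCL10, FABP4, SELENOP, SPP1
and STMN1. The major/MP marker panels are canonical lung-TME genes
(SFTPC for AT2, SCGB1A1 for club cells, FOXJ1 for ciliated cells,
PECAM1 for endothelium, COL1A1 for fibroblasts, MZB1 for plasma cells,
MS4A1 for B cells, CD3D for T cells, FCGR3B for neutrophils, TPSAB1 for
mast cells, LYZ/CD68 for MPs, LILRA4 for pDCs; MARCO/APOE for
macrophages, FCN1 for monocytes, LAMP3 for mature DCs, CLEC9A for cDC1,
CD1C for cDC2), each extended to 3–4 genes. They can be overridden from
YAML. The raw cluster count is data- and resolution-dependent and is
never asserted.

## Ro/e tissue preference

For the observed count table O over types × groups, the expectation
under independence is the chi-squared formula E(i,j) = row_i · col_j /
N, and R<sub>o/e</sub>(i,j) = O/E. By construction Σ_j R·E recovers
the row totals, and E matches any standard chi-squared contingency
routine to 1e-9 (this is asserted against an independent implementation
in the tests). A strict R > 1 is called a preference — a ratio of
exactly 1 is not — and no multiplicity correction is applied to the
per-entry calls; a global chi-squared p-value is reported alongside for
context. Entries in a zero row or column have undefined expectation
and are reported as missing, never imputed as 0 (a silent zero would
fake a depletion). Group tables pool cells across a group's samples;
averaging per-sample ratios instead is a caller-side option by passing
per-sample contingency tables.

## Module scores and group comparisons

The score of gene set S in a cell is mean(S) − mean(controls), with
controls drawn per set gene from its average-expression bin (25 bins,
50 controls per gene by default), excluding set genes; if a bin
contains only set genes the pool widens to neighboring bins. On a
constant matrix every score is exactly 0, and adding a constant to all
genes moves mean scores by < 0.05 (location invariance via control
matching). The packaged M1 set (CXCL9, CXCL10, IL1B, TNF, CD80, CD86,
NOS2, IL6) and M2 set (MRC1, CD163, MSR1, CCL22, IL10, TGFB1) are
canonical polarization programs and can be replaced from GMT.

Group summaries report mean/sd/n per entity, a z-score of the entity
means across entities (all 0 when the means do not vary), and one
shared test: Welch's t-test for two groups (the pooled-variance Student
form is available by flag), one-way ANOVA for three or more. Stars
follow the strict thresholds *P* < 0.05 / 0.01 / 0.001. Type-I error
of both tests is verified at the nominal 5% within [0.03, 0.07] over
1,000 null replicates.

## Differential expression and enrichment

Per-gene two-sided Wilcoxon rank-sum (exact for tiny tie-free samples,
otherwise the normal approximation with tie correction; the continuity
correction is disabled so identical groups yield exactly p = 1),
Benjamini–Hochberg step-up q-values, and volcano classification (up:
log2fc ≥ cut and q < q_cut; down symmetric; defaults |log2fc| ≥ 1,
q < 0.05). Means enter the fold change on the pre-log normalized scale
(expm1 of the stored log1p values) with pseudocount 1, the usual
single-cell convention — computing folds on log-scale means would
compress a planted 8-fold into ~1.5-fold. Over-representation uses the
upper-tail hypergeometric test of the query against each set,
intersected with a declared universe (all detected genes by default),
BH across sets. The packaged 30-set "toy pathway" collection is a
self-contained stand-in exercising the machinery; live GO/KEGG term
lists are deliberately out of scope.

## Ligand–receptor screening

score(pair) = min over ligand-complex members of the sender mean ×
min over receptor-complex members of the receiver mean, on the
normalized scale (the min rule lets one silent subunit nullify a
complex — the CellPhoneDB-family convention; the underlying study names
no LR method, so the simplest defensible one is implemented and
declared). Significance: sender/receiver labels are shuffled jointly
n_perm times and p = (1 + #{permuted ≥ observed}) / (n_perm + 1), so
p ∈ [1/(n_perm+1), 1] and the null rejection rate is calibrated (checked
at 5% within [0.02, 0.08]). The packaged mini database carries the
pairs relevant to tumor→MP signaling (EFNA1–EPHA2/EPHB2, SAA1–FPR2,
APP–FPR2, CXCL14–CXCR4, APP–TREM2, HLA-F–VSIR, and others). **Note:**
PGE2 is a lipid, not a transcript; the PGE2–PTGER axis is represented
by the synthase proxy pair PTGES–PTGER4.

## Synthetic cohort generator

The generator emulates a 10-sample cohort (3 `NOR`, 3 `RUNX3_Neg`,
4 `RUNX3_Pos`; 500 cells per sample by default) with a planted type
tree. Generative model per cell: a type path drawn from its sample's
group composition — by default via exact largest-remainder allocation
(`exact_proportions=True`), so planted compositions are realized
exactly and composition-recovery results are not hostage to sampling
noise; multinomial draws are available for studying that noise. Per
gene: a log-normal baseline mean (log-mean −0.5, log-sd 1.0 → a median
of ~0.6 counts per cell and ~10³ counts per cell over 1,000 genes).
Marker genes instead receive a fixed baseline of 1.0 counts per cell:
canonical markers are reliably expressed transcripts, and drawing their
baselines from the background lottery would occasionally produce
"markers" at 0.05 counts that no method could see. Markers are
multiplied by their population's fold (default 8) in that population
and all its descendants. Counts are negative-binomial with shared
dispersion θ = 10 (variance μ + μ²/10, i.e. α = 0.1, typical of
droplet UMI data) and a per-cell log-normal library factor (log-sd
0.3). All draws flow from one root generator seeded by a single
integer.

The planted group compositions encode directions, not magnitudes (no
cohort proportions are available to calibrate against): fibroblasts are
the only type above their cohort-wide expected share in `RUNX3_Pos`;
club/ciliated/plasma/B cells, neutrophils, mast cells and pDCs sit
above it in `RUNX3_Neg`; T cells and MPs sit below it in both tumor
groups. In the MP tree, macrophages are depleted in `RUNX3_Neg` and
enriched in `RUNX3_Pos` with monocytes mirrored, mature DCs and cDC2
enriched in both tumor groups and cDC1 depleted; among macrophage
states FABP4 is depleted in tumors, CXCL10/SELENOP/SPP1/STMN1 enriched,
and AZU1 split (up in `RUNX3_Pos`, down in `RUNX3_Neg`). Margins to
the weighted cross-group mean are kept ≥ ~0.006 so the sign pattern is
well determined at the 5,000-cell study scale. `planted_roe` computes
the ratio each (type, group) would attain at infinite sample size by
plugging the composition directly into the O/E formula; it is the truth
oracle for recovery tests.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, UMI saturation, transcriptome-wide co-expression structure,
per-sample biological variability beyond composition, or
within-population expression gradients between tissue groups. Passing
recovery tests therefore demonstrates that the pipeline's logic is
correct under a clean marker-driven mixture — not that it is robust to
every artifact of real tissue data. In particular, group-level DE on
synthetic cohorts reflects composition shifts only, so volcano plots
from `run-all` on synthetic data are sparse by design.

## Problem sizes and numerical choices

Recovery checks run the three flat scenarios at 5,000 cells
(13 / 5 / 6 types, marker fold 8, fixed seeds) and require all planted
types recovered with adjusted Rand index ≥ 0.9; end-to-end
orchestration runs the nested `full` scenario at smaller cell counts,
where byte-identical reruns are asserted via the manifest's sha256
hashes. Degenerate inputs are pinned by convention: z-score of a
zero-variance gene is 0, a structureless matrix yields one cluster,
assignment ties break lexicographically and are flagged, undefined Ro/e
entries stay missing, and BH q-values are capped at 1.

## Known limitations

- Marker references and M1/M2 sets are packaged conveniences, not a
  validated atlas; real analyses should supply study-specific panels.
- The Ro/e preference call is a descriptive threshold without
  uncertainty quantification; compositional-data models (CLR,
  Dirichlet-multinomial) are out of scope.
- The LR score ignores cell-fraction thresholds and signaling-network
  context (no CellChat/NicheNet-style inference).
- ORA runs against packaged toy collections; term-level conclusions
  about real pathways require real databases.
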