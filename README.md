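# sctme

Compositional analysis of the tumor microenvironment (TME) from
single-cell RNA-seq, built around the workflow of an NSCLC study that
stratifies patients by RUNX3 immunohistochemistry: cancer and
adjacent-normal tissues fall into three groups (`NOR`, `RUNX3_Neg`,
`RUNX3_Pos`), and the question is which cell types each tissue group
preferentially accumulates or loses, and how the myeloid compartment
reorganizes.

The package is aimed at computational biologists who want the whole
chain as tested, reusable pieces:

- **IHC scoring** (`sctme.ihc`) — the semiquantitative composite score:
  percentage-positivity points (<10% → 0, 10–50% → 1, >50% → 2) plus
  staining-intensity points (no/weak → 0, moderate → 1, strong → 2);
  composite 0–2 → RUNX3-negative, 3–4 → RUNX3-positive.
- **Hierarchical marker annotation** (`sctme.annotate`) — counts are
  normalized (counts-per-10⁴, log1p), clustered (PCA + kNN + Leiden),
  and each cluster is assigned the type whose markers it expresses most
  highly, at three nested levels: 13 major types, 5 mononuclear-phagocyte
  (MP) subtypes, and the six-gene macrophage classification
  (AZU1/CXCL10/FABP4/SELENOP/SPP1/STMN1).
- **Ro/e tissue preference** (`sctme.roe`) — for the cell-count table
  O(i,j) over types × tissue groups, the chi-squared expectation is
  E(i,j) = row_i·col_j / N and the enrichment ratio R = O/E;
  R<sub>o/e</sub> > 1 (strictly) marks a preference of type *i* for
  tissue *j*, R < 1 a depletion.
- **M1/M2 module scores** (`sctme.scoring`) — control-matched gene-set
  scores (set mean minus expression-bin-matched control mean) for the
  classically/alternatively activated macrophage programs, summarized
  per group with t-test/ANOVA and the usual significance stars.
- **DE + over-representation** (`sctme.de`) — per-gene Wilcoxon
  rank-sum with BH correction and volcano classification; upper-tail
  hypergeometric enrichment against packaged toy pathway collections.
- **Ligand–receptor screening** (`sctme.lr`) — mean-expression products
  (min over complex members) with a label-permutation null.
- **Synthetic cohorts** (`sctme.simulate`) — a negative-binomial
  generator with planted hierarchical cell types and group-specific
  composition shifts, so every stage above is testable without any
  external download.

## Worked example

Score three specimens, then simulate the 13-type cohort (10 samples,
5,000 cells), annotate it, and compute tissue preferences:

```python
import numpy as np
from sctme import annotate, ihc, roe, simulate

for s in ihc.score_and_group([("P1", 60, "strong"),
                              ("P2", 30, "moderate"),
                              ("P3", 8, "weak")]):
    print(s.specimen_id, s.overall_score, s.group)
# P1 4 RUNX3_Pos
# P2 2 RUNX3_Neg
# P3 0 RUNX3_Neg

cfg = simulate.default_config("major13", seed=1)
dataset = simulate.simulate_dataset(cfg)
norm = annotate.normalize_log(dataset.adata)
labels = annotate.cluster_cells(norm, seed=1)
ref = annotate.load_marker_reference("major")
mapping = annotate.assign_types(annotate.score_cluster_types(norm, labels, ref))
assigned = np.array([mapping.loc[c, "type"] for c in labels])

annot = dataset.truth.assign(major_type=assigned)
table = roe.roe(roe.contingency(annot, "major_type", "group"))
preferred, _ = roe.preference_calls(table)
print(table.ratio.round(2).loc[["Fibroblasts", "MPs", "TCells"]])
print("preferred in RUNX3_Pos:", list(preferred.index[preferred["RUNX3_Pos"]]))
```

```
group         NOR  RUNX3_Neg  RUNX3_Pos
major_type
Fibroblasts  0.19       0.61       1.90
MPs          1.59       0.58       0.87
TCells       1.44       0.68       0.91
```

`preferred in RUNX3_Pos: ['Fibroblasts']` — fibroblasts are the only
type with R<sub>o/e</sub> > 1 in RUNX3-positive tumor tissue, while MPs
and T cells sit below their expected counts in both tumor groups; these
are exactly the composition shifts the generator plants, recovered
through the full normalize → cluster → score → assign pipeline (14 raw
clusters mapping onto all 13 planted types).

The same stages are available from the shell:

```bash
sctme simulate --scenario major13 --seed 1 --out data/
sctme annotate --counts data/ --meta data/truth.tsv --out annot.tsv --seed 1
sctme roe --annot annot.tsv --type-field major_type --out roe/
sctme run-all --scenario full --seed 1 --out run/   # everything + manifest
```

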