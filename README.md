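# circsig

Pan-cancer circular RNA (circRNA) expression signature analysis for paired
tumor/normal RNA-seq cohorts. The package takes CIRCexplorer2-style
back-splice junction calls, per-sample mapped-read totals and gene-level
FPKM/count matrices, and produces:

- **Quantification** — back-spliced reads per million mapped reads
  (RPM = back-spliced × 10⁶ / mapped reads), junction ratios
  (back-spliced / forward-spliced reads; > 0.5 means the circle outnumbers
  its linear counterpart), support filtering, genomic-origin labels
  (CDS / UTR / complete CDS / intronic / intergenic), isoform diversity per
  host gene, and flanking-intron length / repeat content.
- **Tissue specificity** — the tissue-specificity index over n tissues,
  TSI = Σᵢ (1 − xᵢ/x_max) / (n − 1), computed on per-tissue median
  expression over normal samples; TSI ≤ 0.3 is ubiquitous, TSI ≥ 0.85
  tissue-specific.
- **Differential expression** — a negative-binomial Wald test per cancer
  type (median-of-ratios size factors, method-of-moments dispersion, paired
  design with patient covariates, Benjamini–Hochberg adjustment); features
  are called up/down when adjusted p < 0.05 **and** fold change > 2.
- **Attribution** — Pearson correlation (strong at r ≥ 0.7) of circRNAs
  against host genes and a panel of RNA-binding proteins (RBPs), plus
  binding-peak overlap in the introns flanking the back-splice site, to
  decide whether a circRNA's specificity or dysregulation tracks its host
  gene or an RBP.
- **Signatures** — integration of per-cancer DE tables into cancer-specific
  (one cancer) vs. shared (≥ 2) circRNAs, shared entries split into
  consistent / inconsistent direction, with a ≥ 4-cancer tier and a
  heatmap-ready signed matrix.

A fully seeded synthetic-cohort generator (`circsig.synthetic_data`)
produces paired tumor/normal junction counts, gene expression, a toy gene
annotation and complete ground-truth tables, so that every stage is
testable without any sequencing data.

## Worked example

```python
from circsig import SimConfig, simulate_cohort, PipelineConfig, tsi
from circsig.quantify import rpm_matrix
from circsig.specificity import tsi_pipeline
from circsig.diffexpr import de_per_cancer
from circsig.signatures import classify_signatures, summarize_signatures
import pandas as pd

print(tsi([10, 5, 0, 0, 0]))          # 0.875  (one dominant tissue of five)

cohort = simulate_cohort(SimConfig(rng_seed=1))   # 7 tissues x 10 patients, paired
rpm = rpm_matrix(cohort.junctions)
cats = tsi_pipeline(rpm, 0.1, PipelineConfig())
print(cats["category"].value_counts().to_dict())

de = de_per_cancer(cohort.junctions)
summary, _ = summarize_signatures(
    classify_signatures(pd.concat(de.values(), ignore_index=True))
)
print(summary)
```

prints (seed 1):

```
0.875
{'ubiquitous': 443, 'intermediate': 193, 'tissue_specific': 175}
{'n_total': 189, 'n_cancer_specific': 176, 'n_shared': 13,
 'n_shared_ge4': 8, 'n_consistent': 8, 'n_inconsistent': 5}
```

i.e. of 189 circRNAs dysregulated anywhere, 176 are altered in exactly one
cancer, 13 in two or more (8 of those in ≥ 4 cancers), and the shared ones
split into 8 with a uniform fold-change direction and 5 with mixed
directions.

The same pipeline is scriptable from a shell:

```
circsig simulate --out cohort/ --seed 1
circsig quantify --back cohort/circ_back_counts.tsv \
                 --forward cohort/circ_forward_counts.tsv \
                 --meta cohort/samples.tsv --out quant/
circsig tsi --expr quant/circ_rpm.tsv --meta cohort/samples.tsv --out tsi.tsv
circsig de  --counts cohort/circ_back_counts.tsv --meta cohort/samples.tsv --out de/
circsig classify --de-table de/de_all.tsv --out signatures/
```

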