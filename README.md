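# tn5shadow

**Detection and correction of Tn5 open-chromatin bias in bulk and
single-cell CUT&Tag data.**

CUT&Tag uses a protein A–Tn5 transposase fusion to tagment DNA at
antibody-marked chromatin.  Tn5, however, prefers accessible DNA: some
reads are generated at open chromatin regardless of the targeted histone
mark, so a repressive mark like H3K27me3 acquires false signal precisely
at active gene promoters.  `tn5shadow` corrects this artifact by using a
matched ATAC-seq sample — a direct readout of the same Tn5 accessibility
preference — as a covariate.

The package is aimed at epigenomics analysts working with histone-mark
CUT&Tag (bulk replicates or sparse single-cell matrices) who need
bias-aware signal tracks and cell clusterings.

## Method at a glance

For every 200 bp genomic bin, the local signal shape is summarized as the
10 bp-resolution mean RPM coverage over the 1 kb window centered on the
bin (reads extended 146 bp from their 5' ends), giving 100 features per
assay.  An elastic-net logistic regression

&nbsp;&nbsp;&nbsp;&nbsp;P(true mark | x) = σ(wᵀ·z(x) + b),&nbsp;&nbsp;
x = [CUT&Tag profile, ATAC profile] ∈ ℝ²⁰⁰,

with l1_ratio = 0.5 and z-scored features, is trained on benchmark bins
curated from orthogonal biology: a true repressive bin lies at a
non-expressed gene with zero conjugate acetyl-mark reads and recurs
across samples; a false bin lies at a highly expressed gene under a
conjugate-mark peak.  Applied genome-wide, the per-bin probability is the
corrected signal (scores < 0.5 can be floored to 0 for browsers).
Single-cell matrices are first densified by meta-cell smoothing (each
cell plus its 10 nearest embedding neighbours), then scored per cell with
the bulk-trained model.

Evaluation is biology-informed rather than ChIP-referenced: Pearson
correlation of the corrected score with gene expression over promoter
bins, with the reciprocal conjugate mark over covered bins, and a
TSS ± 300 bp vs 300 bp–3 kb center/flank enrichment diagnostic.  See
`docs/methods.md` for the full model description and the synthetic study
conditions.

## Worked example

The package ships a self-contained simulator, so the whole workflow runs
offline:

```bash
tn5shadow simulate --seed 3 --beta 0.5 --out-dir fixture/
tn5shadow curate --mark-class repressive \
    --candidates fixture/cuttag_rep0.peaks.bed \
    --candidates fixture/cuttag_rep1.peaks.bed \
    --genes fixture/genes.bed --expression fixture/expression.tsv \
    --chrom-sizes fixture/genome.chrom.sizes \
    --conjugate-reads fixture/conjugate.bed \
    --conjugate-peaks fixture/conjugate.peaks.bed \
    --n-top-expressed 30 --recurrence-min 2 --out labels.bed
tn5shadow train --labels labels.bed \
    --cuttag fixture/cuttag_rep0.bed --cuttag fixture/cuttag_rep1.bed \
    --atac fixture/atac.bed --chrom-sizes fixture/genome.chrom.sizes \
    --seed 1 --out model.tn5shadow
tn5shadow correct --model model.tn5shadow \
    --cuttag fixture/cuttag_rep0.bed --atac fixture/atac.bed \
    --chrom-sizes fixture/genome.chrom.sizes --out scores.bedgraph
tn5shadow evaluate --scores scores.bedgraph \
    --genes fixture/genes.bed --expression fixture/expression.tsv \
    --chrom-sizes fixture/genome.chrom.sizes --out report.tsv
```

The curate step prints

```
curated 300 true / 120 false bins -> labels.bed
```

— the simulator plants 30 repressive domains (10 bins each) at
non-expressed genes and 30 accessible promoters (4 bins each) at the most
expressed genes, and the rules recover exactly those.  The final step
prints

```
promoter-bin correlation with expression: r = -0.349
```

a strongly negative correlation, as a repressive mark should show; the
same uncorrected RPM signal reaches only r ≈ −0.07 because bias reads at
active promoters mask the anticorrelation.  `correct` also writes
`scores.bedgraph.floored` with sub-0.5 scores zeroed for browser display.

For single cells, `tn5shadow sc-correct` consumes an MTX triplet plus an
embedding TSV and emits the corrected score matrix;
`tn5shadow sc-cluster` clusters either matrix (PCA + k-means) and reports
the adjusted Rand index against ground-truth labels when present.

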