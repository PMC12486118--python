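# Methods

## The problem

CUT&Tag profiles histone modifications by tethering a protein A–Tn5 fusion
to an antibody against the target mark; Tn5 then tagments nearby DNA.
Because Tn5 itself prefers nucleosome-free, accessible chromatin, a
fraction of reads is generated at open regions regardless of where the
targeted mark actually sits.  For a repressive mark such as H3K27me3 this
produces conspicuous false signal at active gene promoters — loci where
the mark cannot biologically occur.  The artifact survives protocol-level
mitigations (high-salt washes) and is amplified in sparse single-cell
data, where a handful of biased reads can dominate a cell's profile.

`tn5shadow` treats the artifact as a classification problem.  For every
200 bp genomic bin it asks: given the local CUT&Tag signal shape *and*
the local ATAC-seq signal shape (ATAC-seq being a direct readout of the
same Tn5 accessibility preference), is the observed CUT&Tag signal a
genuine mark or an open-chromatin shadow?  The corrected track is the
per-bin probability of a genuine mark.

## Signal model

Mapped reads (BED, one row per read; MAPQ/duplicate filtering assumed
upstream) are extended 146 bp from their 5' end — one nucleosomal
footprint — piled up per base pair, and normalized to reads per million
(RPM).  The genome is tiled into non-overlapping 200 bp bins on a fixed
grid (trailing partial bins dropped; analysis restricted to autosome-like
included chromosomes — chrM/chrX/chrY excluded by default).  A bin's
feature vector is the 10 bp-resolution mean coverage over the 1 kb window
centered on the bin (100 values per signal role), concatenated across
roles in the fixed order (CUT&Tag, ATAC, IgG), optionally followed by the
flattened 200x4 one-hot DNA sequence of the bin.  The production
configuration uses CUT&Tag + ATAC only (200 features): in benchmarking,
IgG and sequence features do not improve the correlation-based metrics,
and sequence preference is largely implicit in the ATAC covariate.

Window values are means, not sums, so feature scale is independent of the
step size; the choice is recorded in the recipe that travels with every
trained model.  Bin "center" of a 200 bp bin is start + 100; the window is
[center − 500, center + 500), zero-padded at chromosome ends.

## Benchmark curation

Ground-truth labels come from orthogonal biology rather than from a
reference assay:

* **Repressive rule family** (H3K27me3-style).  TRUE bins overlap the
  promoter (TSS ± 1 kb) or body of a non-expressed gene (0 RPKM), contain
  zero conjugate acetyl-mark reads in every conjugate sample, and recur in
  at least `recurrence_min` of the CUT&Tag samples (production-scale
  default 14 of 17).  FALSE bins overlap the promoter/body of a top-expressed
  gene (top 8,032 by default, sized to match the non-expressed set) and
  overlap a conjugate-mark peak.
* **Active rule family** (H3K27ac-style).  TRUE bins sit in promoters/
  bodies of top-expressed genes with zero repressive reads within
  ± 500 bp; FALSE bins sit at non-expressed genes and overlap a
  repressive peak.
* **Heterochromatin rule family** (H3K9me3-style).  Operates on
  variable-width peak regions: TRUE regions have ≥ 5 reads in *every*
  same-mark sample, stay clear of top-expressed gene bodies ± 10 kb, and
  contain zero acetyl reads; FALSE regions violate the gene-distance rule
  and carry ≥ 5 reads in *any* acetyl sample.  Surviving regions are
  split onto the 200 bp grid.

All overlaps use the ≥ 1 bp convention on half-open coordinates.
Candidate bins snap to the global 200 bp grid so recurrence counting is
well defined across samples.  Bins qualifying as both TRUE and FALSE are
dropped and counted in the result's provenance.

## Classifier

The production model is logistic regression with an elastic-net penalty
(mixing parameter l1_ratio = 0.5, saga solver, up to 10,000 iterations,
inverse regularization strength C = 1.0).  Features are z-scored with
statistics computed on the training rows; the statistics are stored in
the model file because elastic-net penalties are scale-sensitive and
prediction must reuse the training standardization.  Signal patterns from
different CUT&Tag samples over the same bin are independent training
rows; shared ATAC/IgG blocks are reused across samples.  Random-forest
(100 trees) and gradient-boosting baselines are available behind the same
interface; a registry allows further model families to be added.
Generalization is reported as stratified 5-fold cross-validation
accuracy, with fold-internal standardization.  Non-convergence raises a
warning and is flagged in the model provenance.

Prediction covers every genome-tiling bin and yields scores in [0, 1].
Both the raw score track and a floored track (scores < 0.5 set to 0, the
browser-visualization convention) can be emitted.  Model files are
versioned pickles; loading verifies the format marker and version and a
round trip reproduces predictions bit-identically.

## Evaluation

Because a ChIP-style reference is deliberately not treated as truth,
evaluation uses biology-informed correlations: (i) Pearson r between
per-bin scores and the expression of the gene whose promoter (TSS ± 1 kb)
the bin occupies — repressive marks should be negative, active marks
positive; a bin inside several promoter windows is assigned the gene with
the nearest TSS, ties to the higher-expressed gene; (ii) Pearson r
against the reciprocal conjugate mark's signal over read-covered bins
(eligibility: ≥ 1 read in ≥ m samples; 6 of 17 at production scale); (iii) a
macs2-style comparator that scores each bin with the fold enrichment of
an overlapping peak (max over overlaps) or 0.  The promoter diagnostic
summarizes a track by mean signal at TSS ± 300 bp versus 300 bp–3 kb
flanks, pooled over a gene set; log2(center/flank) > 0 at ubiquitously
expressed promoters (top 1,000 genes by minimum cross-cell-type
expression) flags open-chromatin bias for a repressive mark.  Group
comparisons wrap the one-sided Wilcoxon signed-rank and rank-sum tests.

## Single-cell correction

Sparse cells × 200 bp-bin count matrices are smoothed with a meta-cell
rule: each cell's counts are summed with its 10 nearest neighbours
(Euclidean distance in a supplied low-dimensional embedding, ties broken
by cell index; 11 cells total).  Smoothed counts become a per-cell
pseudo-track — counts are RPM-normalized against the cell's smoothed
total and smeared as 146 bp reads over their bin — from which window
profiles are extracted; the shared bulk ATAC track supplies the covariate
block, and the bulk-trained model scores every candidate bin in every
cell.  Candidate bins default to the top bins by cross-cell variance
(deterministic tie-break by coordinate).  Clustering is PCA (50
components) followed by k-means (10 restarts, fixed seed) with k set to
the number of ground-truth cell types, scored by adjusted Rand index.
Count matrices are depth-normalized and log1p-transformed before PCA;
corrected score matrices are clustered as-is.  The uncorrected baseline
in all comparisons is the normalized **raw** count matrix — the corrected
arm includes meta-cell smoothing as an integral pipeline step, matching
how the correction is deployed.

## Synthetic study conditions

The generator builds a 2 × 2 Mb genome with 120 genes on a uniform
200 bp-aligned grid (gene bodies 10 kb; slots sized so no gene's widest
rule window — body ± 10 kb — reaches a neighbour's planted intervals).
35% of genes are non-expressed; the rest draw log-normal expression
(mean 2, sigma 1 on the log scale) with a 3-cell-type expression table
(per-type log-normal jitter, sigma 0.25) for ubiquitous-gene selection.
Thirty non-expressed genes host planted repressive domains (2 kb,
spanning promoter and 5' body).  Every expressed gene's promoter gets an
accessible interval (800 bp around the TSS) with log-normal per-promoter
strength (sigma 0.75, independent of expression); the accessible
promoters of the 30 most-expressed genes are the planted false-candidate
regions.  The accessibility distribution leaks a small per-bp weight
(0.08 relative to a typical promoter) into repressed domains — closed
chromatin is closed only relatively — while the acetyl-mark occupancy
used for conjugate assays has no leak.  Without this structure the
fixture is degenerate: ATAC alone would separate the training classes,
the classifier could ignore CUT&Tag entirely, and zero-signal bins would
score near 1.

Bias is a mixture at the insertion level: each CUT&Tag 5' position is
drawn from the mark distribution with probability 1 − β and from the
accessibility distribution with probability β, plus a uniform background
(0.2% of reads by default); ATAC samples accessibility + background, IgG
background only, and a ChIP-style reference is the β = 0 assay.  Bulk
depth is 1e5 reads per sample.  Candidate peak files are derived from
the truth intervals with the fold enrichment their sampling density
implies (so curation and comparator tests are independent of peak-caller
noise); accessible intervals always appear as CUT&Tag candidates, with
fold enrichment 0 when β = 0.

Curation-recovery experiments use clean sampling (background fraction 0):
the read-exclusivity filters are presence/absence tests, and uniform
background would fail bins at the Poisson rate of chance hits rather
than exercising the rules.  The promoter diagnostic instead runs at
depth 3e5 with 30% background for both arms, because the center/flank
ratio needs well-conditioned flank coverage.

Single-cell fixtures sample 3 × 50 cells at 150 reads per cell
(Poisson-jittered), with per-cell openness multipliers (log-normal,
sigma 0.6) modulating the effective bias fraction.  Cell type A carries
a distinct third of the repressive domains; types B and C share the rest
except for one exclusive domain each, so their distinction is fragile
under bias and sparsity — by construction, the regime where correction
matters.  The confounded fixture uses β = 0.8.  The embedding consumed
by the smoother is fabricated as PCA coordinates of the noiseless type
profiles plus unit Gaussian jitter (scaled so neighbours are type-pure),
standing in for an upstream LSI/PCA pipeline.

What the fixture does **not** emulate: nucleosome positioning, Tn5
sequence-level cleavage preference (a different bias), PCR duplicates,
batch effects, or peak-caller noise.  Passing tests therefore demonstrate
that the statistical machinery recovers a planted insertion-level bias
under controlled conditions, not that any particular real dataset is
bias-free after correction.

## Numerical choices and degenerate inputs

Pearson correlations raise on zero-variance input and require ≥ 3 pairs.
Constant features pass through standardization untouched (SD treated
as 1).  Empty fragment collections cannot be RPM-normalized and raise.
Window profiles zero-pad beyond chromosome ends.  bedGraph output merges
adjacent equal-value intervals and round-trips exactly.  Cells with zero
smoothed counts are scored from all-zero features (a constant,
intercept-driven score).  All stochastic components (simulation,
training, clustering) are seeded; identical seeds give byte-identical
outputs.

## Problem sizes

The default study conditions (4 Mb genome, 20,000 genome bins, 1e5 reads
per bulk sample, 840 training rows, 150 cells, 10 sampling replicates for
the correlation and clustering experiments) were chosen so the entire
test suite and the reproduction script each complete in a few minutes on
one CPU while leaving every recovery margin wide.

## Known limitations

The corrected score is a probability, not a quantitative occupancy level;
downstream peak calling on the score track is out of scope.  The
heterochromatin rule family labels variable-width regions and splits them
to bins afterwards, which can slightly blur region boundaries.  The
single-cell pseudo-track is piecewise-constant at 200 bp resolution, so
its window profiles are coarser than the bulk profiles the model was
trained on; standardization absorbs most of the scale mismatch, but
per-cell scores near the decision boundary are less calibrated than bulk
scores.  Deep-learning model families are not implemented; the registry
exists so they can be added behind the same interface.
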