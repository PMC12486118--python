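"""Self-contained fixture generator: toy genome, genes, planted regions,
and fragment sampling with tunable open-chromatin bias.

The bias mechanism is a mixture at the insertion level: each CUT&Tag read's
5' position is drawn from the mark-occupancy distribution with probability
``1 - beta`` and from the chromatin-accessibility distribution with
probability ``beta`` (plus a small uniform background), so ``beta`` is the
single knob every recovery test sweeps.  ATAC-seq reads follow
accessibility + background; IgG follows background only; a ChIP-style
reference uses ``beta = 0``.

The reference genome couples regulation and chromatin the way the real
assays assume: expressed genes get accessible promoters (where biased
CUT&Tag reads pile up), a subset of non-expressed genes hosts the planted
true-mark regions (spanning promoter and 5' gene body, as repressive
domains do), and the accessible promoters of the most expressed genes are
the planted false-candidate regions.  All planted intervals sit on the
200 bp tiling grid so bin-level recovery is exact, and truth classes never
overlap.

Peak files are derived from the truth intervals rather than realized reads:
candidate peaks for a CUT&Tag assay are the union of mark and accessible
intervals, annotated with the fold enrichment their sampling density implies
at the requested ``beta``.  This keeps curation and comparator tests
independent of peak-caller noise: at ``beta = 0`` an accessible interval
still appears as a candidate but carries fold enrichment 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .groundtruth import ExpressionTable, GeneAnnotation
from .singlecell import CellBinMatrix, CellEmbedding
from .tracks import (
    FragmentCollection,
    GenomeLayout,
    GenomicBin,
    tile_genome,
)

READ_LENGTH = 50
EXTENSION_BP = 146


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Defaults give a 2 x 2 Mb toy genome with 200 genes and 1e5 reads per
    bulk sample, small enough that every downstream test runs in seconds.
    ``background_fraction`` is kept low (0.2% of reads uniform) so that the
    read-exclusivity curation filters measure rule logic rather than the
    Poisson rate of chance background hits; see the methods note.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 120
    fraction_nonexpressed: float = 0.35
    gene_body_bp: int = 10_000
    n_true_regions: int = 30
    true_region_bp: int = 2_000
    n_false_candidate_regions: int = 30
    accessible_bp: int = 800
    promoter_weight_sigma: float = 0.75
    closed_leak: float = 0.08
    background_fraction: float = 0.002
    depth: int = 100_000
    n_samples: int = 3
    # single-cell conditions
    n_cell_types: int = 3
    n_cells_per_type: int = 50
    per_cell_depth: int = 150
    sc_openness_sigma: float = 0.6
    embedding_dim: int = 10
    expression_celltypes: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_nonexpressed <= 1:
            raise ValueError("fraction_nonexpressed must be in [0, 1]")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must be in [0, 1]")
        if self.depth <= 0 or self.per_cell_depth <= 0:
            raise ValueError("depths must be > 0")


@dataclass
class TruthBundle:
    """Everything the generator knows: genome, genes, planted intervals.

    Regenerable bit-identically from (config, seed); every interval table
    has columns chrom/start/end.
    """

    cfg: SimulationConfig
    layout: GenomeLayout
    annotation: GeneAnnotation
    expression: ExpressionTable
    expression_by_celltype: pd.DataFrame
    true_mark_regions: pd.DataFrame  # planted repressive-mark intervals
    accessible_regions: pd.DataFrame  # accessible promoters (with weight col)
    false_candidate_regions: pd.DataFrame  # accessible promoters of top genes
    accessibility_weights: pd.DataFrame = None  # atac/bias sampling intervals
    active_mark_weights: pd.DataFrame = None  # acetyl-mark sampling intervals
    marked_gene_ids: list = field(default_factory=list)
    sc_type_region_indices: list = field(default_factory=list)

    def true_bins(self, width: int = 200) -> list[GenomicBin]:
        return _intervals_to_bins(self.true_mark_regions, width)

    def false_bins(self, width: int = 200) -> list[GenomicBin]:
        return _intervals_to_bins(self.false_candidate_regions, width)

    def sc_type_regions(self, t: int) -> pd.DataFrame:
        return self.true_mark_regions.iloc[self.sc_type_region_indices[t]]

    def labeled_bins(self, width: int = 200):
        """Planted truth as a LabeledBinSet (true mark bins vs accessible
        false-candidate bins) for training/evaluation oracles."""
        from .groundtruth import LabeledBinSet

        tb = self.true_bins(width)
        fb = self.false_bins(width)
        return LabeledBinSet(
            bins=pd.DataFrame(
                {
                    "chrom": [b.chrom for b in tb + fb],
                    "start": [b.start for b in tb + fb],
                    "width": width,
                    "label": [1] * len(tb) + [0] * len(fb),
                    "recurrence": 1,
                }
            ),
            provenance={"source": "planted-truth"},
        )

    def genome_sequences(self) -> dict[str, str]:
        """Deterministic random DNA for the layout (for sequence features)."""
        rng = np.random.default_rng(self.cfg.seed + 777)
        out = {}
        for chrom in self.layout.chrom_names:
            n = self.layout.length_of(chrom)
            out[chrom] = "".join(
                np.array(["A", "C", "G", "T"])[rng.integers(0, 4, n)]
            )
        return out


def _intervals_to_bins(intervals: pd.DataFrame, width: int) -> list[GenomicBin]:
    bins = []
    for chrom, s, e in zip(intervals["chrom"], intervals["start"], intervals["end"]):
        for b in range((s // width) * width, e, width):
            bins.append(GenomicBin(chrom, b, width))
    return bins


def simulate_reference(cfg: SimulationConfig) -> TruthBundle:
    """Build the toy genome: genes, expression, planted truth intervals.

    Genes sit on a uniform grid (one slot per gene, 200 bp-aligned) so that
    promoters, bodies and planted intervals of different genes never
    overlap.  Expression is zero-inflated log-normal.  Planted true-mark
    intervals span the promoter and 5' body of marked non-expressed genes;
    accessible intervals are symmetric around every expressed gene's TSS.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom_names = tuple(f"chr{i + 1}" for i in range(cfg.n_chroms))
    layout = GenomeLayout(
        chrom_names=chrom_names,
        chrom_lengths=tuple([cfg.chrom_length] * cfg.n_chroms),
        included_chroms=chrom_names,
    )
    genes_per_chrom = cfg.n_genes // cfg.n_chroms
    slot = cfg.chrom_length // (genes_per_chrom + 1)
    # neighbouring genes must stay clear of each other's widest rule window
    # (gene body +/- 10 kb in the heterochromatin rule) plus planted intervals
    margin = 10_000 + cfg.true_region_bp
    if slot < cfg.gene_body_bp + margin:
        raise ValueError(
            "genes cannot be placed without overlap: increase chrom_length or "
            "reduce n_genes / gene_body_bp"
        )
    rows = []
    gid = 0
    for chrom in chrom_names:
        for j in range(genes_per_chrom):
            start = ((j + 1) * slot // 200) * 200
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{gid:04d}", chrom, start, start + cfg.gene_body_bp, strand))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    annotation = GeneAnnotation(genes)
    n_nonexpr = round(cfg.fraction_nonexpressed * len(genes))
    ids = genes["gene_id"].to_numpy()
    nonexpr_ids = rng.choice(ids, size=n_nonexpr, replace=False)
    base = np.zeros(len(genes))
    expressed_mask = ~np.isin(ids, nonexpr_ids)
    base[expressed_mask] = rng.lognormal(mean=2.0, sigma=1.0, size=expressed_mask.sum())
    expression = ExpressionTable(
        pd.Series(base, index=ids), source_label="synthetic-rnaseq"
    )
    # multi-cell-type table: shared base with mild per-type jitter; zeros stay zero
    by_type = {}
    for t in range(cfg.expression_celltypes):
        jitter = rng.lognormal(mean=0.0, sigma=0.25, size=len(genes))
        by_type[f"celltype{t}"] = base * jitter
    expression_by_celltype = pd.DataFrame(by_type, index=ids)

    tss = annotation.tss()
    # planted true-mark regions on a subset of non-expressed genes
    if cfg.n_true_regions > n_nonexpr:
        raise ValueError("n_true_regions exceeds the number of non-expressed genes")
    marked_ids = sorted(nonexpr_ids)[: cfg.n_true_regions]
    mark_rows = []
    for g in marked_ids:
        row = genes[genes["gene_id"] == g].iloc[0]
        t = int(tss[g])
        if row["strand"] == "+":
            s = t - 600
            e = s + cfg.true_region_bp
        else:
            e = t + 600 + 200
            s = e - cfg.true_region_bp
        s = (s // 200) * 200
        mark_rows.append((row["chrom"], s, s + cfg.true_region_bp))
    true_mark = pd.DataFrame(mark_rows, columns=["chrom", "start", "end"])
    # accessible promoters at every expressed gene; per-promoter strength is
    # log-normal, independent of transcript level, so neither signal alone
    # separates marked from accessible bins cleanly
    acc_rows = []
    expressed_ids = ids[expressed_mask]
    half_acc = cfg.accessible_bp // 2
    for g in expressed_ids:
        row = genes[genes["gene_id"] == g].iloc[0]
        t = int(tss[g])
        s = ((t - half_acc) // 200) * 200
        acc_rows.append((row["chrom"], s, s + cfg.accessible_bp))
    accessible = pd.DataFrame(acc_rows, columns=["chrom", "start", "end"])
    accessible["weight"] = rng.lognormal(
        mean=0.0, sigma=cfg.promoter_weight_sigma, size=len(accessible)
    )
    # false candidates: accessible promoters of the top-expressed genes
    order = np.argsort(-base[expressed_mask], kind="stable")
    top_ids = expressed_ids[order[: cfg.n_false_candidate_regions]]
    top_mask = np.isin(expressed_ids, top_ids)
    false_candidates = accessible[top_mask].reset_index(drop=True)
    _assert_disjoint(true_mark, accessible)
    # Tn5 sees repressed chromatin as closed but not sealed: the
    # accessibility distribution leaks a small per-bp weight into the mark
    # intervals, while the acetyl (active-mark) occupancy does not
    leak = true_mark.copy()
    leak["weight"] = cfg.closed_leak
    accessibility_weights = pd.concat(
        [accessible[["chrom", "start", "end", "weight"]], leak], ignore_index=True
    )
    active_mark_weights = accessible[["chrom", "start", "end", "weight"]].copy()
    # single-cell: partition true regions into one distinct type and two
    # closely related types whose repressive domains differ by a single
    # region each, so the fine distinction is fragile under bias + sparsity
    n = cfg.n_true_regions
    n_a = max(1, n // 3)
    idx = list(range(n))
    type_a = idx[:n_a]
    shared_bc = idx[n_a : n - 2]
    b_excl = [idx[n - 2]]
    c_excl = [idx[n - 1]]
    sc_types = [type_a, shared_bc + b_excl, shared_bc + c_excl]
    return TruthBundle(
        cfg=cfg,
        layout=layout,
        annotation=annotation,
        expression=expression,
        expression_by_celltype=expression_by_celltype,
        true_mark_regions=true_mark,
        accessible_regions=accessible,
        false_candidate_regions=false_candidates,
        accessibility_weights=accessibility_weights,
        active_mark_weights=active_mark_weights,
        marked_gene_ids=list(marked_ids),
        sc_type_region_indices=sc_types[: cfg.n_cell_types],
    )


def _assert_disjoint(a: pd.DataFrame, b: pd.DataFrame) -> None:
    for chrom in set(a["chrom"]):
        ai = a[a["chrom"] == chrom]
        bi = b[b["chrom"] == chrom]
        for s, e in zip(ai["start"], ai["end"]):
            if ((bi["start"] < e) & (bi["end"] > s)).any():
                raise ValueError(
                    "planted truth classes overlap; adjust gene spacing"
                )


ASSAYS = ("cuttag_repressive", "cuttag_active", "atac", "igg", "chip_reference")


def _interval_sampler(intervals: pd.DataFrame, rng, n: int, genome_bp_shift: int):
    """Sample n 5'-end positions over the intervals, uniform within each
    interval, across intervals proportional to length x per-bp weight; the
    position is shifted so the 146 bp extension is centered on it."""
    lengths = (intervals["end"] - intervals["start"]).to_numpy()
    mass = lengths.astype(float)
    if "weight" in intervals.columns:
        mass = mass * intervals["weight"].to_numpy()
    which = rng.choice(len(intervals), size=n, p=mass / mass.sum())
    offsets = rng.integers(0, lengths[which])
    pos = intervals["start"].to_numpy()[which] + offsets - genome_bp_shift
    return intervals["chrom"].to_numpy()[which], np.maximum(pos, 0)


def simulate_bulk(
    bundle: TruthBundle,
    assay: str,
    beta: float = 0.0,
    depth: int | None = None,
    seed: int = 0,
    source_label: str | None = None,
    background_fraction: float | None = None,
) -> tuple[FragmentCollection, pd.DataFrame]:
    """Sample a bulk fragment set and its truth-derived candidate peak file.

    CUT&Tag 5' positions follow (1 - beta) x mark + beta x accessibility
    + background; ATAC follows accessibility + background; IgG background
    only; the ChIP-style reference is the matching CUT&Tag assay at
    beta = 0.  Peaks carry a ``fold_enrichment`` column computed from the
    sampling densities actually used.  ``background_fraction`` overrides the
    config default (set 0 for clean-sampling curation fixtures).
    """
    cfg = bundle.cfg
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; known: {ASSAYS}")
    depth = cfg.depth if depth is None else depth
    if depth < 100:
        import warnings

        warnings.warn("depth < 100: sampled statistics will be meaningless")
    rng = np.random.default_rng(seed)
    p_bg = cfg.background_fraction if background_fraction is None else background_fraction
    if assay == "cuttag_repressive":
        mark_iv, acc_iv = bundle.true_mark_regions, bundle.accessibility_weights
        p_mark = (1 - p_bg) * (1 - beta)
        p_acc = (1 - p_bg) * beta
    elif assay == "cuttag_active":
        # the active mark occupies acetylated promoters (no leak into
        # repressed domains); its bias component still follows accessibility
        mark_iv, acc_iv = bundle.active_mark_weights, bundle.accessibility_weights
        p_mark = (1 - p_bg) * (1 - beta)
        p_acc = (1 - p_bg) * beta
    elif assay == "atac":
        mark_iv, acc_iv = None, bundle.accessibility_weights
        p_mark, p_acc = 0.0, 1 - p_bg
    elif assay == "igg":
        mark_iv, acc_iv = None, None
        p_mark = p_acc = 0.0
        p_bg = 1.0
    else:  # chip_reference
        mark_iv, acc_iv = bundle.true_mark_regions, None
        p_mark, p_acc = 1 - p_bg, 0.0
    n_bg, n_acc, n_mark = rng.multinomial(depth, [p_bg, p_acc, p_mark])
    half = EXTENSION_BP // 2
    chroms_parts, pos_parts = [], []
    if n_mark and mark_iv is not None:
        c, p = _interval_sampler(mark_iv, rng, n_mark, half)
        chroms_parts.append(c)
        pos_parts.append(p)
    if n_acc and acc_iv is not None:
        c, p = _interval_sampler(acc_iv, rng, n_acc, half)
        chroms_parts.append(c)
        pos_parts.append(p)
    if n_bg:
        genome_bp = sum(bundle.layout.chrom_lengths)
        raw = rng.integers(0, genome_bp - EXTENSION_BP, size=n_bg)
        bounds = np.cumsum(bundle.layout.chrom_lengths)
        which = np.searchsorted(bounds, raw, side="right")
        offset = raw - np.concatenate([[0], bounds[:-1]])[which]
        chroms_parts.append(np.array(bundle.layout.chrom_names)[which])
        pos_parts.append(offset)
    if chroms_parts:
        chroms = np.concatenate(chroms_parts)
        pos = np.concatenate(pos_parts)
    else:
        chroms = np.array([], dtype=str)
        pos = np.array([], dtype=int)
    lengths = dict(zip(bundle.layout.chrom_names, bundle.layout.chrom_lengths))
    max_pos = np.array([lengths[c] for c in chroms]) - READ_LENGTH if len(chroms) else pos
    pos = np.minimum(pos, max_pos)
    records = pd.DataFrame(
        {
            "chrom": chroms,
            "start": pos.astype(int),
            "end": pos.astype(int) + READ_LENGTH,
            "strand": "+",
        }
    )
    records = records.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    frags = FragmentCollection(
        records=records,
        total_count=len(records),
        source_label=source_label or f"{assay}-seed{seed}",
    )
    peaks = _truth_peaks(bundle, assay, p_mark, p_acc, p_bg, mark_iv, acc_iv)
    return frags, peaks


def _truth_peaks(bundle, assay, p_mark, p_acc, p_bg, mark_iv, acc_iv) -> pd.DataFrame:
    genome_bp = sum(bundle.layout.chrom_lengths)
    bg_density = p_bg / genome_bp if p_bg > 0 else 1.0 / genome_bp
    rows = []
    seen = set()

    def add(intervals, p_class):
        if intervals is None or len(intervals) == 0:
            return
        lengths = (intervals["end"] - intervals["start"]).to_numpy().astype(float)
        weights = (
            intervals["weight"].to_numpy().astype(float)
            if "weight" in intervals.columns
            else np.ones(len(intervals))
        )
        total_mass = float((lengths * weights).sum())
        # per-bp sampling density of each interval, relative to background
        fes = (p_class * weights / total_mass) / bg_density if total_mass else weights * 0
        for chrom, s, e, fe in zip(
            intervals["chrom"], intervals["start"], intervals["end"], fes
        ):
            key = (chrom, int(s), int(e))
            if key not in seen:
                seen.add(key)
                rows.append((chrom, int(s), int(e), "peak", float(fe)))

    add(mark_iv, p_mark)
    add(acc_iv, p_acc)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "fold_enrichment"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in peaks.iterrows():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r['name']}\t{r.fold_enrichment:g}\n")


def simulate_cells(
    bundle: TruthBundle,
    beta: float = 0.6,
    n_cells_per_type: int | None = None,
    per_cell_depth: int | None = None,
    seed: int = 0,
    background_fraction: float | None = None,
) -> tuple[CellBinMatrix, CellEmbedding, np.ndarray]:
    """Sample a cells x 200 bp-bin count matrix with type-specific marks.

    All cell types share the accessibility landscape (the confounder); each
    type carries its own subset of the planted mark regions, with two types
    sharing most of theirs so that, under strong bias and sparse counts,
    uncorrected profiles struggle to separate them.  Per-cell openness is
    jittered (log-normal) so the bias axis varies between cells of the same
    type.  The embedding fabricates an upstream dimension-reduction output:
    PCA coordinates of the noiseless type profiles plus Gaussian jitter.
    """
    cfg = bundle.cfg
    n_per = cfg.n_cells_per_type if n_cells_per_type is None else n_cells_per_type
    depth = cfg.per_cell_depth if per_cell_depth is None else per_cell_depth
    if depth < 50:
        import warnings

        warnings.warn("per_cell_depth < 50: cells will be nearly empty")
    p_bg = cfg.background_fraction if background_fraction is None else background_fraction
    rng = np.random.default_rng(seed)
    bins = tile_genome(bundle.layout, 200)
    width = 200
    bin_index: dict[tuple[str, int], int] = {
        (b.chrom, b.start): i for i, b in enumerate(bins)
    }
    chrom_nbins = {c: bundle.layout.length_of(c) // width for c in bundle.layout.included_chroms}
    chrom_offset = {}
    off = 0
    for c in bundle.layout.included_chroms:
        chrom_offset[c] = off
        off += chrom_nbins[c]

    def interval_bin_weights(intervals: pd.DataFrame) -> np.ndarray:
        w = np.zeros(len(bins))
        weights = (
            intervals["weight"].to_numpy()
            if "weight" in intervals.columns
            else np.ones(len(intervals))
        )
        for chrom, s, e, wt in zip(
            intervals["chrom"], intervals["start"], intervals["end"], weights
        ):
            for b in range((s // width) * width, e, width):
                i = bin_index.get((chrom, b))
                if i is not None:
                    w[i] += wt * (min(e, b + width) - max(s, b))
        total = w.sum()
        return w / total if total else w

    acc_w = interval_bin_weights(bundle.accessibility_weights)
    type_w = [
        interval_bin_weights(bundle.sc_type_regions(t)) for t in range(cfg.n_cell_types)
    ]
    n_cells = n_per * cfg.n_cell_types
    labels = np.repeat([f"type{t}" for t in range(cfg.n_cell_types)], n_per)
    bg_w = np.full(len(bins), 1.0 / len(bins))
    rows_ij, cols_ij, data_ij = [], [], []
    for c in range(n_cells):
        t = c // n_per
        openness = rng.lognormal(mean=0.0, sigma=cfg.sc_openness_sigma)
        b_eff = beta * openness / (beta * openness + (1 - beta))
        d_c = max(20, int(rng.poisson(depth)))
        p = p_bg * bg_w + (1 - p_bg) * (b_eff * acc_w + (1 - b_eff) * type_w[t])
        counts = rng.multinomial(d_c, p / p.sum())
        nz = np.nonzero(counts)[0]
        rows_ij.extend([c] * len(nz))
        cols_ij.extend(nz.tolist())
        data_ij.extend(counts[nz].tolist())
    matrix = sparse.csr_matrix(
        (data_ij, (rows_ij, cols_ij)), shape=(n_cells, len(bins))
    )
    barcodes = [f"cell{c:04d}" for c in range(n_cells)]
    # fabricated embedding: PCA of the noiseless per-type mean profiles
    mean_profiles = np.stack(
        [
            p_bg * bg_w + (1 - p_bg) * (0.5 * beta * acc_w + (1 - 0.5 * beta) * type_w[t])
            for t in range(cfg.n_cell_types)
        ]
    )
    centered = mean_profiles - mean_profiles.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    centroids = u * s  # n_types x n_types coordinates
    d = cfg.embedding_dim
    coords = rng.normal(0.0, 1.0, size=(n_cells, d))
    scale = 25.0 / max(np.abs(centroids).max(), 1e-12)
    for c in range(n_cells):
        t = c // n_per
        coords[c, : centroids.shape[1]] += centroids[t] * scale
    emb = CellEmbedding(coords=coords, source_label="synthetic-pca")
    mat = CellBinMatrix(matrix=matrix, barcodes=barcodes, bins=bins, labels=labels)
    return mat, emb, labels
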