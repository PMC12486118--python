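"""Curation of true/false marked 200 bp benchmark regions for a histone mark.

The benchmark exploits two pieces of orthogonal biology:

* expression logic — a repressive mark (H3K27me3, H3K9me3) should sit on
  non-expressed genes, an active mark (H3K27ac) on highly expressed ones;
* reciprocal conjugate exclusivity — methylation and acetylation of the same
  histone residue cannot co-occur on one nucleosome in a homogeneous
  population, so e.g. a candidate H3K27me3 bin containing any H3K27ac read
  is suspect.

Three rule families are implemented, one per mark class:
``curate_repressive`` (H3K27me3-style, recurrence across samples),
``curate_active`` (H3K27ac-style, flanking-window read exclusion) and
``curate_heterochromatin`` (H3K9me3-style, per-sample read-count thresholds
on variable-width peak regions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tracks import (
    DEFAULT_BIN_WIDTH,
    FragmentCollection,
    GenomeLayout,
    GenomicBin,
    count_overlapping_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class GeneAnnotation:
    """Gene bodies with strand-aware TSS; promoter = TSS +/- flank."""

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if not required.issubset(self.genes.columns):
            raise ValueError(f"gene table must have columns {sorted(required)}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")

    def tss(self) -> pd.Series:
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "-", g["end"] - 1, g["start"]),
            index=g["gene_id"],
            name="tss",
        )

    def promoters(self, flank: int = 1000) -> pd.DataFrame:
        tss = self.tss().to_numpy()
        return pd.DataFrame(
            {
                "gene_id": self.genes["gene_id"].to_numpy(),
                "chrom": self.genes["chrom"].to_numpy(),
                "start": np.maximum(tss - flank, 0),
                "end": tss + flank,
            }
        )

    def bodies(self, flank: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.genes["gene_id"].to_numpy(),
                "chrom": self.genes["chrom"].to_numpy(),
                "start": np.maximum(self.genes["start"].to_numpy() - flank, 0),
                "end": self.genes["end"].to_numpy() + flank,
            }
        )

    def promoter_or_body(self, promoter_flank: int = 1000) -> pd.DataFrame:
        return pd.concat(
            [self.promoters(promoter_flank), self.bodies()], ignore_index=True
        )

    def subset(self, gene_ids) -> "GeneAnnotation":
        wanted = set(gene_ids)
        return GeneAnnotation(
            self.genes[self.genes["gene_id"].isin(wanted)].reset_index(drop=True)
        )

    @classmethod
    def from_bed(cls, path) -> "GeneAnnotation":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 3, 5],
            names=["chrom", "start", "end", "gene_id", "strand"],
        )
        return cls(df[["gene_id", "chrom", "start", "end", "strand"]])

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for _, r in self.genes.iterrows():
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n"
                )


@dataclass
class ExpressionTable:
    """gene_id -> expression (RPKM or a normalized index); values >= 0."""

    values: pd.Series
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression table")
        if (self.values < 0).any():
            raise ValueError("expression values must be >= 0")

    @classmethod
    def from_tsv(cls, path, source_label: str = "") -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "value"])
        return cls(pd.Series(df["value"].to_numpy(), index=df["gene_id"]), source_label)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", header=False)


@dataclass
class CurationConfig:
    mark_class: str = "repressive_exclusivity"
    promoter_flank: int = 1000
    n_nonexpressed: int | None = None  # None: all zero-expression genes
    n_top_expressed: int = 8032
    recurrence_min: int = 14
    conjugate_read_threshold: int = 0  # any read disqualifies when 0
    flanking_bp: int = 500
    heterochromatin_flank_bp: int = 10000
    min_reads: int = 5
    exclude_chroms: tuple[str, ...] = ("chrM", "chrX", "chrY")

    def __post_init__(self) -> None:
        if self.recurrence_min < 1:
            raise ValueError("recurrence_min must be >= 1")
        if self.min_reads < 0 or self.conjugate_read_threshold < 0:
            raise ValueError("read thresholds must be >= 0")


@dataclass
class LabeledBinSet:
    """200 bp bins labeled true (1) / false (0), with curation provenance."""

    bins: pd.DataFrame  # columns: chrom, start, width, label, recurrence
    n_conflicts_dropped: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "width", "label", "recurrence"}
        if not required.issubset(self.bins.columns):
            raise ValueError(f"bins must have columns {sorted(required)}")
        if not set(self.bins["label"].unique()).issubset({0, 1}):
            raise ValueError("labels must be 0/1")
        dup = self.bins.duplicated(subset=["chrom", "start"])
        if dup.any():
            raise ValueError("a bin may carry only one label")

    @property
    def n_true(self) -> int:
        return int((self.bins["label"] == 1).sum())

    @property
    def n_false(self) -> int:
        return int((self.bins["label"] == 0).sum())

    def total_kb(self, label: int) -> float:
        sel = self.bins[self.bins["label"] == label]
        return float((sel["width"]).sum()) / 1000.0

    def as_bins(self, label: int | None = None) -> list[GenomicBin]:
        sel = self.bins if label is None else self.bins[self.bins["label"] == label]
        return [
            GenomicBin(c, int(s), int(w))
            for c, s, w in zip(sel["chrom"], sel["start"], sel["width"])
        ]

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for _, r in self.bins.iterrows():
                name = "true" if r.label == 1 else "false"
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.start + r.width}\t{name}\t{r.recurrence}\t.\n"
                )

    @classmethod
    def from_bed(cls, path) -> "LabeledBinSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"name": str},  # keep 'true'/'false' literal, not booleans
        )
        return cls(
            pd.DataFrame(
                {
                    "chrom": df["chrom"],
                    "start": df["start"].astype(int),
                    "width": (df["end"] - df["start"]).astype(int),
                    "label": (df["name"].str.lower() == "true").astype(int),
                    "recurrence": df["score"].astype(int),
                }
            )
        )


# ---------------------------------------------------------------------------
# gene-set selection


def pick_gene_sets(expr: ExpressionTable, n: int) -> tuple[set, set]:
    """Zero-expression genes and the n highest-expressed genes.

    Ties in the top set are broken by lexicographic gene id so the selection
    is deterministic.
    """
    values = expr.values
    if len(values) == 0:
        raise ValueError("expression table is empty")
    if n > len(values):
        raise ValueError(f"n={n} exceeds gene count {len(values)}")
    nonexpressed = set(values.index[values == 0])
    if len(nonexpressed) == len(values):
        raise ValueError("all genes have zero expression; top-expressed set undefined")
    df = pd.DataFrame({"gene_id": values.index, "value": values.to_numpy()})
    df = df.sort_values(["value", "gene_id"], ascending=[False, True], kind="stable")
    top = set(df["gene_id"].head(n))
    return nonexpressed, top


def pick_ubiquitous_genes(multi_celltype_expr: pd.DataFrame, n: int = 1000) -> set:
    """Top n genes ranked by their minimum expression across cell types."""
    if multi_celltype_expr.shape[1] < 2:
        raise ValueError("need expression in at least two cell types")
    if n > len(multi_celltype_expr):
        raise ValueError(f"n={n} exceeds gene count {len(multi_celltype_expr)}")
    mins = multi_celltype_expr.min(axis=1)
    df = pd.DataFrame({"gene_id": mins.index, "value": mins.to_numpy()})
    df = df.sort_values(["value", "gene_id"], ascending=[False, True], kind="stable")
    return set(df["gene_id"].head(n))


# ---------------------------------------------------------------------------
# interval helpers


def _merge_intervals(intervals: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, g in intervals.groupby("chrom", sort=False):
        g = g.sort_values("start")
        starts, ends = [], []
        for s, e in zip(g["start"], g["end"]):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def overlaps_any(bins: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each bin overlap (>= 1 bp) any interval?"""
    out = np.zeros(len(bins), dtype=bool)
    if len(intervals) == 0 or len(bins) == 0:
        return out
    merged = _merge_intervals(intervals)
    for chrom, g in bins.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        bs = g["start"].to_numpy()
        be = bs + g["width"].to_numpy() if "width" in g else g["end"].to_numpy()
        idx = np.searchsorted(starts, be, side="left") - 1
        hit = (idx >= 0) & (ends[np.maximum(idx, 0)] > bs)
        out[g.index.to_numpy()] = hit
    return out


def read_peaks_bed(path) -> pd.DataFrame:
    """Peak BED with optional 4th name and 5th fold-enrichment column."""
    df = pd.read_csv(path, sep="\t", header=None)
    cols = ["chrom", "start", "end", "name", "fold_enrichment"]
    df = df.iloc[:, : min(5, df.shape[1])]
    df.columns = cols[: df.shape[1]]
    if "fold_enrichment" in df.columns:
        df["fold_enrichment"] = df["fold_enrichment"].astype(float)
    return df


def candidate_bins_from_peaks(
    peaks: pd.DataFrame,
    width: int = DEFAULT_BIN_WIDTH,
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """200 bp genome-grid bins overlapping any peak by >= 1 bp, deduplicated.

    Bins snap to the global tiling grid (start a multiple of ``width``) so
    candidate bins are comparable across samples; bins extending past a
    chromosome end are dropped when a layout is supplied.
    """
    rows = []
    for chrom, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"]):
        first = (s // width) * width
        last = -(-e // width) * width  # ceil
        for b in range(first, last, width):
            rows.append((chrom, b))
    df = pd.DataFrame(rows, columns=["chrom", "start"]).drop_duplicates()
    df["width"] = width
    if layout is not None:
        keep = df["chrom"].isin(layout.included_chroms)
        lengths = dict(zip(layout.chrom_names, layout.chrom_lengths))
        keep &= (df["start"] + width) <= df["chrom"].map(lengths).fillna(-1)
        df = df[keep]
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _bin_key_frame(bin_sets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Union of per-sample candidate bins with per-bin recurrence counts."""
    if not bin_sets:
        raise ValueError("need at least one sample's candidate bins")
    keyed = [
        b[["chrom", "start", "width"]].drop_duplicates() for b in bin_sets
    ]
    allbins = pd.concat(keyed, ignore_index=True)
    if len(allbins) == 0:
        raise ValueError("candidate bin union is empty")
    rec = (
        allbins.groupby(["chrom", "start", "width"], sort=True)
        .size()
        .reset_index(name="recurrence")
    )
    return rec


def _conjugate_counts(
    bins: pd.DataFrame,
    frag_sets: Sequence[FragmentCollection],
    layout: GenomeLayout | None,
    flank: int = 0,
) -> np.ndarray:
    """Per-bin read counts (rows = bins, cols = samples), bins widened by flank."""
    reg = pd.DataFrame(
        {
            "chrom": bins["chrom"],
            "start": np.maximum(bins["start"] - flank, 0),
            "end": bins["start"] + bins["width"] + flank,
        }
    )
    counts = np.zeros((len(bins), len(frag_sets)), dtype=int)
    for j, frags in enumerate(frag_sets):
        counts[:, j] = count_overlapping_reads(frags, reg, layout=layout)
    return counts


def _finalize(
    bins: pd.DataFrame,
    is_true: np.ndarray,
    is_false: np.ndarray,
    provenance: dict,
) -> LabeledBinSet:
    conflict = is_true & is_false
    n_conflicts = int(conflict.sum())
    if n_conflicts:
        logger.info("dropping %d bins qualifying as both true and false", n_conflicts)
    keep_true = is_true & ~conflict
    keep_false = is_false & ~conflict
    out = bins.loc[keep_true | keep_false].copy()
    out["label"] = np.where(keep_true[keep_true | keep_false], 1, 0)
    out = out.reset_index(drop=True)
    return LabeledBinSet(
        bins=out[["chrom", "start", "width", "label", "recurrence"]],
        n_conflicts_dropped=n_conflicts,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# curation rule families


def curate_repressive(
    candidates_per_sample: Sequence[pd.DataFrame],
    annotation: GeneAnnotation,
    nonexpressed: set,
    top_expressed: set,
    conjugate_frag_sets: Sequence[FragmentCollection],
    conjugate_peak_sets: Sequence[pd.DataFrame],
    cfg: CurationConfig,
    layout: GenomeLayout | None = None,
) -> LabeledBinSet:
    """Repressive-mark (H3K27me3-style) true/false bin curation.

    TRUE: candidate bins overlapping the promoter (TSS +/- flank) or body of
    a non-expressed gene, containing zero conjugate-mark reads in every
    conjugate sample, and recurring in at least ``recurrence_min`` samples.
    FALSE: candidate bins (from any sample) overlapping the promoter/body of
    a top-expressed gene and overlapping a conjugate-mark peak.  Bins
    qualifying for both are dropped and logged.
    """
    if cfg.recurrence_min > len(candidates_per_sample):
        raise ValueError(
            f"recurrence_min={cfg.recurrence_min} exceeds sample count "
            f"{len(candidates_per_sample)}"
        )
    bins = _bin_key_frame(candidates_per_sample)
    nonexpr_iv = annotation.subset(nonexpressed).promoter_or_body(cfg.promoter_flank)
    top_iv = annotation.subset(top_expressed).promoter_or_body(cfg.promoter_flank)
    in_nonexpr = overlaps_any(bins, nonexpr_iv)
    in_top = overlaps_any(bins, top_iv)
    conj_counts = _conjugate_counts(bins, conjugate_frag_sets, layout)
    conj_clean = (conj_counts <= cfg.conjugate_read_threshold).all(axis=1)
    conj_peaks = (
        pd.concat(
            [p[["chrom", "start", "end"]] for p in conjugate_peak_sets],
            ignore_index=True,
        )
        if conjugate_peak_sets
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    in_conj_peak = overlaps_any(bins, conj_peaks)
    is_true = in_nonexpr & conj_clean & (bins["recurrence"].to_numpy() >= cfg.recurrence_min)
    is_false = in_top & in_conj_peak
    return _finalize(
        bins,
        is_true,
        is_false,
        {
            "mark_class": "repressive_exclusivity",
            "n_samples": len(candidates_per_sample),
            "recurrence_min": cfg.recurrence_min,
        },
    )


def curate_active(
    candidates_per_sample: Sequence[pd.DataFrame],
    annotation: GeneAnnotation,
    nonexpressed: set,
    top_expressed: set,
    conjugate_frag_sets: Sequence[FragmentCollection],
    conjugate_peak_sets: Sequence[pd.DataFrame],
    cfg: CurationConfig,
    layout: GenomeLayout | None = None,
) -> LabeledBinSet:
    """Active-mark (H3K27ac-style) curation.

    TRUE: candidate bins in the promoter/body of top-expressed genes with
    zero repressive-mark reads within the bin extended by ``flanking_bp``
    (default +/- 500 bp) in every repressive sample.  FALSE: candidate bins
    in the promoter/body of non-expressed genes that overlap any
    repressive-mark peak.
    """
    bins = _bin_key_frame(candidates_per_sample)
    nonexpr_iv = annotation.subset(nonexpressed).promoter_or_body(cfg.promoter_flank)
    top_iv = annotation.subset(top_expressed).promoter_or_body(cfg.promoter_flank)
    in_nonexpr = overlaps_any(bins, nonexpr_iv)
    in_top = overlaps_any(bins, top_iv)
    conj_counts = _conjugate_counts(
        bins, conjugate_frag_sets, layout, flank=cfg.flanking_bp
    )
    conj_clean = (conj_counts <= cfg.conjugate_read_threshold).all(axis=1)
    conj_peaks = (
        pd.concat(
            [p[["chrom", "start", "end"]] for p in conjugate_peak_sets],
            ignore_index=True,
        )
        if conjugate_peak_sets
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    in_conj_peak = overlaps_any(bins, conj_peaks)
    is_true = in_top & conj_clean
    is_false = in_nonexpr & in_conj_peak
    return _finalize(
        bins,
        is_true,
        is_false,
        {"mark_class": "active_exclusivity", "flanking_bp": cfg.flanking_bp},
    )


def curate_heterochromatin(
    peaks_per_sample: Sequence[pd.DataFrame],
    annotation: GeneAnnotation,
    top_expressed: set,
    same_mark_frag_sets: Sequence[FragmentCollection],
    conjugate_frag_sets: Sequence[FragmentCollection],
    cfg: CurationConfig,
    layout: GenomeLayout | None = None,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> LabeledBinSet:
    """Heterochromatin-mark (H3K9me3-style) curation on peak regions.

    Rules operate on the variable-width peak regions: TRUE regions carry at
    least ``min_reads`` reads in *every* same-mark sample, do not overlap the
    gene body +/- ``heterochromatin_flank_bp`` of any top-expressed gene, and
    contain zero conjugate (acetyl) reads.  FALSE regions overlap a
    top-expressed gene body +/- flank and have >= ``min_reads`` reads in
    *any* conjugate sample.  Surviving regions are then split onto the
    200 bp grid for model training.
    """
    regions = pd.concat(
        [p[["chrom", "start", "end"]] for p in peaks_per_sample], ignore_index=True
    ).drop_duplicates().reset_index(drop=True)
    if len(regions) == 0:
        raise ValueError("peak region union is empty")
    body_iv = annotation.subset(top_expressed).bodies(flank=cfg.heterochromatin_flank_bp)
    reg_bins = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"],
            "end": regions["end"],
            "width": regions["end"] - regions["start"],
        }
    )
    near_active = overlaps_any(reg_bins, body_iv)
    same_counts = np.stack(
        [count_overlapping_reads(f, regions, layout=layout) for f in same_mark_frag_sets],
        axis=1,
    )
    conj_counts = np.stack(
        [count_overlapping_reads(f, regions, layout=layout) for f in conjugate_frag_sets],
        axis=1,
    )
    is_true = (
        (same_counts >= cfg.min_reads).all(axis=1)
        & ~near_active
        & (conj_counts <= cfg.conjugate_read_threshold).all(axis=1)
    )
    is_false = near_active & (conj_counts >= cfg.min_reads).any(axis=1)
    conflict = is_true & is_false
    n_conflicts = int(conflict.sum())
    labeled_rows = []
    for label, mask in ((1, is_true & ~conflict), (0, is_false & ~conflict)):
        sel = regions.loc[mask]
        if len(sel) == 0:
            continue
        b = candidate_bins_from_peaks(sel, width=bin_width, layout=layout)
        b["label"] = label
        labeled_rows.append(b)
    if labeled_rows:
        bins = pd.concat(labeled_rows, ignore_index=True)
        # a grid bin touched by both a true and a false region is ambiguous
        dup = bins.duplicated(subset=["chrom", "start"], keep=False)
        ambiguous = dup & (
            bins.groupby(["chrom", "start"])["label"].transform("nunique") > 1
        )
        n_conflicts += int(ambiguous.sum()) // 2
        bins = bins[~ambiguous].drop_duplicates(subset=["chrom", "start"])
    else:
        bins = pd.DataFrame(columns=["chrom", "start", "width", "label"])
    bins = bins.reset_index(drop=True)
    bins["recurrence"] = len(peaks_per_sample)
    return LabeledBinSet(
        bins=bins[["chrom", "start", "width", "label", "recurrence"]],
        n_conflicts_dropped=n_conflicts,
        provenance={"mark_class": "heterochromatin_counts", "min_reads": cfg.min_reads},
    )
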