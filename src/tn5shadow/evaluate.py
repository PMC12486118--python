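"""Biology-informed evaluation of corrected CUT&Tag signal.

Correlation with ChIP-style references is deliberately avoided; instead the
corrected score is judged by orthogonal biology: a repressive mark should
correlate negatively with gene expression over promoter bins and with its
reciprocal conjugate (acetyl) mark genome-wide, and signal at the promoters
of ubiquitously expressed genes should show no center-over-flank enrichment
unless open-chromatin bias is present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .groundtruth import GeneAnnotation
from .tracks import FragmentCollection, GenomicBin, SignalTrack, count_overlapping_reads


@dataclass
class PromoterBinMap:
    """bins within TSS +/- flank of a gene, with that gene's expression.

    A bin inside several genes' promoter windows is assigned the gene whose
    TSS is nearest the bin center; exact distance ties go to the higher
    expressed gene.
    """

    mapping: pd.DataFrame  # columns: bin_index, chrom, start, gene_id, expression
    flank: int


@dataclass
class EnrichmentSummary:
    center_score: float
    flank_score: float
    log2_ratio: float | None  # None when flank_score == 0

    @property
    def defined(self) -> bool:
        return self.log2_ratio is not None


def build_promoter_bin_map(
    bins: Sequence[GenomicBin],
    annotation: GeneAnnotation,
    expression: pd.Series,
    flank: int = 1000,
) -> PromoterBinMap:
    """Map genome-tiling bins to the gene promoter they fall into."""
    genes = annotation.genes
    tss = annotation.tss()
    rows = []
    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, g in genes.groupby("chrom", sort=False):
        gt = pd.DataFrame(
            {"gene_id": g["gene_id"].to_numpy(), "tss": tss[g["gene_id"]].to_numpy()}
        ).sort_values("tss", kind="stable")
        by_chrom[chrom] = gt
    for i, b in enumerate(bins):
        gt = by_chrom.get(b.chrom)
        if gt is None:
            continue
        positions = gt["tss"].to_numpy()
        center = b.center
        j = np.searchsorted(positions, center)
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < len(positions):
                gene_id = gt["gene_id"].iloc[cand]
                d = abs(int(positions[cand]) - center)
                expr = float(expression.get(gene_id, 0.0))
                key = (d, -expr)
                if best is None or key < best[0]:
                    best = (key, gene_id, int(positions[cand]))
        if best is None:
            continue
        _, gene_id, gtss = best
        # overlap of [start, end) with [tss - flank, tss + flank)
        if gtss - flank < b.end and gtss + flank > b.start:
            rows.append((i, b.chrom, b.start, gene_id, float(expression.get(gene_id, 0.0))))
    return PromoterBinMap(
        mapping=pd.DataFrame(
            rows, columns=["bin_index", "chrom", "start", "gene_id", "expression"]
        ),
        flank=flank,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def corr_with_expression(scores: np.ndarray, pmap: PromoterBinMap) -> float:
    """Pearson r between per-bin score and mapped gene expression."""
    idx = pmap.mapping["bin_index"].to_numpy()
    return _pearson(np.asarray(scores)[idx], pmap.mapping["expression"].to_numpy())


def eligible_bins(
    bins: Sequence[GenomicBin],
    frag_sets: Sequence[FragmentCollection],
    min_reads: int = 1,
    min_samples: int = 1,
    extension_bp: int = 146,
    layout=None,
) -> np.ndarray:
    """Bins with >= min_reads in >= min_samples of the CUT&Tag samples.

    Genome-wide correlations are restricted to read-covered bins; the vast
    unsequenced remainder of the genome would otherwise dominate r.
    """
    hits = np.zeros(len(bins), dtype=int)
    for frags in frag_sets:
        counts = count_overlapping_reads(frags, bins, extension_bp, layout=layout)
        hits += (counts >= min_reads).astype(int)
    return hits >= min_samples


def corr_with_conjugate(
    scores: np.ndarray,
    reference_track: SignalTrack,
    bins: Sequence[GenomicBin],
    eligible: np.ndarray,
) -> float:
    """Pearson r between score and mean conjugate-mark signal over eligible bins."""
    eligible = np.asarray(eligible, dtype=bool)
    if eligible.sum() < 3:
        raise ValueError("fewer than 3 eligible bins")
    ref = np.zeros(len(bins))
    df = pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
        }
    )
    for chrom, g in df.groupby("chrom", sort=False):
        ref[g.index.to_numpy()] = reference_track.interval_mean(
            chrom, g["start"].to_numpy(), g["end"].to_numpy()
        )
    return _pearson(np.asarray(scores)[eligible], ref[eligible])


def macs2_bin_scores(peaks: pd.DataFrame, bins: Sequence[GenomicBin]) -> np.ndarray:
    """Comparator scoring: each bin takes the fold enrichment of an
    overlapping peak (max when several overlap), 0 when none."""
    if "fold_enrichment" not in peaks.columns:
        raise ValueError("peaks need a fold_enrichment column")
    out = np.zeros(len(bins))
    order = {}
    for i, b in enumerate(bins):
        order.setdefault(b.chrom, []).append(i)
    for chrom, idxs in order.items():
        starts = np.array([bins[i].start for i in idxs])
        width = np.array([bins[i].width for i in idxs])
        sub = peaks[peaks["chrom"] == chrom]
        for ps, pe, fe in zip(sub["start"], sub["end"], sub["fold_enrichment"]):
            hit = (starts < pe) & (starts + width > ps)
            sel = np.asarray(idxs)[hit]
            out[sel] = np.maximum(out[sel], fe)
    return out


def promoter_enrichment(
    track: SignalTrack,
    gene_ids,
    annotation: GeneAnnotation,
    center_bp: int = 300,
    flank_outer_bp: int = 3000,
) -> EnrichmentSummary:
    """Mean signal at TSS +/- center_bp versus the flanking 300 bp-3 kb.

    Pooled over the gene set, strand-agnostic.  A log2 center/flank ratio
    above 0 for a repressive mark at ubiquitously expressed promoters flags
    open-chromatin bias.
    """
    sub = annotation.subset(gene_ids)
    if len(sub.genes) == 0:
        raise ValueError("empty gene set")
    tss = sub.tss()
    center_sum = center_n = flank_sum = flank_n = 0.0
    for gene_id, chrom in zip(sub.genes["gene_id"], sub.genes["chrom"]):
        if chrom not in track.values:
            continue
        t = int(tss[gene_id])
        center_sum += float(track.interval_sum(chrom, [t - center_bp], [t + center_bp])[0])
        center_n += 2 * center_bp
        flank_sum += float(
            track.interval_sum(chrom, [t - flank_outer_bp], [t - center_bp])[0]
            + track.interval_sum(chrom, [t + center_bp], [t + flank_outer_bp])[0]
        )
        flank_n += 2 * (flank_outer_bp - center_bp)
    center = center_sum / center_n if center_n else 0.0
    flank = flank_sum / flank_n if flank_n else 0.0
    ratio = float(np.log2(center / flank)) if flank > 0 and center > 0 else None
    return EnrichmentSummary(center_score=center, flank_score=flank, log2_ratio=ratio)


def tss_profile_matrix(
    track: SignalTrack,
    annotation: GeneAnnotation,
    gene_ids=None,
    flank: int = 3000,
    step: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Strand-oriented genes x positions mean-signal matrix around the TSS.

    Minus-strand profiles are reversed so column 0 is always the upstream
    edge.  Returns (matrix, column means).
    """
    sub = annotation if gene_ids is None else annotation.subset(gene_ids)
    tss = sub.tss()
    n_steps = 2 * flank // step
    mat = np.zeros((len(sub.genes), n_steps))
    offsets = np.arange(n_steps) * step
    for row, (gene_id, chrom, strand) in enumerate(
        zip(sub.genes["gene_id"], sub.genes["chrom"], sub.genes["strand"])
    ):
        if chrom not in track.values:
            continue
        t = int(tss[gene_id])
        starts = t - flank + offsets
        vals = track.interval_sum(chrom, starts, starts + step) / step
        mat[row] = vals[::-1] if strand == "-" else vals
    return mat, mat.mean(axis=0)


def compare_groups(
    values_a,
    values_b,
    test: str = "rank_sum_one_sided",
    alternative: str = "less",
):
    """One-sided Wilcoxon tests (library-backed plumbing).

    ``alternative`` follows the scipy convention for ``values_a`` relative to
    ``values_b``; the default tests whether *a* is shifted below *b*.
    Returns (statistic, p-value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "signed_rank_one_sided":
        if len(a) != len(b):
            raise ValueError("signed-rank test requires paired samples")
        if np.all(a == b):
            raise ValueError("all paired differences are zero")
        res = stats.wilcoxon(a, b, alternative=alternative)
    elif test == "rank_sum_one_sided":
        if len(set(a) | set(b)) == 1:
            raise ValueError("all observations tied")
        res = stats.mannwhitneyu(a, b, alternative=alternative)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
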