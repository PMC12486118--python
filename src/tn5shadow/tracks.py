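"""Fragment I/O, read-extension pileups, genome tiling and window profiles.

CUT&Tag and ATAC-seq mapped reads arrive as BED records (one row per read,
upstream MAPQ/duplicate filtering assumed done).  Each read is extended from
its 5' end to a fixed length (146 bp, one nucleosomal footprint), piled up
per base pair and depth-normalized to reads-per-million (RPM).  Analysis
operates on a fixed 200 bp genome tiling; the model features are
10 bp-resolution mean-coverage profiles over the 1 kb window centered on a
bin.

All coordinates are 0-based half-open (BED native), internally and in every
emitted file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

DEFAULT_EXTENSION_BP = 146
DEFAULT_BIN_WIDTH = 200
DEFAULT_EXCLUDE_CHROMS = ("chrM", "chrX", "chrY")


class GenomicBin(NamedTuple):
    """A half-open genomic interval [start, start + width) on the tiling grid."""

    chrom: str
    start: int
    width: int = DEFAULT_BIN_WIDTH

    @property
    def end(self) -> int:
        return self.start + self.width

    @property
    def center(self) -> int:
        return self.start + self.width // 2


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths and the subset included in the analysis.

    Sex chromosomes and the mitochondrial contig are excluded by default:
    chromatin-state analysis is restricted to autosomes to avoid confounding
    from X inactivation, and mtDNA reads are artifacts of the assay.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    included_chroms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")
        unknown = set(self.included_chroms) - set(self.chrom_names)
        if unknown:
            raise ValueError(f"included_chroms not in chrom_names: {sorted(unknown)}")
        if len(set(self.included_chroms)) != len(self.included_chroms):
            raise ValueError("duplicate included chromosomes")

    @classmethod
    def from_dict(
        cls,
        sizes: dict[str, int],
        exclude: Sequence[str] = DEFAULT_EXCLUDE_CHROMS,
    ) -> "GenomeLayout":
        names = tuple(sizes)
        lengths = tuple(int(sizes[c]) for c in names)
        included = tuple(c for c in names if c not in set(exclude))
        return cls(names, lengths, included)

    @classmethod
    def from_chrom_sizes(
        cls, path, exclude: Sequence[str] = DEFAULT_EXCLUDE_CHROMS
    ) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls.from_dict(dict(zip(df["chrom"], df["length"].astype(int))), exclude)

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_names.index(chrom)]

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for c, l in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{c}\t{l}\n")


@dataclass
class FragmentCollection:
    """Post-filter mapped read/fragment records on a named genome.

    ``records`` holds one row per read with columns chrom/start/end/strand;
    strand is '+', '-' or '.' (unknown, treated as '+' for 5'-end purposes).
    """

    records: pd.DataFrame
    total_count: int
    source_label: str = ""

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "strand"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(required)}")
        if self.total_count != len(self.records):
            raise ValueError("total_count does not match number of records")

    def per_chrom_counts(self) -> dict[str, int]:
        return self.records.groupby("chrom", sort=False).size().to_dict()

    def five_prime_positions(self) -> np.ndarray:
        """0-based position of each record's 5' end."""
        start = self.records["start"].to_numpy()
        end = self.records["end"].to_numpy()
        neg = (self.records["strand"] == "-").to_numpy()
        return np.where(neg, end - 1, start)

    def extended_intervals(
        self, extension_bp: int = DEFAULT_EXTENSION_BP, layout: GenomeLayout | None = None
    ) -> pd.DataFrame:
        """Half-open intervals covered by each read extended from its 5' end.

        Plus-strand (and unknown-strand) reads extend rightward from ``start``;
        minus-strand reads extend leftward from ``end - 1``.  Intervals are
        clipped at 0 and, when a layout is given, at chromosome ends.
        """
        p5 = self.five_prime_positions()
        neg = (self.records["strand"] == "-").to_numpy()
        starts = np.where(neg, p5 - extension_bp + 1, p5)
        ends = starts + extension_bp
        starts = np.maximum(starts, 0)
        if layout is not None:
            lengths = self.records["chrom"].map(
                dict(zip(layout.chrom_names, layout.chrom_lengths))
            ).to_numpy()
            ends = np.minimum(ends, lengths)
        out = pd.DataFrame(
            {"chrom": self.records["chrom"].to_numpy(), "start": starts, "end": ends}
        )
        return out[out["end"] > out["start"]].reset_index(drop=True)


class BedParseError(ValueError):
    pass


def load_fragments(
    path,
    layout: GenomeLayout | None = None,
    drop_chroms: Sequence[str] = DEFAULT_EXCLUDE_CHROMS,
    on_unknown_chrom: str = "skip",
    source_label: str | None = None,
) -> FragmentCollection:
    """Read a mapped-reads BED file into a :class:`FragmentCollection`.

    Records on ``drop_chroms`` (mtDNA, sex chromosomes by default) are
    removed.  ``on_unknown_chrom`` controls records on chromosomes absent
    from ``layout``: ``"skip"`` drops them with a warning, ``"error"``
    raises.  Record order is preserved.
    """
    if on_unknown_chrom not in ("skip", "error"):
        raise ValueError("on_unknown_chrom must be 'skip' or 'error'")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if not 0 <= start < end:
                raise BedParseError(
                    f"{path}: line {lineno}: require 0 <= start < end, got {start},{end}"
                )
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            rows.append((parts[0], start, end, strand))
    if rows:
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    else:
        df = pd.DataFrame(columns=["chrom", "start", "end", "strand"]).astype(
            {"start": int, "end": int}
        )
    df = df[~df["chrom"].isin(set(drop_chroms))]
    if layout is not None:
        known = df["chrom"].isin(set(layout.included_chroms))
        if not known.all():
            bad = sorted(df.loc[~known, "chrom"].unique())
            if on_unknown_chrom == "error":
                raise BedParseError(f"{path}: records on unknown chromosomes {bad}")
            import warnings

            warnings.warn(f"{path}: skipping records on chromosomes {bad}")
            df = df[known]
        lengths = dict(zip(layout.chrom_names, layout.chrom_lengths))
        too_long = df["end"].to_numpy() > df["chrom"].map(lengths).to_numpy()
        if too_long.any():
            raise BedParseError(f"{path}: {int(too_long.sum())} records extend past chromosome end")
    df = df.reset_index(drop=True)
    return FragmentCollection(
        records=df, total_count=len(df), source_label=source_label or str(path)
    )


@dataclass
class SignalTrack:
    """Per-bp RPM-normalized coverage of 5'-extended reads.

    ``values[chrom]`` is a float array of length ``chrom_length``.  Raw
    coverage adds 1 per read over ``extension_bp`` positions; values are then
    divided by ``total_count / 1e6``.
    """

    values: dict[str, np.ndarray]
    layout: GenomeLayout
    normalization_factor: float
    extension_bp: int = DEFAULT_EXTENSION_BP
    _cumsums: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def cumsum(self, chrom: str) -> np.ndarray:
        """Padded cumulative sum used for O(1) interval sums."""
        cs = self._cumsums.get(chrom)
        if cs is None:
            cs = np.concatenate([[0.0], np.cumsum(self.values[chrom])])
            self._cumsums[chrom] = cs
        return cs

    def interval_sum(self, chrom: str, starts, ends) -> np.ndarray:
        """Sum of per-bp coverage over [start, end); out-of-chromosome bp count 0."""
        cs = self.cumsum(chrom)
        n = len(self.values[chrom])
        s = np.clip(np.asarray(starts), 0, n)
        e = np.clip(np.asarray(ends), 0, n)
        e = np.maximum(e, s)
        return cs[e] - cs[s]

    def interval_mean(self, chrom: str, starts, ends) -> np.ndarray:
        """Mean per-bp coverage over [start, end), zero-padding outside the chromosome."""
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        width = ends - starts
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.interval_sum(chrom, starts, ends) / width
        return np.where(width > 0, out, 0.0)


def build_signal_track(
    frags: FragmentCollection,
    layout: GenomeLayout,
    extension_bp: int = DEFAULT_EXTENSION_BP,
) -> SignalTrack:
    """Pile up 5'-extended reads and normalize to reads-per-million."""
    if frags.total_count == 0:
        raise ValueError("cannot RPM-normalize an empty fragment collection")
    norm = frags.total_count / 1e6
    values: dict[str, np.ndarray] = {}
    ext = frags.extended_intervals(extension_bp, layout=layout)
    grouped = {c: g for c, g in ext.groupby("chrom", sort=False)}
    for chrom in layout.included_chroms:
        n = layout.length_of(chrom)
        diff = np.zeros(n + 1)
        g = grouped.get(chrom)
        if g is not None:
            np.add.at(diff, g["start"].to_numpy(), 1.0)
            np.add.at(diff, g["end"].to_numpy(), -1.0)
        values[chrom] = np.cumsum(diff[:-1]) / norm
    return SignalTrack(
        values=values, layout=layout, normalization_factor=norm, extension_bp=extension_bp
    )


def tile_genome(layout: GenomeLayout, width: int = DEFAULT_BIN_WIDTH) -> list[GenomicBin]:
    """Non-overlapping half-open bins on the global grid; trailing partial bins dropped."""
    if width <= 0:
        raise ValueError("width must be > 0")
    bins: list[GenomicBin] = []
    for chrom in layout.included_chroms:
        n_full = layout.length_of(chrom) // width
        bins.extend(GenomicBin(chrom, i * width, width) for i in range(n_full))
    return bins


def bins_to_frame(bins: Sequence[GenomicBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
        }
    )


def window_profile(
    track: SignalTrack,
    bin: GenomicBin,
    window_bp: int = 1000,
    step_bp: int = 10,
) -> np.ndarray:
    """10 bp-resolution mean-coverage profile over the window centered on a bin.

    Returns ``window_bp / step_bp`` values; value *i* is the mean per-bp
    coverage over step *i* of the window ``[center - window_bp/2,
    center + window_bp/2)``.  Positions outside the chromosome contribute 0.
    """
    return window_profiles(track, [bin], window_bp, step_bp)[0]


def window_profiles(
    track: SignalTrack,
    bins: Sequence[GenomicBin],
    window_bp: int = 1000,
    step_bp: int = 10,
) -> np.ndarray:
    """Vectorized :func:`window_profile` over many bins (rows align with input)."""
    if window_bp % step_bp != 0:
        raise ValueError("window_bp must be divisible by step_bp")
    n_steps = window_bp // step_bp
    out = np.zeros((len(bins), n_steps))
    if not bins:
        return out
    df = bins_to_frame(bins)
    df["center"] = [b.center for b in bins]
    offsets = np.arange(n_steps) * step_bp
    for chrom, g in df.groupby("chrom", sort=False):
        win_start = g["center"].to_numpy()[:, None] - window_bp // 2 + offsets[None, :]
        sums = track.interval_sum(chrom, win_start.ravel(), (win_start + step_bp).ravel())
        out[g.index.to_numpy()] = sums.reshape(len(g), n_steps) / step_bp
    return out


def bin_means(track: SignalTrack, bins: Sequence[GenomicBin]) -> np.ndarray:
    """Mean per-bp normalized coverage inside each bin (the raw RPM signal
    per bin, used as the uncorrected comparator)."""
    out = np.zeros(len(bins))
    df = bins_to_frame(bins)
    for chrom, g in df.groupby("chrom", sort=False):
        if chrom not in track.values:
            continue
        out[g.index.to_numpy()] = track.interval_mean(
            chrom, g["start"].to_numpy(), g["end"].to_numpy()
        )
    return out


def count_overlapping_reads(
    frags: FragmentCollection,
    regions: Sequence[GenomicBin] | pd.DataFrame,
    extension_bp: int = DEFAULT_EXTENSION_BP,
    layout: GenomeLayout | None = None,
) -> np.ndarray:
    """Number of 5'-extended reads overlapping each region by >= 1 bp.

    Matches the BEDtools at-least-1-bp overlap convention on half-open
    intervals.  Runs in O((n + m) log n) via sorted endpoint searches.
    """
    if isinstance(regions, pd.DataFrame):
        reg = regions[["chrom", "start", "end"]].reset_index(drop=True)
    else:
        reg = bins_to_frame(list(regions))
    counts = np.zeros(len(reg), dtype=int)
    if frags.total_count == 0 or len(reg) == 0:
        return counts
    ext = frags.extended_intervals(extension_bp, layout=layout)
    by_chrom = {c: g for c, g in ext.groupby("chrom", sort=False)}
    for chrom, g in reg.groupby("chrom", sort=False):
        reads = by_chrom.get(chrom)
        if reads is None:
            continue
        starts = np.sort(reads["start"].to_numpy())
        ends = np.sort(reads["end"].to_numpy())
        n = len(starts)
        # overlap iff read.start < region.end and read.end > region.start
        n_end_before = np.searchsorted(ends, g["start"].to_numpy(), side="right")
        n_start_after = n - np.searchsorted(starts, g["end"].to_numpy(), side="left")
        counts[g.index.to_numpy()] = n - n_end_before - n_start_after
    return counts


def write_bedgraph(bins: Sequence[GenomicBin] | pd.DataFrame, values, path) -> None:
    """Write per-bin values as 4-column bedGraph, merging adjacent equal values.

    Adjacent means same chromosome and abutting coordinates.  Values must be
    finite.  The written intervals round-trip through :func:`read_bedgraph`.
    """
    if isinstance(bins, pd.DataFrame):
        df = bins[["chrom", "start", "end"]].copy()
    else:
        df = bins_to_frame(list(bins))
    values = np.asarray(values, dtype=float)
    if len(values) != len(df):
        raise ValueError("values and bins differ in length")
    if len(values) and not np.all(np.isfinite(values)):
        raise ValueError("bedGraph values must be finite")
    with open(path, "w") as fh:
        if len(df) == 0:
            return
        chroms = df["chrom"].to_numpy()
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        cur = [chroms[0], starts[0], ends[0], values[0]]
        for c, s, e, v in zip(chroms[1:], starts[1:], ends[1:], values[1:]):
            if c == cur[0] and s == cur[2] and v == cur[3]:
                cur[2] = e
            else:
                fh.write(f"{cur[0]}\t{cur[1]}\t{cur[2]}\t{cur[3]:g}\n")
                cur = [c, s, e, v]
        fh.write(f"{cur[0]}\t{cur[1]}\t{cur[2]}\t{cur[3]:g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    return df


def bedgraph_values_at(bedgraph: pd.DataFrame, bins: Sequence[GenomicBin]) -> np.ndarray:
    """Recover one value per bin from a merged bedGraph (0 where uncovered)."""
    out = np.zeros(len(bins))
    by_chrom = {c: g.sort_values("start") for c, g in bedgraph.groupby("chrom", sort=False)}
    for i, b in enumerate(bins):
        g = by_chrom.get(b.chrom)
        if g is None:
            continue
        starts = g["start"].to_numpy()
        idx = np.searchsorted(starts, b.start, side="right") - 1
        if idx >= 0 and g["end"].to_numpy()[idx] > b.start:
            out[i] = g["value"].to_numpy()[idx]
    return out


def write_fragments_bed(frags: FragmentCollection, path) -> None:
    df = frags.records
    with open(path, "w") as fh:
        for chrom, start, end, strand in zip(
            df["chrom"], df["start"], df["end"], df["strand"]
        ):
            fh.write(f"{chrom}\t{start}\t{end}\tread\t0\t{strand}\n")
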