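"""Per-bin feature construction for the bias classifier.

A 200 bp candidate bin is described by the 10 bp-resolution mean-coverage
profile over the 1 kb window centered on it, for each selected signal role
(CUT&Tag, ATAC-seq, IgG), optionally followed by the flattened one-hot
encoding of the bin's 200 bp DNA sequence.  Signal patterns from different
CUT&Tag samples over the same bin are treated as independent training
observations; shared covariate tracks (ATAC, IgG) are reused across samples.

Feature columns follow a fixed role order (cuttag, atac, igg, sequence)
regardless of recipe declaration order, and the recipe travels with any
trained model so training and prediction always agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .groundtruth import LabeledBinSet
from .tracks import GenomicBin, SignalTrack, window_profiles

ROLE_ORDER = ("cuttag", "atac", "igg")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class FeatureRecipe:
    """Which feature blocks enter the model and at what resolution."""

    track_roles: tuple[str, ...] = ("cuttag", "atac")
    include_sequence: bool = False
    window_bp: int = 1000
    step_bp: int = 10
    bin_width: int = 200

    def __post_init__(self) -> None:
        if "cuttag" not in self.track_roles:
            raise ValueError("the cuttag role is always required")
        unknown = set(self.track_roles) - set(ROLE_ORDER)
        if unknown:
            raise ValueError(f"unknown track roles: {sorted(unknown)}")
        if self.window_bp % self.step_bp != 0:
            raise ValueError("window_bp must be divisible by step_bp")

    @property
    def ordered_roles(self) -> tuple[str, ...]:
        return tuple(r for r in ROLE_ORDER if r in self.track_roles)

    @property
    def n_profile_points(self) -> int:
        return self.window_bp // self.step_bp

    @property
    def n_columns(self) -> int:
        n = self.n_profile_points * len(self.track_roles)
        if self.include_sequence:
            n += self.bin_width * 4
        return n

    def to_dict(self) -> dict:
        return {
            "track_roles": list(self.track_roles),
            "include_sequence": self.include_sequence,
            "window_bp": self.window_bp,
            "step_bp": self.step_bp,
            "bin_width": self.bin_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureRecipe":
        return cls(
            track_roles=tuple(d["track_roles"]),
            include_sequence=bool(d["include_sequence"]),
            window_bp=int(d["window_bp"]),
            step_bp=int(d["step_bp"]),
            bin_width=int(d["bin_width"]),
        )


@dataclass
class FeatureMatrix:
    """Rows = (bin, source-sample) observations; columns per the recipe."""

    X: np.ndarray
    recipe: FeatureRecipe
    row_meta: pd.DataFrame  # columns: chrom, start, sample
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.X.shape[1] != self.recipe.n_columns:
            raise ValueError(
                f"expected {self.recipe.n_columns} columns, got {self.X.shape[1]}"
            )
        if self.y is not None and len(self.y) != len(self.X):
            raise ValueError("labels and rows differ in length")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")

    def to_tsv(self, path) -> None:
        df = pd.concat(
            [self.row_meta.reset_index(drop=True), pd.DataFrame(self.X)], axis=1
        )
        if self.y is not None:
            df["label"] = self.y
        df.to_csv(path, sep="\t", index=False)


def one_hot(seq: str, expected_len: int = 200) -> np.ndarray:
    """One-hot encode a DNA string as an (L, 4) matrix over (A, C, G, T).

    Case-insensitive; N rows are all-zero.  Any other character is an error.
    """
    if len(seq) != expected_len:
        raise ValueError(f"expected a {expected_len} bp sequence, got {len(seq)} bp")
    out = np.zeros((expected_len, 4))
    for i, base in enumerate(seq.upper()):
        if base == "N":
            continue
        try:
            out[i, _BASE_INDEX[base]] = 1.0
        except KeyError:
            raise ValueError(f"illegal base {base!r} at position {i}") from None
    return out


def _fetch_sequence(fasta, chrom: str, start: int, end: int) -> str:
    if isinstance(fasta, Mapping):
        seq = fasta[chrom][start:end]
        if len(seq) != end - start:
            raise ValueError(f"bin {chrom}:{start}-{end} outside contig")
        return seq
    # pyfaidx.Fasta or similar indexed access
    rec = fasta[chrom][start:end]
    seq = rec.seq if hasattr(rec, "seq") else str(rec)
    if len(seq) != end - start:
        raise ValueError(f"bin {chrom}:{start}-{end} outside contig")
    return seq


def featurize_bins(
    bins: Sequence[GenomicBin],
    tracks: Mapping[str, SignalTrack],
    recipe: FeatureRecipe,
    fasta=None,
) -> np.ndarray:
    """One feature row per bin, columns in canonical role order."""
    missing = [r for r in recipe.ordered_roles if r not in tracks]
    if missing:
        raise ValueError(f"missing tracks for roles: {missing}")
    if recipe.include_sequence and fasta is None:
        raise ValueError("recipe includes sequence features but no fasta given")
    blocks = [
        window_profiles(tracks[role], bins, recipe.window_bp, recipe.step_bp)
        for role in recipe.ordered_roles
    ]
    if recipe.include_sequence:
        seq_block = np.stack(
            [
                one_hot(
                    _fetch_sequence(fasta, b.chrom, b.start, b.end), recipe.bin_width
                ).ravel()
                for b in bins
            ]
        ) if bins else np.zeros((0, recipe.bin_width * 4))
        blocks.append(seq_block)
    return np.hstack(blocks) if blocks else np.zeros((len(bins), 0))


def build_training_matrix(
    labeled: LabeledBinSet,
    cuttag_tracks: Sequence[SignalTrack],
    shared_tracks: Mapping[str, SignalTrack],
    recipe: FeatureRecipe,
    fasta=None,
    sample_labels: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Training matrix with one row per (labeled bin x CUT&Tag sample).

    Each CUT&Tag dataset's signal pattern over the same bin is an independent
    observation; shared ATAC/IgG tracks (and sequence) are reused across
    samples, and labels are replicated accordingly.
    """
    if not cuttag_tracks:
        raise ValueError("need at least one CUT&Tag sample track")
    bins = labeled.as_bins()
    if not bins:
        raise ValueError("labeled bin set is empty")
    labels = labeled.bins["label"].to_numpy()
    if sample_labels is None:
        sample_labels = [f"sample{i}" for i in range(len(cuttag_tracks))]
    shared_blocks = {
        role: window_profiles(shared_tracks[role], bins, recipe.window_bp, recipe.step_bp)
        for role in recipe.ordered_roles
        if role != "cuttag"
    }
    seq_block = None
    if recipe.include_sequence:
        seq_block = featurize_bins(
            bins,
            {"cuttag": cuttag_tracks[0], **shared_tracks},
            FeatureRecipe(
                track_roles=("cuttag",),
                include_sequence=True,
                window_bp=recipe.window_bp,
                step_bp=recipe.step_bp,
                bin_width=recipe.bin_width,
            ),
            fasta=fasta,
        )[:, recipe.n_profile_points :]
    rows, metas = [], []
    for track, name in zip(cuttag_tracks, sample_labels):
        blocks = []
        for role in recipe.ordered_roles:
            if role == "cuttag":
                blocks.append(
                    window_profiles(track, bins, recipe.window_bp, recipe.step_bp)
                )
            else:
                blocks.append(shared_blocks[role])
        if seq_block is not None:
            blocks.append(seq_block)
        rows.append(np.hstack(blocks))
        metas.append(
            pd.DataFrame(
                {
                    "chrom": [b.chrom for b in bins],
                    "start": [b.start for b in bins],
                    "sample": name,
                }
            )
        )
    return FeatureMatrix(
        X=np.vstack(rows),
        recipe=recipe,
        row_meta=pd.concat(metas, ignore_index=True),
        y=np.tile(labels, len(cuttag_tracks)),
    )
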