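"""Tiny construction helpers shared across test modules."""

import pandas as pd

from tn5shadow import tracks as tr


def GenomeLayoutFactory():
    return tr.GenomeLayout(
        chrom_names=("chrA", "chrB"),
        chrom_lengths=(10_000, 4_000),
        included_chroms=("chrA", "chrB"),
    )


def make_frags(rows, label="test"):
    """rows: list of (chrom, start, end, strand)."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return tr.FragmentCollection(records=df, total_count=len(df), source_label=label)
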