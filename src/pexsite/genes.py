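"""Gene models and aligned ribosome-footprint tables.

Internally every interval is 0-based half-open ``[start, end)``; GFF3 is
1-based inclusive and is converted exactly at the I/O boundary (see
:func:`gff3_to_internal` / :func:`internal_to_gff3`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "FootprintTable",
    "gff3_to_internal",
    "internal_to_gff3",
]

MITO_CHROM_NAMES = {"chrm", "chrmt", "mito", "mt", "chrmito"}


def gff3_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based inclusive GFF3 interval to 0-based half-open."""
    if start_1based < 1 or end_1based < start_1based:
        raise ValueError(
            f"invalid GFF3 interval {start_1based}..{end_1based} "
            "(need 1 <= start <= end)"
        )
    return start_1based - 1, end_1based


def internal_to_gff3(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive GFF3."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid internal interval [{start}, {end})")
    return start + 1, end


@dataclass
class GeneModel:
    """One gene: strand-aware CDS intervals plus exclusion flags.

    ``cds_intervals`` are 0-based half-open, non-overlapping within the
    gene, and kept sorted by start.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    dubious: bool = False
    mitochondrial: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        ivs = sorted((int(s), int(e)) for s, e in self.cds_intervals)
        if not ivs:
            raise ValueError(f"{self.gene_id}: gene needs at least one CDS interval")
        for (s, e) in ivs:
            if s < 0 or e <= s:
                raise ValueError(f"{self.gene_id}: bad interval [{s}, {e})")
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap within gene")
        self.cds_intervals = ivs
        self.dubious = bool(self.dubious)
        self.mitochondrial = bool(self.mitochondrial)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def cds_positions(self) -> np.ndarray:
        """All genomic CDS positions of the gene (ascending)."""
        return np.concatenate(
            [np.arange(s, e, dtype=np.int64) for s, e in self.cds_intervals]
        )


_FP_COLUMNS = ("chrom", "strand", "three_prime_pos", "length")


@dataclass
class FootprintTable:
    """Aligned ribosome footprints: one row per footprint.

    Columns: ``chrom`` (str), ``strand`` ('+'/'-'), ``three_prime_pos``
    (0-based genomic coordinate of the 3'-most nucleotide), ``length`` (nt).
    Duplicate rows are meaningful (each row is one sequenced footprint).
    """

    df: pd.DataFrame = field(default_factory=lambda: _empty_frame())

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _FP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"footprint table missing columns: {missing}")
        df = df.loc[:, list(_FP_COLUMNS)].reset_index(drop=True)
        if len(df):
            bad_strand = ~df["strand"].isin(["+", "-"])
            if bad_strand.any():
                bad = df.loc[bad_strand, "strand"].unique().tolist()
                raise ValueError(f"strand must be '+' or '-', got {bad}")
            if (df["three_prime_pos"].to_numpy() < 0).any():
                raise ValueError("three_prime_pos must be >= 0")
            if (df["length"].to_numpy() <= 0).any():
                raise ValueError("length must be > 0")
        df["three_prime_pos"] = df["three_prime_pos"].astype(np.int64)
        df["length"] = df["length"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        df["strand"] = df["strand"].astype(str)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_arrays(cls, chrom, strand, three_prime_pos, length) -> "FootprintTable":
        return cls(pd.DataFrame({
            "chrom": chrom,
            "strand": strand,
            "three_prime_pos": three_prime_pos,
            "length": length,
        }))


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str),
        "strand": pd.Series(dtype=str),
        "three_prime_pos": pd.Series(dtype=np.int64),
        "length": pd.Series(dtype=np.int64),
    })
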