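"""Concatenated multi-marker reference alignment ("scaffold") and read tiling.

Reference rows from each gene family are concatenated into one wide matrix
with recorded per-family column partitions; a fragmentary query read from a
single family is tiled into that coordinate system, with every column outside
its family treated as missing data.  Because the marker families are
essentially single-copy, each read represents one organism drawn roughly in
proportion to its abundance, so reads can enter diversity statistics directly
without OTU binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .formats import (
    AMINO_ACIDS,
    AlignedSequence,
    ConsistencyError,
    FormatError,
    GeneFamilyAlignment,
)


@dataclass
class Partition:
    """Half-open column span [start, end) of one gene family, with its
    rate multiplier and gamma shape under the partitioned model."""

    family_id: str
    start: int
    end: int
    rate_multiplier: float = 1.0
    gamma_shape: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"partition {self.family_id!r}: start must be < end")
        if not (self.rate_multiplier > 0 and self.gamma_shape > 0):
            raise ValueError(
                f"partition {self.family_id!r}: rate and shape must be > 0"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class ConcatenatedAlignment:
    """Reference taxa x concatenated columns, with per-family partitions."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: list[Partition]
    total_columns: int = field(init=False)

    def __post_init__(self) -> None:
        self.total_columns = sum(p.width for p in self.partitions)
        expected = 0
        for p in self.partitions:
            if p.start != expected:
                raise ValueError("partitions must be contiguous in family order")
            expected = p.end
        for t in self.taxa:
            if len(self.rows[t]) != self.total_columns:
                raise ValueError(f"row {t!r} has wrong width")

    def partition_of(self, family_id: str) -> Partition:
        for p in self.partitions:
            if p.family_id == family_id:
                return p
        raise KeyError(family_id)

    def extract_partition(self, taxon: str, family_id: str) -> str:
        p = self.partition_of(family_id)
        return self.rows[taxon][p.start:p.end]


@dataclass(frozen=True)
class TiledQuery:
    """A single-family read embedded in the concatenated coordinate system."""

    read_id: str
    sample_id: str
    family_id: str
    row: str
    n_unmasked: int


def concatenate(
    families: list[GeneFamilyAlignment], taxa: list[str]
) -> ConcatenatedAlignment:
    """Concatenate per-family reference alignments over a shared taxon list.

    Taxa missing from a family receive all-gap columns in that family's
    partition, which the likelihood engine treats as missing data.
    """
    taxon_set = set(taxa)
    partitions: list[Partition] = []
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    start = 0
    for fam in families:
        extra = set(fam.ids) - taxon_set
        if extra:
            raise ConsistencyError(
                f"family {fam.family_id!r}: taxa {sorted(extra)} absent from taxa list"
            )
        partitions.append(
            Partition(fam.family_id, start, start + fam.n_columns)
        )
        start += fam.n_columns
        present = {m.id: m.residues for m in fam}
        gap_row = "-" * fam.n_columns
        for t in taxa:
            pieces[t].append(present.get(t, gap_row))
    rows = {t: "".join(pieces[t]) for t in taxa}
    return ConcatenatedAlignment(list(taxa), rows, partitions)


def count_unmasked(residues: str) -> int:
    """Unmasked amino acids: uppercase standard residues only ('X', lowercase
    and gaps are all missing)."""
    return sum(c in AMINO_ACIDS for c in residues)


def tile_query(
    read: AlignedSequence,
    family_id: str,
    partitions: list[Partition],
    sample_id: str = "",
) -> TiledQuery:
    """Embed a family-aligned read into the concatenated coordinates."""
    part = next((p for p in partitions if p.family_id == family_id), None)
    if part is None:
        raise KeyError(family_id)
    if len(read.residues) != part.width:
        raise FormatError(
            f"read {read.id!r}: length {len(read.residues)} does not match "
            f"family {family_id!r} partition width {part.width}"
        )
    total = sum(p.width for p in partitions)
    row = "-" * part.start + read.residues + "-" * (total - part.end)
    return TiledQuery(
        read_id=read.id,
        sample_id=sample_id,
        family_id=family_id,
        row=row,
        n_unmasked=count_unmasked(read.residues),
    )


def length_filter(
    queries: list[TiledQuery], min_unmasked: int = 50
) -> list[TiledQuery]:
    """Drop reads with fewer than ``min_unmasked`` unmasked amino acids."""
    return [q for q in queries if q.n_unmasked >= min_unmasked]


# -- partition table I/O ----------------------------------------------------

def write_partitions(partitions: list[Partition], path) -> None:
    pd.DataFrame(
        [
            {"family_id": p.family_id, "start": p.start, "end": p.end,
             "rate_multiplier": p.rate_multiplier, "gamma_shape": p.gamma_shape}
            for p in partitions
        ]
    ).to_csv(path, sep="\t", index=False)


def read_partitions(path) -> list[Partition]:
    df = pd.read_csv(path, sep="\t")
    return [
        Partition(str(r.family_id), int(r.start), int(r.end),
                  float(r.rate_multiplier), float(r.gamma_shape))
        for r in df.itertuples()
    ]


def write_concatenated(aln: ConcatenatedAlignment, path) -> None:
    members = [AlignedSequence(t, aln.rows[t]) for t in aln.taxa]
    from .formats import write_alignment

    write_alignment(GeneFamilyAlignment("concatenated", members), path)
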