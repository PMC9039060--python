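"""Core domain types shared by all pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class GenomeKind(str, Enum):
    SAG = "SAG"
    MAG = "MAG"


@dataclass
class SeqRecord:
    """A named DNA sequence (contig / gene / spacer).

    ``seq`` is uppercase over {A,C,G,T,N}; lowercase input is normalized
    on construction.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if set(self.seq) - set("ACGTN"):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(f"sequence {self.id!r} has non-ACGTN characters: {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeMeta:
    """Quality and provenance metadata consumed (not computed) by the
    pipeline: the kind of genome (single amplified vs metagenome-assembled),
    CheckM-style completeness/contamination fractions, a lineage label and,
    once ANI clustering has run, the species-group id."""

    kind: GenomeKind
    completeness: float = 1.0
    contamination: float = 0.0
    lineage: str = ""
    species_group: Optional[str] = None

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            self.kind = GenomeKind(self.kind.upper())
        for name in ("completeness", "contamination"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class GenomeAssembly:
    """An assembled genome: an ordered list of contigs plus metadata."""

    genome_id: str
    contigs: list[SeqRecord]
    meta: GenomeMeta

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate contig ids in {self.genome_id}: {dups}")
        if self.total_length < 1:
            raise ValueError(f"genome {self.genome_id} has zero total length")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def contig(self, contig_id: str) -> SeqRecord:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(f"{self.genome_id} has no contig {contig_id!r}")


@dataclass
class AlignmentSegment:
    """A collinear, gap-free mapping between a query contig interval and a
    reference contig interval (0-based, half-open; equal lengths).

    strand '+' maps query position q to ref_start + (q - query_start);
    strand '-' maps it to ref_end - 1 - (q - query_start), with the query
    base complemented.
    """

    query_genome: str
    query_contig: str
    query_start: int
    query_end: int
    ref_contig: str
    ref_start: int
    ref_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.query_end - self.query_start != self.ref_end - self.ref_start:
            raise ValueError(
                f"segment {self.query_contig}:{self.query_start}-{self.query_end} "
                "is not length-matched to its reference interval"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
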