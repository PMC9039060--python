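"""Readers and writers for the standard formats the pipeline exchanges:
FASTA (assemblies, genes, spacers), TSV (manifest and all stage tables),
and minimal PAF for externally produced contig-to-reference alignments.
"""
from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .types import AlignmentSegment, GenomeAssembly, GenomeKind, GenomeMeta, SeqRecord

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "genome_id",
    "fasta_path",
    "kind",
    "completeness",
    "contamination",
    "lineage",
]


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords (uppercased, order preserved).

    Raises ValueError on duplicate ids; an empty file yields an empty
    list with a warning.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq), description=rec.description))
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records with fixed-width line wrapping (default 60 columns)."""
    bio = [
        BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_manifest(path: str | os.PathLike, load_contigs: bool = True) -> list[GenomeAssembly]:
    """Read a genome manifest TSV into GenomeAssembly objects.

    Required columns: genome_id, fasta_path, kind, completeness,
    contamination, lineage. fasta_path is resolved relative to the
    manifest's directory. ``kind`` is case-insensitive (sag/mag).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {', '.join(missing)}")
    base = Path(path).parent
    assemblies = []
    for row_num, row in enumerate(df.itertuples(index=False), start=1):
        try:
            comp = float(row.completeness)
            cont = float(row.contamination)
        except ValueError as e:
            raise ValueError(f"manifest row {row_num}: non-numeric quality field ({e})")
        try:
            meta = GenomeMeta(
                kind=GenomeKind(str(row.kind).upper()),
                completeness=comp,
                contamination=cont,
                lineage=str(row.lineage),
            )
        except ValueError as e:
            raise ValueError(f"manifest row {row_num} ({row.genome_id}): {e}")
        fasta = Path(row.fasta_path)
        if not fasta.is_absolute():
            fasta = base / fasta
        contigs = read_fasta(fasta) if load_contigs else []
        assemblies.append(GenomeAssembly(genome_id=str(row.genome_id), contigs=contigs, meta=meta))
    return assemblies


def write_manifest(assemblies: list[GenomeAssembly], fasta_paths: list[str], path: str | os.PathLike) -> None:
    rows = [
        {
            "genome_id": a.genome_id,
            "fasta_path": p,
            "kind": a.meta.kind.value,
            "completeness": f"{a.meta.completeness:.6g}",
            "contamination": f"{a.meta.contamination:.6g}",
            "lineage": a.meta.lineage,
        }
        for a, p in zip(assemblies, fasta_paths)
    ]
    write_tsv(pd.DataFrame(rows, columns=MANIFEST_COLUMNS), path)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Stage-table convention: tab-separated, header row, no quoting, no index."""
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_paf(path: str | os.PathLike, query_genome_of: dict[str, str] | None = None) -> list[AlignmentSegment]:
    """Read a minimal PAF file into collinear alignment segments.

    Only the 12 mandatory columns are used; without a cigar the alignment
    is assumed collinear and gap-free, so the query and target spans must
    be equal in length (rows where they differ are truncated to the
    shorter span, anchored at the start, with a warning).

    query_genome_of maps query contig id -> genome id (defaults to the
    contig id itself).
    """
    segments = []
    with open(path) as fh:
        for line_num, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"PAF line {line_num}: fewer than 12 columns")
            qname, qstart, qend = f[0], int(f[2]), int(f[3])
            strand, tname, tstart, tend = f[4], f[5], int(f[7]), int(f[8])
            span = min(qend - qstart, tend - tstart)
            if qend - qstart != tend - tstart:
                logger.warning(
                    "PAF line %d: unequal spans without cigar; truncating to %d bp",
                    line_num,
                    span,
                )
            genome = (query_genome_of or {}).get(qname, qname)
            if strand == "+":
                seg = AlignmentSegment(genome, qname, qstart, qstart + span, tname, tstart, tstart + span, "+")
            else:
                seg = AlignmentSegment(genome, qname, qstart, qstart + span, tname, tend - span, tend, "-")
            segments.append(seg)
    return segments
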