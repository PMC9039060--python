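"""Allele matrices and filtered biallelic SNP calling for one species group.

Allele calling is assembly-based: each cell's contigs are placed on the
reference by collinear alignment segments (from the simulator's truth
coordinates or an external PAF), and the cell's base is recorded at every
reference position covered by exactly one contig.  Uncovered positions are
missing; positions covered by conflicting overlapping contigs are set to
missing and logged (conservative under chimerism).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode
from .types import AlignmentSegment, GenomeAssembly, GenomeKind

logger = logging.getLogger(__name__)

MISSING = 4  # allele-matrix code; genotype matrices use -1


def select_reference(genomes: list[GenomeAssembly], max_contamination: float = 0.05) -> str:
    """Pick the reference for a species group: the most complete SAG with
    contamination strictly below the cutoff; ties broken by genome id."""
    sags = [g for g in genomes if g.meta.kind == GenomeKind.SAG]
    if not sags:
        raise ValueError("no SAGs in species group")
    eligible = [g for g in sags if g.meta.contamination < max_contamination]
    if not eligible:
        cands = ", ".join(f"{g.genome_id}(contam={g.meta.contamination})" for g in sags)
        raise ValueError(f"no SAG passes the contamination filter; candidates: {cands}")
    best = sorted(eligible, key=lambda g: (-g.meta.completeness, g.genome_id))[0]
    return best.genome_id


def compose_segments(segments: list[AlignmentSegment], reference_id: str) -> list[AlignmentSegment]:
    """Re-express common-frame segments against a chosen reference genome.

    When segments map contigs of many genomes onto a shared coordinate
    frame (e.g. the simulator's core frame), the reference genome's own
    segments define a frame->reference-contig chart; every other segment
    is intersected with that chart.  Segments already expressed against
    the reference's contigs pass through unchanged.
    """
    ref_own = [s for s in segments if s.query_genome == reference_id]
    chart = []  # (frame_contig, frame_start, frame_end, ref_contig, ref_contig_start)
    for s in ref_own:
        if s.strand != "+":
            raise ValueError("reference self-segments must be forward strand")
        chart.append((s.ref_contig, s.ref_start, s.ref_end, s.query_contig, s.query_start))
    out = []
    for s in segments:
        for fc, fs, fe, rc, rq in chart:
            if s.ref_contig != fc:
                continue
            lo, hi = max(s.ref_start, fs), min(s.ref_end, fe)
            if lo >= hi:
                continue
            if s.strand == "+":
                q0 = s.query_start + (lo - s.ref_start)
                out.append(
                    AlignmentSegment(
                        s.query_genome, s.query_contig, q0, q0 + (hi - lo),
                        rc, rq + (lo - fs), rq + (hi - fs), "+",
                    )
                )
            else:
                q0 = s.query_start + (s.ref_end - hi)
                out.append(
                    AlignmentSegment(
                        s.query_genome, s.query_contig, q0, q0 + (hi - lo),
                        rc, rq + (lo - fs), rq + (hi - fs), "-",
                    )
                )
    return out


@dataclass
class AlleleMatrix:
    """cells x reference-positions allele calls with explicit missingness.

    ``calls`` holds base codes (A=0..T=3) with 4 = missing; positions are
    given per reference contig (0-based), stored as parallel arrays
    ``contig_index``/``pos`` with ``contig_names`` for lookup.
    """

    reference_id: str
    cells: list[str]
    contig_names: list[str]
    contig_index: np.ndarray
    pos: np.ndarray
    calls: np.ndarray  # (n_cells, n_positions) uint8
    n_conflicts: int = 0

    @property
    def positions(self) -> list[tuple[str, int]]:
        return [(self.contig_names[c], int(p)) for c, p in zip(self.contig_index, self.pos)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "contig": [self.contig_names[c] for c in self.contig_index],
                "pos": self.pos,
            }
        )
        for i, cell in enumerate(self.cells):
            df[cell] = ["ACGT."[b] if b <= 4 else "." for b in self.calls[i]]
        return df


_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def build_allele_matrix(
    genomes: list[GenomeAssembly],
    reference_id: str,
    segments: list[AlignmentSegment],
) -> AlleleMatrix:
    """Project every genome's contigs onto the reference and record allele
    calls.  `segments` may be expressed against the reference's contigs or
    against a common frame shared with the reference (auto-composed)."""
    by_id = {g.genome_id: g for g in genomes}
    if reference_id not in by_id:
        raise ValueError(f"reference {reference_id!r} not among genomes")
    ref = by_id[reference_id]
    ref_contigs = {c.id for c in ref.contigs}
    if not any(s.ref_contig in ref_contigs for s in segments):
        composed = compose_segments(segments, reference_id)
        if segments and not composed:
            frames = sorted({s.ref_contig for s in segments})
            raise ValueError(
                f"alignment references unknown contig(s) {frames} (no overlap "
                f"with reference {reference_id!r})"
            )
        segments = composed
    for s in segments:
        if s.ref_contig not in ref_contigs:
            raise ValueError(f"alignment references unknown contig {s.ref_contig!r}")
        if s.query_genome in by_id:
            q_ids = {c.id for c in by_id[s.query_genome].contigs}
            if s.query_contig not in q_ids:
                raise ValueError(
                    f"alignment references unknown contig {s.query_contig!r} "
                    f"of {s.query_genome}"
                )

    contig_names = [c.id for c in ref.contigs]
    offsets = {}
    total = 0
    for c in ref.contigs:
        offsets[c.id] = total
        total += len(c)
    cells = sorted(g.genome_id for g in genomes)
    calls = np.full((len(cells), total), MISSING, dtype=np.uint8)
    conflicts = 0
    cell_idx = {c: i for i, c in enumerate(cells)}
    seq_cache = {
        (g.genome_id, c.id): encode(c.seq) for g in genomes for c in g.contigs
    }
    covered = np.zeros((len(cells), total), dtype=np.uint8)
    for s in segments:
        if s.query_genome not in cell_idx:
            continue
        i = cell_idx[s.query_genome]
        q = seq_cache[(s.query_genome, s.query_contig)][s.query_start : s.query_end]
        if s.strand == "-":
            q = _COMP[q[::-1]]
        lo = offsets[s.ref_contig] + s.ref_start
        sl = slice(lo, lo + (s.ref_end - s.ref_start))
        prev_cov = covered[i, sl]
        prev_val = calls[i, sl]
        clash = (prev_cov > 0) & (prev_val != q)
        n_clash = int(clash.sum())
        if n_clash:
            conflicts += n_clash
            logger.info(
                "%s: %d conflicting overlap position(s) on %s set to missing",
                s.query_genome, n_clash, s.ref_contig,
            )
        newval = np.where(prev_cov == 0, q, np.where(clash, MISSING, prev_val))
        calls[i, sl] = newval
        covered[i, sl] = np.minimum(prev_cov + 1, 250)
    contig_index = np.concatenate(
        [np.full(len(c), k, dtype=np.int32) for k, c in enumerate(ref.contigs)]
    )
    pos = np.concatenate([np.arange(len(c), dtype=np.int64) for c in ref.contigs])
    return AlleleMatrix(
        reference_id=reference_id,
        cells=cells,
        contig_names=contig_names,
        contig_index=contig_index,
        pos=pos,
        calls=calls,
        n_conflicts=conflicts,
    )


@dataclass
class SnpMatrix:
    """Filtered biallelic sites: geno is cells x sites over {0 major,
    1 minor, -1 missing}."""

    reference_id: str
    cells: list[str]
    contig_names: list[str]
    site_contig: np.ndarray  # index into contig_names
    site_pos: np.ndarray
    major: np.ndarray  # base codes
    minor: np.ndarray
    minor_count: np.ndarray
    called_count: np.ndarray
    geno: np.ndarray  # (n_cells, n_sites) int8

    @property
    def n_sites(self) -> int:
        return int(self.site_pos.size)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "contig": [self.contig_names[c] for c in self.site_contig],
                "pos": self.site_pos,
                "major": ["ACGT"[b] for b in self.major],
                "minor": ["ACGT"[b] for b in self.minor],
                "minor_count": self.minor_count,
                "called_count": self.called_count,
            }
        )
        for i, cell in enumerate(self.cells):
            df[cell] = self.geno[i]
        return df


def call_snps(
    matrix: AlleleMatrix,
    min_called_cells: int = 10,
    min_called_frac: float = 0.5,
    min_minor_count: int = 2,
) -> SnpMatrix:
    """Call filtered biallelic SNPs from an allele matrix.

    A position is retained when (a) it is called in at least
    max(min_called_cells, min_called_frac * n_cells) cells, (b) exactly
    two alleles segregate among the calls, and (c) the minor allele is
    seen at least min_minor_count times.  Major = more frequent allele;
    frequency ties go to the alphabetically first base.
    """
    n = len(matrix.cells)
    if n < 2:
        raise ValueError("need at least 2 cells to call SNPs")
    counts = np.stack([(matrix.calls == b).sum(axis=0) for b in range(4)])  # (4, P)
    called = counts.sum(axis=0)
    n_alleles = (counts > 0).sum(axis=0)
    order = np.argsort(-counts, axis=0, kind="stable")  # ties -> lower base code first
    major = order[0]
    minor = order[1]
    major_count = np.take_along_axis(counts, major[None], axis=0)[0]
    minor_count = np.take_along_axis(counts, minor[None], axis=0)[0]
    threshold = max(min_called_cells, min_called_frac * n)
    keep = (called >= threshold) & (n_alleles == 2) & (minor_count >= min_minor_count)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        logger.warning("no sites survive SNP filters; returning empty matrix")
    sub = matrix.calls[:, idx]
    geno = np.full(sub.shape, -1, dtype=np.int8)
    geno[sub == major[idx][None, :]] = 0
    geno[sub == minor[idx][None, :]] = 1
    return SnpMatrix(
        reference_id=matrix.reference_id,
        cells=list(matrix.cells),
        contig_names=list(matrix.contig_names),
        site_contig=matrix.contig_index[idx].copy(),
        site_pos=matrix.pos[idx].copy(),
        major=major[idx].astype(np.uint8),
        minor=minor[idx].astype(np.uint8),
        minor_count=minor_count[idx].astype(np.int64),
        called_count=called[idx].astype(np.int64),
        geno=geno,
    )
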