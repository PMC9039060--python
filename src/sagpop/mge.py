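"""Mobile-genetic-element composition analysis: tetranucleotide frequency
(TNF) profiles with canonical strand merging, contig circularity
screening, the >10 kb carriage rule, lineage-specificity PERMANOVA of MGE
composition, and 99%-ANI MGE grouping.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode, kmer_codes
from .popstructure import DistanceMatrix, permanova
from .types import GenomeAssembly

logger = logging.getLogger(__name__)

MGE_LABELS = ("phage", "prophage", "plasmid")


def _canonical_map() -> tuple[np.ndarray, int]:
    rc_base = np.array([3, 2, 1, 0])
    canon = np.empty(256, dtype=np.int64)
    for idx in range(256):
        digits = [(idx >> (2 * (3 - i))) & 3 for i in range(4)]
        rc = 0
        for d in digits:  # reverse complement read 3'->5'
            rc = rc * 4 + rc_base[d]
        # recompute properly: rc digits are complement of reversed digits
        rcd = [rc_base[d] for d in digits[::-1]]
        rc = (((rcd[0] * 4 + rcd[1]) * 4) + rcd[2]) * 4 + rcd[3]
        canon[idx] = min(idx, rc)
    classes = np.unique(canon)
    remap = np.full(256, -1, dtype=np.int64)
    remap[classes] = np.arange(len(classes))
    return remap[canon], len(classes)


_CANON, N_CANONICAL = _canonical_map()  # 136 strand-merged classes


@dataclass
class TnfVector:
    contig_id: str
    freq: np.ndarray  # canonical 136-dim (or raw 256 with raw=True)


def tnf(seq: str, contig_id: str = "", raw: bool = False) -> TnfVector:
    """Tetranucleotide frequency of a contig.

    4-mer windows slide with step 1; windows containing N are skipped
    entirely (excluded from numerator and denominator); counts of a 4-mer
    and its reverse complement are merged unless raw=True.
    """
    if len(seq) < 4:
        raise ValueError("sequence shorter than 4 bp has no tetranucleotides")
    km = kmer_codes(encode(seq), 4)
    valid = km[km >= 0]
    if valid.size == 0:
        raise ValueError("no N-free tetranucleotide windows")
    if raw:
        counts = np.bincount(valid, minlength=256).astype(float)
    else:
        counts = np.bincount(_CANON[valid], minlength=N_CANONICAL).astype(float)
    return TnfVector(contig_id=contig_id, freq=counts / counts.sum())


def detect_circular(seq: str, min_overlap: int = 50, max_mismatch: int = 0) -> tuple[bool, int]:
    """Terminal-overlap circularity screen.

    Returns (is_circular, longest overlap length) where the overlap is a
    prefix of length >= min_overlap equal to a suffix with at most
    max_mismatch mismatches.  Overlap lengths up to half the contig are
    considered.
    """
    n = len(seq)
    if n < 2 * min_overlap:
        raise ValueError("contig shorter than twice the minimum overlap")
    codes = encode(seq)
    best = 0
    for ln in range(n // 2, min_overlap - 1, -1):
        mism = int(np.count_nonzero(codes[:ln] != codes[n - ln :]))
        if mism <= max_mismatch:
            best = ln
            break
    return best > 0, best


def carriage_table(
    genomes: list[GenomeAssembly],
    mge_labels: pd.DataFrame,
    min_len: int = 10_000,
) -> pd.DataFrame:
    """Per-genome MGE-type presence: a genome is positive for a type iff
    it has at least one contig of that label strictly longer than min_len.

    mge_labels columns: contig_id, genome_id, label.
    """
    contig_len = {(g.genome_id, c.id): len(c) for g in genomes for c in g.contigs}
    known = {g.genome_id for g in genomes}
    rows = {g.genome_id: {t: False for t in MGE_LABELS} for g in genomes}
    for r in mge_labels.itertuples(index=False):
        if r.genome_id not in known or (r.genome_id, r.contig_id) not in contig_len:
            raise ValueError(f"MGE label for unknown contig {r.contig_id!r} ({r.genome_id})")
        if r.label not in MGE_LABELS:
            raise ValueError(f"unknown MGE label {r.label!r}")
        if contig_len[(r.genome_id, r.contig_id)] > min_len:
            rows[r.genome_id][r.label] = True
    out = pd.DataFrame(
        [
            {"genome_id": g.genome_id, "lineage": g.meta.lineage, **rows[g.genome_id]}
            for g in genomes
        ]
    )
    out["any_mge"] = out[list(MGE_LABELS)].any(axis=1)
    return out


def tnf_permanova(
    mge_contigs: list[tuple[str, str, str, str]],  # (contig_id, lineage, label, seq)
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float, int]:
    """Lineage-specificity of MGE composition: PERMANOVA of Euclidean
    distances between TNF profiles against lineage labels.

    Prophage contigs are excluded before the distance computation (their
    host-genome background cannot be separated from the element); the
    count of exclusions is returned alongside (F, p).
    """
    kept = [(c, l, s) for c, l, lab, s in mge_contigs if lab != "prophage"]
    n_excluded = len(mge_contigs) - len(kept)
    if n_excluded:
        logger.info("excluded %d prophage contig(s) from TNF PERMANOVA", n_excluded)
    if not kept:
        raise ValueError("no non-prophage MGE contigs")
    profiles = np.stack([tnf(s, c).freq for c, _l, s in kept])
    labels = np.array([l for _c, l, _s in kept])
    diff = profiles[:, None, :] - profiles[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(ids=[c for c, _l, _s in kept], d=(d + d.T) / 2)
    f, p = permanova(dm, labels, n_perm=n_perm, seed=seed)
    return f, p, n_excluded


def group_mges_by_ani(
    mge_contigs: list[tuple[str, str]],  # (contig_id, seq)
    threshold: float = 0.99,
    frag_len: int = 1000,
) -> pd.DataFrame:
    """Single-linkage grouping of MGE contigs at >= threshold ANI.

    Returns a table (contig_id, group_id, group_size); group ids are
    named after the lexicographically smallest member.
    """
    from .ani import cluster_ani_seqs

    if not mge_contigs:
        return pd.DataFrame(columns=["contig_id", "group_id", "group_size"])
    labels = cluster_ani_seqs(
        mge_contigs, threshold=threshold * 100 if threshold <= 1 else threshold, frag_len=frag_len
    )
    sizes = pd.Series(labels).value_counts().to_dict()
    return pd.DataFrame(
        {
            "contig_id": [c for c, _ in mge_contigs],
            "group_id": labels,
            "group_size": [sizes[l] for l in labels],
        }
    )


def tnf_outlier_flags(
    genome: GenomeAssembly, z_cutoff: float = 2.0, min_len: int = 4
) -> pd.DataFrame:
    """Naive composition-based MGE flagger (heuristic, not a detector):
    flags contigs whose TNF Euclidean distance from the genome's median
    profile is a z-score outlier."""
    usable = [c for c in genome.contigs if len(c) >= min_len]
    if len(usable) < 3:
        raise ValueError("need at least 3 contigs to assess outliers")
    profiles = np.stack([tnf(c.seq, c.id).freq for c in usable])
    median = np.median(profiles, axis=0)
    dists = np.linalg.norm(profiles - median, axis=1)
    sd = dists.std()
    z = (dists - dists.mean()) / sd if sd > 0 else np.zeros_like(dists)
    return pd.DataFrame(
        {
            "contig_id": [c.id for c in usable],
            "length": [len(c) for c in usable],
            "tnf_z": z,
            "flagged": z > z_cutoff,
        }
    )
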