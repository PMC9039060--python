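"""CRISPR repeat-spacer array detection and protospacer matching.

The array finder follows the CRT recipe: exact 8-mer seeds recurring at a
spacing compatible with one repeat+spacer period nucleate a candidate
repeat, which is extended while the two seed copies agree, located
genome-wide allowing a per-copy mismatch budget, chained under the
spacer-length bounds, and accepted when at least three copies remain and
the spacers are mutually distinct (tandem-repeat guard).

Spacer hits are classified against the 95% ANI species grouping:
self (same genome, outside the source array +/- margin), within_lineage
(another genome of the same species group), or cross_lineage.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import canonical, encode, kmer_codes, revcomp, sliding_mismatches
from .types import GenomeAssembly

logger = logging.getLogger(__name__)

SEED_K = 8


@dataclass
class CrisprArray:
    genome_id: str
    contig_id: str
    start: int
    end: int
    repeat_consensus: str
    spacers: list  # of (seq, start, end)
    n_repeats: int


@dataclass
class SpacerHit:
    spacer_id: str
    source_genome: str
    target_genome: str
    target_contig: str
    pos: int
    strand: str
    mismatches: int
    hit_class: str  # self | within_lineage | cross_lineage


def _chain_occurrences(
    occs: np.ndarray, mms: np.ndarray, rl: int, anchor: int, spacer_min: int, spacer_max: int
) -> list[int]:
    """Greedy bidirectional chain of repeat occurrences through the anchor,
    stepping by one spacer at a time (smallest mismatch, then position)."""
    if anchor not in occs:
        # tolerate anchors shifted by extension: use nearest occurrence
        k = int(np.argmin(np.abs(occs - anchor)))
        anchor = int(occs[k])
    chain = [anchor]
    cur = anchor
    while True:
        lo, hi = cur + rl + spacer_min, cur + rl + spacer_max
        window = [(mms[i], occs[i]) for i in range(len(occs)) if lo <= occs[i] <= hi]
        if not window:
            break
        _, nxt = min(window)
        chain.append(int(nxt))
        cur = int(nxt)
    cur = anchor
    while True:
        lo, hi = cur - rl - spacer_max, cur - rl - spacer_min
        window = [(mms[i], occs[i]) for i in range(len(occs)) if lo <= occs[i] <= hi]
        if not window:
            break
        _, prv = min(window)
        chain.insert(0, int(prv))
        cur = int(prv)
    return chain


def _consensus(codes: np.ndarray, starts: list[int], rl: int) -> np.ndarray:
    block = np.stack([codes[s : s + rl] for s in starts])
    counts = np.stack([(block == b).sum(axis=0) for b in range(4)])
    return counts.argmax(axis=0).astype(np.uint8)


def find_arrays(
    genome: GenomeAssembly,
    repeat_len: tuple[int, int] = (19, 48),
    spacer_len: tuple[int, int] = (17, 50),
    min_repeats: int = 3,
    max_repeat_mismatch: int = 1,
) -> list[CrisprArray]:
    """Detect CRISPR repeat-spacer arrays on every contig of a genome."""
    rl_min, rl_max = repeat_len
    sp_min, sp_max = spacer_len
    period_min, period_max = rl_min + sp_min, rl_max + sp_max
    arrays: list[CrisprArray] = []
    for contig in genome.contigs:
        codes = encode(contig.seq)
        n = codes.size
        if n < min_repeats * rl_min + (min_repeats - 1) * sp_min:
            continue
        km = kmer_codes(codes, SEED_K)
        order = np.argsort(km, kind="stable")
        sv = km[order]
        seen: set = set()
        candidates = []
        # iterate recurring seeds: for each position, the next occurrence of
        # the same 8-mer within one period; candidates are deduplicated by
        # span and competing ones resolved longest-span-first below
        bounds = {}
        for i in range(km.size):
            v = km[i]
            if v < 0:
                continue
            lo = bounds.get(v)
            if lo is None:
                lo = np.searchsorted(sv, v, side="left")
                bounds[v] = lo
            hi = np.searchsorted(sv, v, side="right")
            positions = np.sort(order[lo:hi])
            for j in positions:
                if j <= i:
                    continue
                p = j - i
                if p < period_min:
                    continue
                if p > period_max:
                    break
                cand = _build_candidate(
                    codes, int(i), int(j), rl_min, rl_max, sp_min, sp_max,
                    min_repeats, max_repeat_mismatch,
                )
                if cand is not None:
                    starts, rl = cand
                    key = (tuple(starts), rl)
                    if key not in seen:
                        seen.add(key)
                        candidates.append((starts, rl))
                    break
        # resolve overlaps: prefer more repeat copies, then longer span
        candidates.sort(key=lambda c: (-len(c[0]), -(c[0][-1] + c[1] - c[0][0])))
        taken = np.zeros(n, dtype=bool)
        for starts, rl in candidates:
            a, b = starts[0], starts[-1] + rl
            if taken[a:b].any():
                continue
            taken[a:b] = True
            cons = _consensus(codes, starts, rl)
            spacers = [
                (contig.seq[s + rl : t], s + rl, t)
                for s, t in zip(starts[:-1], starts[1:])
            ]
            arrays.append(
                CrisprArray(
                    genome_id=genome.genome_id,
                    contig_id=contig.id,
                    start=int(a),
                    end=int(b),
                    repeat_consensus="".join("ACGT"[c] for c in cons),
                    spacers=spacers,
                    n_repeats=len(starts),
                )
            )
    arrays.sort(key=lambda a: (a.contig_id, a.start))
    return arrays


def _build_candidate(
    codes, i, j, rl_min, rl_max, sp_min, sp_max, min_repeats, max_repeat_mismatch
):
    n = codes.size
    # extend the seed pair while the two copies agree
    left = 0
    while (
        i - left - 1 >= 0
        and codes[i - left - 1] == codes[j - left - 1]
        and SEED_K + left < rl_max
    ):
        left += 1
    right = 0
    while (
        j + SEED_K + right < n
        and codes[i + SEED_K + right] == codes[j + SEED_K + right]
        and SEED_K + left + right < rl_max
    ):
        right += 1
    a = i - left
    rl = SEED_K + left + right
    if rl < rl_min:
        return None
    unit = codes[a : a + rl]
    mm = sliding_mismatches(codes, unit)
    occ = np.flatnonzero(mm <= max_repeat_mismatch)
    if occ.size < min_repeats:
        return None
    chain = _chain_occurrences(occ, mm[occ], rl, a, sp_min, sp_max)
    if len(chain) < min_repeats:
        return None
    gaps = [t - (s + rl) for s, t in zip(chain[:-1], chain[1:])]

    def disagreement(cols):
        vals = [int(v) for v in cols]
        return len(vals) - max(vals.count(v) for v in set(vals))

    # trim: the pairwise seed extension can overrun the repeat boundary
    # when just the two seeded copies agree by chance; a true repeat
    # column disagrees in at most max_repeat_mismatch copies, a spacer
    # column in most of them.  Scan a short boundary window and cut
    # through the innermost spacer-like column (an outer column can look
    # repeat-like by coincidence)
    window = min(8, rl - rl_min)
    cut = 0
    for d in range(window):
        if disagreement([codes[s + rl - 1 - d] for s in chain]) > max_repeat_mismatch:
            cut = d + 1
    if cut:
        rl -= cut
        gaps = [g + cut for g in gaps]
    window = min(8, rl - rl_min)
    cut = 0
    for d in range(window):
        if disagreement([codes[s + d] for s in chain]) > max_repeat_mismatch:
            cut = d + 1
    if cut:
        chain = [s + cut for s in chain]
        rl -= cut
        gaps = [g + cut for g in gaps]
    if any(g > sp_max for g in gaps):
        return None
    # extend boundaries while every copy agrees unanimously and the
    # spacer-length bounds still hold
    while (
        rl < rl_max
        and min(gaps) > sp_min
        and chain[-1] + rl < n
        and len({int(codes[s + rl]) for s in chain}) == 1
    ):
        rl += 1
        gaps = [g - 1 for g in gaps]
    while (
        rl < rl_max
        and min(gaps) > sp_min
        and chain[0] - 1 >= 0
        and len({int(codes[s - 1]) for s in chain}) == 1
    ):
        chain = [s - 1 for s in chain]
        rl += 1
        gaps = [g - 1 for g in gaps]
    # enforce the per-copy mismatch budget against the consensus
    cons = _consensus(codes, chain, rl)
    good = [s for s in chain if int((codes[s : s + rl] != cons).sum()) <= max_repeat_mismatch]
    if len(good) < min_repeats or good != chain:
        chain = _longest_run(good, chain)
        if len(chain) < min_repeats:
            return None
        cons = _consensus(codes, chain, rl)
    # tandem-repeat guard: spacers must be mutually distinct in >=50% of pairs
    spacers = [codes[s + rl : t].tobytes() for s, t in zip(chain[:-1], chain[1:])]
    if len(spacers) >= 2:
        pairs = [(x, y) for xi, x in enumerate(spacers) for y in spacers[xi + 1 :]]
        distinct = sum(1 for x, y in pairs if x != y)
        if distinct / len(pairs) < 0.5:
            return None
    if any(not (sp_min <= len(s) <= sp_max) for s in spacers):
        return None
    return chain, rl


def _longest_run(good: list[int], chain: list[int]) -> list[int]:
    """Longest contiguous sub-chain consisting only of good copies."""
    good_set = set(good)
    best, cur = [], []
    for s in chain:
        if s in good_set:
            cur.append(s)
            if len(cur) > len(best):
                best = list(cur)
        else:
            cur = []
    return best


# ---------------------------------------------------------------------------
# Protospacer matching


def _find_exact(hay: str, needle: str) -> list[int]:
    out = []
    start = hay.find(needle)
    while start != -1:
        out.append(start)
        start = hay.find(needle, start + 1)
    return out


def _match_one_strand(contig_codes: np.ndarray, contig_str: str, spacer: str, max_mm: int) -> list[tuple[int, int]]:
    """(pos, mismatches) of full-length matches with <= max_mm mismatches.

    Pigeonhole seeding: with <= max_mm mismatches at least one of the
    (max_mm+1) equal chunks of the spacer matches exactly.
    """
    m = len(spacer)
    n_chunks = max_mm + 1
    bounds = [round(k * m / n_chunks) for k in range(n_chunks + 1)]
    cand = set()
    for k in range(n_chunks):
        chunk = spacer[bounds[k] : bounds[k + 1]]
        for p in _find_exact(contig_str, chunk):
            start = p - bounds[k]
            if 0 <= start <= len(contig_str) - m:
                cand.add(start)
    sp = encode(spacer)
    hits = []
    for start in sorted(cand):
        mm = int((contig_codes[start : start + m] != sp).sum())
        if mm <= max_mm:
            hits.append((start, mm))
    return hits


def match_spacers(
    spacers: pd.DataFrame,
    genome_set: list[GenomeAssembly],
    max_mismatch: int = 1,
    exclusion_margin: int = 500,
    species_groups: dict[str, str] | None = None,
) -> list[SpacerHit]:
    """Match spacers against every contig of every genome, both strands.

    `spacers` columns: spacer_id, genome_id, contig_id, array_start,
    array_end, seq.  Hits falling within the source array +/- the
    exclusion margin are discarded.  species_groups maps genome_id to its
    95% ANI group (required for lineage classification).
    """
    species_groups = species_groups or {}
    for g in genome_set:
        if g.genome_id not in species_groups:
            if g.meta.species_group is None:
                raise ValueError(f"genome {g.genome_id} has no species group")
            species_groups[g.genome_id] = g.meta.species_group
    enc_cache = [
        (g, [(c, encode(c.seq)) for c in g.contigs]) for g in genome_set
    ]
    hits: list[SpacerHit] = []
    for row in spacers.itertuples(index=False):
        seq = row.seq
        if len(seq) < 17:
            raise ValueError(f"spacer {row.spacer_id} shorter than 17 bp")
        src_group = species_groups.get(row.genome_id)
        rc = revcomp(seq)
        for g, contigs in enc_cache:
            for contig, codes in contigs:
                for strand, s in (("+", seq), ("-", rc)):
                    for pos, mm in _match_one_strand(codes, contig.seq, s, max_mismatch):
                        if (
                            g.genome_id == row.genome_id
                            and contig.id == row.contig_id
                            and pos + len(seq) > row.array_start - exclusion_margin
                            and pos < row.array_end + exclusion_margin
                        ):
                            continue
                        if g.genome_id == row.genome_id:
                            cls = "self"
                        elif species_groups.get(g.genome_id) == src_group:
                            cls = "within_lineage"
                        else:
                            cls = "cross_lineage"
                        hits.append(
                            SpacerHit(
                                spacer_id=row.spacer_id,
                                source_genome=row.genome_id,
                                target_genome=g.genome_id,
                                target_contig=contig.id,
                                pos=pos,
                                strand=strand,
                                mismatches=mm,
                                hit_class=cls,
                            )
                        )
    return hits


def hits_to_frame(hits: list[SpacerHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spacer_id": h.spacer_id,
                "source_genome": h.source_genome,
                "target_genome": h.target_genome,
                "target_contig": h.target_contig,
                "pos": h.pos,
                "strand": h.strand,
                "mismatches": h.mismatches,
                "hit_class": h.hit_class,
            }
            for h in hits
        ],
        columns=[
            "spacer_id", "source_genome", "target_genome", "target_contig",
            "pos", "strand", "mismatches", "hit_class",
        ],
    )


def spacer_rarefaction(
    spacer_sets: dict[str, set],
    mode: str = "closed_form",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected unique spacers vs genomes sampled within one lineage.

    Uniqueness is by exact sequence identity after canonical-strand
    normalization (the lexicographic minimum of a spacer and its reverse
    complement).
    """
    genomes = sorted(spacer_sets)
    n = len(genomes)
    if n < 2:
        raise ValueError("need at least 2 genomes with arrays")
    canon_sets = {g: {canonical(s) for s in spacer_sets[g]} for g in genomes}
    universe = sorted(set().union(*canon_sets.values()))
    m = np.array([sum(1 for g in genomes if s in canon_sets[g]) for s in universe])
    ks = np.arange(1, n + 1)
    if mode == "closed_form":
        expected = [
            float(sum(1.0 - math.comb(n - int(mf), int(k)) / math.comb(n, int(k)) for mf in m))
            for k in ks
        ]
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        membership = np.array([[s in canon_sets[g] for g in genomes] for s in universe])
        acc = np.zeros(n)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            seen = np.maximum.accumulate(membership[:, perm], axis=1)
            acc += seen.sum(axis=0)
        expected = list(acc / n_perm)
    else:
        raise ValueError(f"unknown rarefaction mode {mode!r}")
    return pd.DataFrame({"k": ks, "expected_spacers": expected})
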