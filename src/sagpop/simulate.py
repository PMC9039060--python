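"""Synthetic recombining-community generator.

Produces haploid populations evolved forward in time under a Wright-Fisher
model with point mutation and homologous-recombination tract import, then
layers on the genomic features the downstream stages analyse: lineage-
specific mobile elements (phage, prophage, plasmid), CRISPR repeat-spacer
arrays whose spacers are copied from the circulating MGE pool (plus a
self-targeting fraction), and 16S rRNA genes with planted primer-site
mismatches or introns.  Single-cell genomes are degraded with MDA-style
contiguous-block dropout, and a mock MAG is built by consensus plus
composition-based contig filtering.

Every stochastic placement is logged in truth tables so that downstream
stage outputs can be checked exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import decode, encode
from .types import AlignmentSegment, GenomeAssembly, GenomeKind, GenomeMeta, SeqRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Wright-Fisher population


@dataclass
class SimParams:
    """Forward-simulation parameters.

    recomb_rate is the per-genome per-generation probability that an
    offspring imports one homologous tract (geometric length, mean
    tract_mean bp, truncated at the chromosome end -- no wrap) from a
    second uniformly chosen donor.  Mutation is per-site per-generation,
    to a uniformly chosen different base.
    """

    pop_size: int = 100
    genome_length: int = 50_000
    mut_rate: float = 2.5e-5
    recomb_rate: float = 0.0
    tract_mean: float = 5000.0
    generations: int = 1000
    sample_n: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not (0.0 <= self.mut_rate <= 1.0 and 0.0 <= self.recomb_rate <= 1.0):
            raise ValueError("rates must be in [0,1]")
        if self.tract_mean < 1:
            raise ValueError("tract_mean must be >= 1 bp")
        if self.sample_n > self.pop_size:
            raise ValueError("sample_n cannot exceed pop_size")


@dataclass
class EventLog:
    """Per-generation event records sufficient to replay the simulation.

    parents[g][i] is the parent index of offspring i at generation g;
    tracts[g] has rows (recipient, donor, start, end); mutations[g] has
    rows (cell, pos, new_base_code).
    """

    parents: list = field(default_factory=list)
    tracts: list = field(default_factory=list)
    mutations: list = field(default_factory=list)

    def n_tracts(self) -> int:
        return int(sum(len(t) for t in self.tracts))

    def n_mutations(self) -> int:
        return int(sum(len(m) for m in self.mutations))

    def mutation_table(self) -> pd.DataFrame:
        rows = []
        for g, m in enumerate(self.mutations):
            for cell, pos, base in m:
                rows.append((g, int(cell), int(pos), "ACGT"[int(base)]))
        return pd.DataFrame(rows, columns=["generation", "cell", "pos", "base"])

    def tract_table(self) -> pd.DataFrame:
        rows = []
        for g, t in enumerate(self.tracts):
            for rec, don, s, e in t:
                rows.append((g, int(rec), int(don), int(s), int(e)))
        return pd.DataFrame(rows, columns=["generation", "recipient", "donor", "start", "end"])


@dataclass
class PopulationTruth:
    """Sampled genomes plus the complete event history that produced them."""

    params: SimParams
    anc_codes: np.ndarray
    sample_codes: np.ndarray  # (sample_n, L) uint8
    sample_ids: list[str]
    sampled_indices: np.ndarray
    events: EventLog

    @property
    def ancestral(self) -> str:
        return decode(self.anc_codes)

    @property
    def genomes(self) -> list[str]:
        return [decode(row) for row in self.sample_codes]


def simulate_population(
    params: SimParams, ancestral: Optional[np.ndarray] = None
) -> PopulationTruth:
    """Forward Wright-Fisher haploid simulation with tract recombination.

    Each generation every offspring copies a uniformly chosen parent;
    with probability recomb_rate it then imports one tract from a second
    uniformly chosen donor (previous generation); finally point mutations
    are applied at rate mut_rate per site.  After `generations`
    generations, sample_n cells are drawn without replacement.
    """
    p = params
    if p.generations < 10 * p.pop_size:
        logger.warning(
            "generations=%d < 10*pop_size=%d: population may not be at "
            "drift-mutation equilibrium",
            p.generations,
            10 * p.pop_size,
        )
    rng = np.random.default_rng(p.seed)
    N, L = p.pop_size, p.genome_length
    if ancestral is not None:
        if ancestral.size != L:
            raise ValueError("ancestral length must equal genome_length")
        anc = ancestral.astype(np.uint8)
    else:
        anc = rng.integers(0, 4, L, dtype=np.uint8)
    pop = np.tile(anc, (N, 1))
    events = EventLog()
    mu_total = p.mut_rate * N * L
    for _g in range(p.generations):
        parents = rng.integers(0, N, N)
        new = pop[parents]
        # recombination: tract import from the parental generation
        rec = np.flatnonzero(rng.random(N) < p.recomb_rate)
        tr = np.empty((len(rec), 4), dtype=np.int64)
        if len(rec):
            donors = rng.integers(0, N, len(rec))
            starts = rng.integers(0, L, len(rec))
            lengths = rng.geometric(1.0 / p.tract_mean, len(rec))
            ends = np.minimum(L, starts + lengths)
            for k, (r, d, s, e) in enumerate(zip(rec, donors, starts, ends)):
                new[r, s:e] = pop[d, s:e]
                tr[k] = (r, d, s, e)
        # mutation
        n_mut = rng.poisson(mu_total)
        mut = np.empty((n_mut, 3), dtype=np.int64)
        if n_mut:
            cells = rng.integers(0, N, n_mut)
            pos = rng.integers(0, L, n_mut)
            shift = rng.integers(1, 4, n_mut).astype(np.uint8)
            vals = (new[cells, pos] + shift) % 4
            new[cells, pos] = vals
            mut[:, 0], mut[:, 1], mut[:, 2] = cells, pos, vals
        events.parents.append(parents)
        events.tracts.append(tr)
        events.mutations.append(mut)
        pop = new
    idx = rng.choice(N, p.sample_n, replace=False)
    width = max(2, len(str(p.sample_n - 1)))
    ids = [f"cell{str(i).zfill(width)}" for i in range(p.sample_n)]
    return PopulationTruth(
        params=p,
        anc_codes=anc,
        sample_codes=pop[idx].copy(),
        sample_ids=ids,
        sampled_indices=idx,
        events=events,
    )


def replay(truth: PopulationTruth) -> np.ndarray:
    """Re-derive the sampled genomes from the ancestral sequence and the
    event log alone (no random numbers).  Used to verify that the log is a
    complete account of the simulation."""
    p = truth.params
    N, L = p.pop_size, p.genome_length
    pop = np.tile(truth.anc_codes, (N, 1))
    for parents, tracts, muts in zip(
        truth.events.parents, truth.events.tracts, truth.events.mutations
    ):
        new = pop[parents]
        for r, d, s, e in tracts:
            new[r, s:e] = pop[d, s:e]
        if len(muts):
            new[muts[:, 0], muts[:, 1]] = muts[:, 2].astype(np.uint8)
        pop = new
    return pop[truth.sampled_indices].copy()


# ---------------------------------------------------------------------------
# Feature embedding


@dataclass
class MgeSpec:
    mge_id: str
    label: str  # phage | prophage | plasmid
    length: int
    gc: float
    carriage: float

    def __post_init__(self) -> None:
        if self.label not in ("phage", "prophage", "plasmid"):
            raise ValueError(f"bad MGE label {self.label!r}")
        if not (0.0 <= self.carriage <= 1.0):
            raise ValueError("carriage probability must be in [0,1]")
        if self.length < 1:
            raise ValueError("MGE length must be positive")


@dataclass
class CrisprPlan:
    repeat_len: int = 28
    spacer_len: int = 33
    n_spacers: int = 3
    self_frac: float = 0.2


@dataclass
class SsuPlan:
    length: int = 1200
    amplicon: int = 460
    fw_pos: int = 100
    mismatch_frac: float = 0.2
    n_mismatch: int = 2
    intron_frac: float = 0.2
    intron_len: int = 500


@dataclass
class FeaturePlan:
    mge_pool: list[MgeSpec] = field(default_factory=list)
    crispr: Optional[CrisprPlan] = None
    ssu: Optional[SsuPlan] = None


@dataclass
class AugmentedCell:
    cell_id: str
    chrom: np.ndarray  # assembled chromosome codes (core + insertions)
    # (asm_start, asm_end, core_start or -1, feature_id or "") collinear pieces
    segments: list
    replicons: list  # (contig_id, codes, label, mge_id)
    carried: list  # mge_ids carried (any label)


@dataclass
class AugmentedPopulation:
    """A sampled population with embedded features plus truth tables."""

    pop_id: str
    lineage: str
    truth: PopulationTruth
    cells: list[AugmentedCell]
    pool_seqs: dict  # mge_id -> codes
    pool_specs: list[MgeSpec]
    insert_sites: dict  # feature_id -> core position
    mge_carriage: pd.DataFrame
    spacer_origins: pd.DataFrame
    ssu_edits: pd.DataFrame
    crispr_truth: pd.DataFrame
    ssu_seqs: dict  # cell_id -> codes of the (possibly intron-bearing) 16S

    @property
    def core_name(self) -> str:
        return f"{self.pop_id}:core"


def _random_gc_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    is_gc = rng.random(length) < gc
    half = rng.integers(0, 2, length)
    # A=0,C=1,G=2,T=3 : GC -> {1,2}, AT -> {0,3}
    return np.where(is_gc, 1 + half, 3 * half).astype(np.uint8)


def _concrete_primer(rng: np.random.Generator, iupac: str) -> str:
    from .primers import IUPAC_SETS

    return "".join(sorted(IUPAC_SETS[c])[rng.integers(0, len(IUPAC_SETS[c]))] for c in iupac)


def _choose_sites(rng: np.random.Generator, L: int, n: int, min_gap: int = 3000) -> list[int]:
    for _ in range(1000):
        sites = np.sort(rng.integers(2000, L - 2000, n))
        if n < 2 or np.all(np.diff(sites) >= min_gap):
            return [int(s) for s in sites]
    raise RuntimeError("could not place insertion sites; genome too short")


def embed_features(
    truth: PopulationTruth,
    plan: FeaturePlan,
    rng: np.random.Generator,
    pop_id: str = "pop",
    lineage: str = "lineage",
    fw_primer: str = "AAACTYAAAKGAATTGRCGG",
    rv_primer: str = "ACGGGCGGTGTGTRC",
) -> AugmentedPopulation:
    """Embed MGEs, CRISPR arrays and 16S genes into a sampled population.

    Prophages are inserted in-chromosome at a fixed per-element site;
    phage and plasmid elements become separate replicons.  One CRISPR
    array and one 16S gene are inserted per chromosome at fixed sites.
    Spacers are copied verbatim from MGEs the cell carries (or, flagged,
    from the lineage pool when it carries none) and from the cell's own
    chromosome for the self-targeting fraction.
    """
    L = truth.params.genome_length
    n = len(truth.sample_ids)
    pool_seqs = {m.mge_id: _random_gc_seq(rng, m.length, m.gc) for m in plan.mge_pool}
    prophages = [m for m in plan.mge_pool if m.label == "prophage"]
    n_sites = len(prophages) + (1 if plan.crispr else 0) + (1 if plan.ssu else 0)
    site_list = _choose_sites(rng, L, n_sites) if n_sites else []
    insert_sites: dict[str, int] = {}
    i = 0
    for m in prophages:
        insert_sites[m.mge_id] = site_list[i]
        i += 1
    if plan.crispr:
        insert_sites["crispr"] = site_list[i]
        i += 1
    if plan.ssu:
        insert_sites["ssu"] = site_list[i]
        i += 1

    # shared CRISPR repeat and 16S template for the population
    repeat = _random_gc_seq(rng, plan.crispr.repeat_len, 0.5) if plan.crispr else None
    ssu_template = None
    fw_real = rv_real = None
    if plan.ssu:
        s = plan.ssu
        ssu_template = _random_gc_seq(rng, s.length, 0.55)
        fw_real = _concrete_primer(rng, fw_primer)
        rv_real = _concrete_primer(rng, rv_primer)
        ssu_template[s.fw_pos : s.fw_pos + len(fw_real)] = encode(fw_real)
        from ._seq import revcomp

        rv_site = encode(revcomp(rv_real))
        rv_start = s.fw_pos + s.amplicon - len(rv_real)
        ssu_template[rv_start : rv_start + len(rv_real)] = rv_site

    # plan per-cell 16S edit classes: disjoint mismatch / intron subsets
    ssu_class = ["clean"] * n
    if plan.ssu:
        n_mm = int(round(plan.ssu.mismatch_frac * n))
        n_intron = int(round(plan.ssu.intron_frac * n))
        order = rng.permutation(n)
        for j in order[:n_mm]:
            ssu_class[j] = "mismatch"
        for j in order[n_mm : n_mm + n_intron]:
            ssu_class[j] = "intron"

    cells: list[AugmentedCell] = []
    carriage_rows, origin_rows, ssu_rows, crispr_rows = [], [], [], []
    ssu_seqs: dict[str, np.ndarray] = {}
    for ci, cell_id in enumerate(truth.sample_ids):
        core = truth.sample_codes[ci]
        carried = [m.mge_id for m in plan.mge_pool if rng.random() < m.carriage]
        for mid in carried:
            spec = next(m for m in plan.mge_pool if m.mge_id == mid)
            carriage_rows.append((cell_id, mid, spec.label, spec.length))
        replicons = [
            (f"{cell_id}_{m.mge_id}", pool_seqs[m.mge_id].copy(), m.label, m.mge_id)
            for m in plan.mge_pool
            if m.mge_id in carried and m.label in ("phage", "plasmid")
        ]

        # build insertion payloads at fixed sites
        payloads: list[tuple[int, str, np.ndarray]] = []
        for m in prophages:
            if m.mge_id in carried:
                payloads.append((insert_sites[m.mge_id], m.mge_id, pool_seqs[m.mge_id]))
        if plan.crispr:
            cp = plan.crispr
            for _attempt in range(100):
                spacers, origins = [], []
                for si in range(cp.n_spacers):
                    while True:
                        if rng.random() < cp.self_frac:
                            site = insert_sites["crispr"]
                            while True:
                                pos = int(rng.integers(0, L - cp.spacer_len))
                                if abs(pos - site) > 2000:
                                    break
                            seq = core[pos : pos + cp.spacer_len].copy()
                            origin = ("self", cell_id, pos)
                        else:
                            if carried:
                                mid = carried[rng.integers(0, len(carried))]
                                okind = "mge"
                            else:
                                mid = plan.mge_pool[rng.integers(0, len(plan.mge_pool))].mge_id
                                okind = "pool"
                            pos = int(rng.integers(0, len(pool_seqs[mid]) - cp.spacer_len))
                            seq = pool_seqs[mid][pos : pos + cp.spacer_len].copy()
                            origin = (okind, mid, pos)
                        if not any(np.array_equal(seq, s) for s in spacers):
                            break
                    spacers.append(seq)
                    origins.append(origin)
                # keep the true repeat boundaries identifiable: the bases
                # flanking the repeats must be mutually distinct across
                # spacers (up to the 4-letter alphabet), so no boundary
                # column can look repeat-like by chance
                firsts = {int(s[0]) for s in spacers}
                lasts = {int(s[-1]) for s in spacers}
                want = min(len(spacers), 4)
                if len(spacers) < 2 or (len(firsts) >= want and len(lasts) >= want):
                    break
            for si, (seq, origin) in enumerate(zip(spacers, origins)):
                origin_rows.append(
                    (cell_id, f"{cell_id}_sp{si}", decode(seq), origin[0], origin[1], origin[2])
                )
            parts = [repeat]
            for sp in spacers:
                parts.extend([sp, repeat])
            array_codes = np.concatenate(parts)
            payloads.append((insert_sites["crispr"], "crispr", array_codes))
            crispr_rows.append(
                (
                    cell_id,
                    insert_sites["crispr"],
                    decode(repeat),
                    cp.n_spacers,
                    ";".join(decode(s) for s in spacers),
                )
            )
        if plan.ssu:
            s = plan.ssu
            gene = ssu_template.copy()
            cls = ssu_class[ci]
            detail = ""
            if cls == "mismatch":
                # mutate n_mismatch positions of the forward primer site,
                # avoiding the 3'-terminal window so the total-mismatch rule
                # (not the 3' rule) is what fires
                offs = list(range(len(fw_real) - 4))[: s.n_mismatch]
                for o in offs:
                    gene[s.fw_pos + o] = (gene[s.fw_pos + o] + 1) % 4
                detail = f"fw_mm={s.n_mismatch}"
            elif cls == "intron":
                mid = s.fw_pos + len(fw_real) + (s.amplicon - len(fw_real) - len(rv_real)) // 2
                intron = _random_gc_seq(rng, s.intron_len, 0.5)
                gene = np.concatenate([gene[:mid], intron, gene[mid:]])
                detail = f"intron={s.intron_len}"
            payloads.append((insert_sites["ssu"], "ssu", gene))
            ssu_seqs[cell_id] = gene
            ssu_rows.append((cell_id, cls, detail))

        payloads.sort(key=lambda t: t[0])
        pieces, segments = [], []
        asm = 0
        prev = 0
        for site, fid, codes in payloads:
            if site > prev:
                pieces.append(core[prev:site])
                segments.append((asm, asm + site - prev, prev, ""))
                asm += site - prev
            pieces.append(codes)
            segments.append((asm, asm + len(codes), -1, fid))
            asm += len(codes)
            prev = site
        if prev < L:
            pieces.append(core[prev:])
            segments.append((asm, asm + L - prev, prev, ""))
            asm += L - prev
        chrom = np.concatenate(pieces) if pieces else core.copy()
        cells.append(AugmentedCell(cell_id, chrom, segments, replicons, carried))

    return AugmentedPopulation(
        pop_id=pop_id,
        lineage=lineage,
        truth=truth,
        cells=cells,
        pool_seqs=pool_seqs,
        pool_specs=list(plan.mge_pool),
        insert_sites=insert_sites,
        mge_carriage=pd.DataFrame(
            carriage_rows, columns=["cell", "mge_id", "label", "length"]
        ),
        spacer_origins=pd.DataFrame(
            origin_rows, columns=["cell", "spacer_id", "seq", "origin", "source", "source_pos"]
        ),
        ssu_edits=pd.DataFrame(ssu_rows, columns=["cell", "planned_class", "detail"]),
        crispr_truth=pd.DataFrame(
            crispr_rows, columns=["cell", "core_site", "repeat", "n_spacers", "spacers"]
        ),
        ssu_seqs=ssu_seqs,
    )


def plain_population(truth: PopulationTruth, pop_id: str = "pop", lineage: str = "lineage") -> AugmentedPopulation:
    """Wrap a bare population as an AugmentedPopulation with no features."""
    L = truth.params.genome_length
    cells = [
        AugmentedCell(cid, truth.sample_codes[i].copy(), [(0, L, 0, "")], [], [])
        for i, cid in enumerate(truth.sample_ids)
    ]
    empty = pd.DataFrame()
    return AugmentedPopulation(
        pop_id, lineage, truth, cells, {}, [], {},
        empty, empty, empty, empty, {},
    )


def full_assemblies(aug: AugmentedPopulation) -> list[GenomeAssembly]:
    """Complete (no-dropout) single-cell assemblies: whole chromosome plus
    all carried extra replicons.  Used for feature-recovery checks."""
    out = []
    for cell in aug.cells:
        contigs = [SeqRecord(id=f"{cell.cell_id}_chr", seq=decode(cell.chrom))]
        contigs += [SeqRecord(id=cid, seq=decode(codes)) for cid, codes, _, _ in cell.replicons]
        meta = GenomeMeta(kind=GenomeKind.SAG, completeness=1.0, contamination=0.0, lineage=aug.lineage)
        out.append(GenomeAssembly(genome_id=cell.cell_id, contigs=contigs, meta=meta))
    return out


# ---------------------------------------------------------------------------
# MDA-style dropout


@dataclass
class SagParams:
    breadth_mean: float = 0.7
    breadth_sd: float = 0.1
    block_mean: int = 5000
    min_contig: int = 500
    contam_prob: float = 0.0
    uniform_dropout: bool = False  # ablation: per-site instead of block dropout

    def __post_init__(self) -> None:
        if not (0.0 < self.breadth_mean <= 1.0):
            raise ValueError("breadth_mean must be in (0,1]")
        if self.min_contig < 1:
            raise ValueError("min_contig must be >= 1")


@dataclass
class SagifyResult:
    assemblies: list[GenomeAssembly]
    segments: list[AlignmentSegment]  # contig -> population core frame
    recovery: pd.DataFrame  # per-cell breadth draw / realized recovery
    contig_truth: pd.DataFrame  # per-contig provenance incl. MGE labels
    mge_labels: pd.DataFrame  # realized contig_id/genome_id/label (>0 bp)
    # retained pieces of planted MGEs, in MGE-internal coordinates
    feature_segments: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["genome_id", "contig_id", "qstart", "qend", "mge_id", "fstart", "fend"]
        )
    )


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    limit = mean * (1 - mean)
    if var >= limit:
        raise ValueError(
            f"breadth_sd={sd} infeasible for Beta with mean {mean}; need sd < "
            f"{np.sqrt(limit):.4f}"
        )
    nu = limit / var - 1
    return mean * nu, (1 - mean) * nu


def _union(intervals):
    merged = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def _draw_blocks(rng, length: int, target: int, block_mean: int) -> list[tuple[int, int]]:
    """Union of random blocks (uniform start, exponential length) grown
    until it covers target positions; the final block is trimmed so the
    realized coverage matches the drawn breadth."""
    intervals: list[tuple[int, int]] = []
    covered = 0
    guard = 0
    while covered < target and guard < 100000:
        guard += 1
        s = int(rng.integers(0, length))
        ln = max(1, int(rng.exponential(block_mean)))
        e = min(length, s + ln)
        new_cov = sum(b - a for a, b in _union(intervals + [(s, e)]))
        if new_cov > target:
            # trim the block end until the union hits the target exactly
            lo, hi = s + 1, e
            while lo < hi:
                mid = (lo + hi) // 2
                if sum(b - a for a, b in _union(intervals + [(s, mid)])) >= target:
                    hi = mid
                else:
                    lo = mid + 1
            e = lo
        intervals = _union(intervals + [(s, e)])
        covered = sum(b - a for a, b in intervals)
    return intervals


def sagify(aug: AugmentedPopulation, params: SagParams, rng: np.random.Generator) -> SagifyResult:
    """Degrade full genomes into SAG assemblies with contiguous-block
    dropout, fragmentation, a minimum contig size, and optional
    cross-cell contamination."""
    if params.breadth_sd > 0:
        a, b = _beta_params(params.breadth_mean, params.breadth_sd)
    assemblies, all_segments, rec_rows, contig_rows, label_rows = [], [], [], [], []
    fseg_rows = []
    L = aug.truth.params.genome_length
    core_name = aug.core_name
    for ci, cell in enumerate(aug.cells):
        breadth = (
            float(np.clip(rng.beta(a, b), 0.0, 1.0))
            if params.breadth_sd > 0
            else params.breadth_mean
        )
        asm_len = len(cell.chrom)
        if params.uniform_dropout:
            keep = rng.random(asm_len) < breadth
            # contiguous runs of kept positions
            edges = np.flatnonzero(np.diff(np.concatenate(([0], keep.view(np.int8), [0]))))
            intervals = list(zip(edges[::2], edges[1::2]))
        elif breadth >= 1.0:
            intervals = [(0, asm_len)]
        else:
            intervals = _draw_blocks(rng, asm_len, int(breadth * asm_len), params.block_mean)
        contigs, cell_segments = [], []
        k = 0
        recovered_core = 0
        for s, e in intervals:
            if e - s < params.min_contig:
                continue
            cid = f"{cell.cell_id}_c{k}"
            k += 1
            contigs.append(SeqRecord(id=cid, seq=decode(cell.chrom[s:e])))
            contig_rows.append((aug.pop_id, cell.cell_id, cid, e - s, "chromosome", ""))
            # map the retained assembled interval back to core coordinates
            for a0, a1, c0, fid in cell.segments:
                lo, hi = max(s, a0), min(e, a1)
                if lo >= hi:
                    continue
                if c0 >= 0:
                    seg = AlignmentSegment(
                        cell.cell_id, cid, lo - s, hi - s,
                        core_name, c0 + (lo - a0), c0 + (hi - a0), "+",
                    )
                    cell_segments.append(seg)
                    recovered_core += hi - lo
                elif fid:
                    # retained piece of an inserted feature (prophage etc.)
                    frac = (hi - lo) / (a1 - a0)
                    spec = next((m for m in aug.pool_specs if m.mge_id == fid), None)
                    if spec is not None:
                        fseg_rows.append(
                            (cell.cell_id, cid, lo - s, hi - s, fid, lo - a0, hi - a0)
                        )
                        if frac > 0.5:
                            label_rows.append((cid, cell.cell_id, spec.label, hi - lo, fid))
        # extra replicons survive whole with probability = breadth
        for cid, codes, label, mid in cell.replicons:
            if rng.random() < breadth and len(codes) >= params.min_contig:
                contigs.append(SeqRecord(id=cid, seq=decode(codes)))
                contig_rows.append((aug.pop_id, cell.cell_id, cid, len(codes), label, mid))
                label_rows.append((cid, cell.cell_id, label, len(codes), mid))
                fseg_rows.append((cell.cell_id, cid, 0, len(codes), mid, 0, len(codes)))
        # contamination: one foreign contig copied from another cell
        if params.contam_prob > 0 and rng.random() < params.contam_prob and len(aug.cells) > 1:
            others = [j for j in range(len(aug.cells)) if j != ci]
            donor = aug.cells[others[rng.integers(0, len(others))]]
            ln = int(rng.integers(2000, 8001))
            s = int(rng.integers(0, max(1, len(donor.chrom) - ln)))
            cid = f"{cell.cell_id}_contam"
            contigs.append(SeqRecord(id=cid, seq=decode(donor.chrom[s : s + ln])))
            contig_rows.append((aug.pop_id, cell.cell_id, cid, ln, "contaminant", donor.cell_id))
            for a0, a1, c0, fid in donor.segments:
                lo, hi = max(s, a0), min(s + ln, a1)
                if lo >= hi or c0 < 0:
                    continue
                cell_segments.append(
                    AlignmentSegment(
                        cell.cell_id, cid, lo - s, hi - s,
                        core_name, c0 + (lo - a0), c0 + (hi - a0), "+",
                    )
                )
        if not contigs:
            contigs = [SeqRecord(id=f"{cell.cell_id}_c0", seq=decode(cell.chrom[:params.min_contig]))]
        completeness = min(1.0, recovered_core / L)
        meta = GenomeMeta(
            kind=GenomeKind.SAG,
            completeness=completeness,
            contamination=params.contam_prob * 0.05,
            lineage=aug.lineage,
        )
        assemblies.append(GenomeAssembly(genome_id=cell.cell_id, contigs=contigs, meta=meta))
        all_segments.extend(cell_segments)
        rec_rows.append((cell.cell_id, breadth, completeness, len(contigs)))
    return SagifyResult(
        assemblies=assemblies,
        segments=all_segments,
        recovery=pd.DataFrame(rec_rows, columns=["cell", "breadth_draw", "recovered_frac", "n_contigs"]),
        contig_truth=pd.DataFrame(
            contig_rows,
            columns=["pop_id", "cell", "contig_id", "length", "source", "source_id"],
        ),
        mge_labels=pd.DataFrame(
            label_rows, columns=["contig_id", "genome_id", "label", "length", "mge_id"]
        ),
        feature_segments=pd.DataFrame(
            fseg_rows,
            columns=["genome_id", "contig_id", "qstart", "qend", "mge_id", "fstart", "fend"],
        ),
    )


# ---------------------------------------------------------------------------
# Mock MAG


def mock_mag(
    aug: AugmentedPopulation,
    tnf_z_cutoff: float = 2.0,
    min_contig: int = 2500,
    frag_mean: int = 5000,
    rng: Optional[np.random.Generator] = None,
) -> tuple[GenomeAssembly, list[AlignmentSegment], pd.DataFrame]:
    """Build a mock MAG: majority-rule consensus of the sampled core
    chromosomes, fragmented into contigs, pooled with one representative
    contig per MGE circulating in the population, then filtered the way a
    composition binner would -- contigs whose tetranucleotide profile is a
    z-score outlier vs the median contig are excluded, as are contigs
    below the minimum size.  Returns (assembly, core-frame segments,
    exclusion truth)."""
    from .mge import tnf

    rng = rng or np.random.default_rng(0)
    codes = aug.truth.sample_codes
    if codes.shape[0] < 1:
        raise ValueError("population is empty")
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    consensus = counts.argmax(axis=0).astype(np.uint8)  # ties -> lowest base code
    L = consensus.size
    # fragment the consensus
    cuts = [0]
    while cuts[-1] < L:
        cuts.append(min(L, cuts[-1] + max(500, int(rng.exponential(frag_mean)))))
    candidates = []  # (contig_id, codes, kind, core_start)
    for i, (s, e) in enumerate(zip(cuts[:-1], cuts[1:])):
        candidates.append((f"mag_c{i}", consensus[s:e], "consensus", s))
    carried_ids = sorted(set(aug.mge_carriage["mge_id"])) if len(aug.mge_carriage) else []
    for mid in carried_ids:
        spec = next(m for m in aug.pool_specs if m.mge_id == mid)
        candidates.append((f"mag_{mid}", aug.pool_seqs[mid], spec.label, -1))

    contigs, segments, excl_rows = [], [], []
    # size filter first (as a binner would), so short noisy fragments do
    # not distort the composition statistics
    sized = []
    for cid, c, kind, start in candidates:
        if len(c) < min_contig:
            excl_rows.append((cid, kind, len(c), float("nan"), "min_contig"))
        else:
            sized.append((cid, c, kind, start))
    if not sized:
        raise ValueError("all candidate contigs excluded; nothing left to bin")
    profiles = np.stack([tnf(decode(c)).freq for _, c, _, _ in sized])
    median = np.median(profiles, axis=0)
    dists = np.linalg.norm(profiles - median, axis=1)
    # robust z (median/MAD): a plain z-score lets a handful of strong
    # compositional outliers inflate the spread and mask themselves
    mad = np.median(np.abs(dists - np.median(dists)))
    scale = 1.4826 * mad if mad > 0 else (dists.std() or 1.0)
    z = (dists - np.median(dists)) / scale
    for (cid, c, kind, start), zi in zip(sized, z):
        if zi > tnf_z_cutoff:
            excl_rows.append((cid, kind, len(c), float(zi), "tnf_outlier"))
            continue
        contigs.append(SeqRecord(id=cid, seq=decode(c)))
        if start >= 0:
            segments.append(
                AlignmentSegment(f"{aug.pop_id}_MAG", cid, 0, len(c), aug.core_name, start, start + len(c), "+")
            )
    if not contigs:
        raise ValueError("all candidate contigs excluded; nothing left to bin")
    kept_core = sum(s.query_end - s.query_start for s in segments)
    meta = GenomeMeta(kind=GenomeKind.MAG, completeness=min(1.0, kept_core / L), contamination=0.0, lineage=aug.lineage)
    asm = GenomeAssembly(genome_id=f"{aug.pop_id}_MAG", contigs=contigs, meta=meta)
    exclusions = pd.DataFrame(excl_rows, columns=["contig_id", "kind", "length", "tnf_z", "reason"])
    return asm, segments, exclusions


# ---------------------------------------------------------------------------
# Gene emission (ORF-like fixed windows with truth family ids)

_CATEGORIES = ["C", "E", "G", "J", "K", "L", "M", "P", "R", "S", "T", "V"]


def extract_genes(
    aug: AugmentedPopulation,
    assemblies: list[GenomeAssembly],
    segments: list[AlignmentSegment],
    feature_segments: pd.DataFrame,
    gene_length: int = 900,
) -> pd.DataFrame:
    """Emit fixed-length ORF-like gene windows with truth family ids.

    Chromosomal genes are windows of the population core-coordinate grid
    fully contained in a contig's aligned span, so the same window in two
    cells yields alignable homologs (truth family = window index).  MGE
    genes are windows anchored on the element's own coordinate grid
    (consistent across carriers regardless of how the element was split
    over contigs), flagged mge.
    """
    by_contig: dict[tuple[str, str], list[AlignmentSegment]] = {}
    for seg in segments:
        by_contig.setdefault((seg.query_genome, seg.query_contig), []).append(seg)
    fseg_by_contig: dict[tuple[str, str], list] = {}
    for r in feature_segments.itertuples(index=False):
        fseg_by_contig.setdefault((r.genome_id, r.contig_id), []).append(r)
    rows = []
    for asm in assemblies:
        for contig in asm.contigs:
            key = (asm.genome_id, contig.id)
            for seg in by_contig.get(key, []):
                if seg.ref_contig != aug.core_name:
                    continue
                w = -(-seg.ref_start // gene_length)  # ceil division
                while (w + 1) * gene_length <= seg.ref_end:
                    q0 = seg.query_start + (w * gene_length - seg.ref_start)
                    seq = contig.seq[q0 : q0 + gene_length]
                    cat = _CATEGORIES[w % len(_CATEGORIES)]
                    rows.append(
                        (f"{contig.id}_g{w}", asm.genome_id, f"{aug.pop_id}|core|{w}", cat, False, seq)
                    )
                    w += 1
            for fs in fseg_by_contig.get(key, []):
                w = -(-fs.fstart // gene_length)
                while (w + 1) * gene_length <= fs.fend:
                    q0 = fs.qstart + (w * gene_length - fs.fstart)
                    seq = contig.seq[q0 : q0 + gene_length]
                    rows.append(
                        (
                            f"{contig.id}_m{fs.mge_id}_g{w}",
                            asm.genome_id,
                            f"{aug.pop_id}|{fs.mge_id}|{w}",
                            "X",
                            True,
                            seq,
                        )
                    )
                    w += 1
    return pd.DataFrame(
        rows, columns=["gene_id", "genome_id", "family_truth", "category", "mge_flag", "seq"]
    )


# ---------------------------------------------------------------------------
# Community driver (multi-species fixture)


def default_feature_plan(rng: np.random.Generator) -> FeaturePlan:
    """Study-like per-lineage feature plan: a large lytic phage, a
    conjugative-plasmid-like element, and a prophage, all compositionally
    distinct from the host chromosome (low GC), plus one CRISPR array and
    one 16S gene per cell."""
    return FeaturePlan(
        mge_pool=[
            MgeSpec("phageA", "phage", 12_000, 0.30, 0.8),
            MgeSpec("plasA", "plasmid", 11_000, 0.34, 0.6),
            MgeSpec("proA", "prophage", 12_000, 0.30, 0.5),
        ],
        crispr=CrisprPlan(),
        ssu=SsuPlan(),
    )


@dataclass
class SpeciesSim:
    pop_id: str
    lineage: str
    aug: AugmentedPopulation
    sags: SagifyResult
    mag: GenomeAssembly
    mag_segments: list[AlignmentSegment]
    mag_exclusions: pd.DataFrame
    genes: pd.DataFrame


@dataclass
class Community:
    species: list[SpeciesSim]

    @property
    def assemblies(self) -> list[GenomeAssembly]:
        out = []
        for sp in self.species:
            out.extend(sp.sags.assemblies)
            out.append(sp.mag)
        return out


def simulate_community(
    n_species: int = 3,
    pop_size: int = 100,
    genome_length: int = 50_000,
    mut_rate: float = 2.5e-5,
    recomb_rate: float = 1e-2,
    tract_mean: float = 5000.0,
    generations: int = 1000,
    sample_n: int = 16,
    species_divergence: float = 0.12,
    sag_params: Optional[SagParams] = None,
    tnf_z_cutoff: float = 2.0,
    gene_length: int = 900,
    seed: int = 0,
) -> Community:
    """Simulate a community of divergent species-level populations, each a
    Wright-Fisher sample with embedded features, degraded into SAGs, plus
    one mock MAG per species.  Species ancestors are made mutually
    divergent by independent substitution at `species_divergence` of sites
    (pairwise divergence roughly 1.8x that), far beyond the 95% ANI
    species boundary; within-species diversity stays below 1%."""
    root = np.random.default_rng(seed)
    sag_params = sag_params or SagParams()
    species = []
    base = root.integers(0, 4, genome_length, dtype=np.uint8)
    for si in range(n_species):
        pop_id = f"sp{si + 1}"
        lineage = f"Lineage_{chr(ord('A') + si)}"
        sub_seed = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        anc = base.copy()
        n_sub = int(species_divergence * genome_length)
        pos = rng.choice(genome_length, n_sub, replace=False)
        anc[pos] = (anc[pos] + rng.integers(1, 4, n_sub)) % 4
        params = SimParams(
            pop_size=pop_size,
            genome_length=genome_length,
            mut_rate=mut_rate,
            recomb_rate=recomb_rate,
            tract_mean=tract_mean,
            generations=generations,
            sample_n=sample_n,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth = simulate_population(params, ancestral=anc)
        truth.sample_ids = [f"{pop_id}_{cid}" for cid in truth.sample_ids]
        plan = default_feature_plan(rng)
        aug = embed_features(truth, plan, rng, pop_id=pop_id, lineage=lineage)
        sags = sagify(aug, sag_params, rng)
        mag, mag_segments, mag_excl = mock_mag(aug, tnf_z_cutoff=tnf_z_cutoff, rng=rng)
        genes_sag = extract_genes(aug, sags.assemblies, sags.segments, sags.feature_segments, gene_length)
        mag_fsegs = pd.DataFrame(
            [
                (mag.genome_id, c.id, 0, len(c), c.id.split("_", 1)[1], 0, len(c))
                for c in mag.contigs
                if not c.id.startswith("mag_c")
            ],
            columns=["genome_id", "contig_id", "qstart", "qend", "mge_id", "fstart", "fend"],
        )
        genes_mag = extract_genes(aug, [mag], mag_segments, mag_fsegs, gene_length)
        genes = pd.concat([genes_sag, genes_mag], ignore_index=True)
        species.append(
            SpeciesSim(pop_id, lineage, aug, sags, mag, mag_segments, mag_excl, genes)
        )
    return Community(species=species)
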