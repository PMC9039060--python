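"""Gene-family clustering, presence/absence matrices, the >=2-SAG
singleton filter, rarefaction curves, and the SAG-collective vs MAG
gene-content comparison.

Families are built by CD-HIT-style greedy incremental clustering on
nucleotide sequences: genes are processed longest-first and each joins
the first existing family whose representative it matches at the identity
threshold (12-mer prefilter, then full-query infix alignment), otherwise
it founds a new family.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PREFILTER_K = 12


@dataclass
class Gene:
    gene_id: str
    genome_id: str
    seq: str
    category: str = ""
    mge_flag: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) < 90:
            raise ValueError(f"gene {self.gene_id} shorter than 90 bp")


@dataclass
class Family:
    family_id: str
    representative: str  # gene_id
    rep_seq: str
    members: list = field(default_factory=list)  # gene_ids
    genomes: set = field(default_factory=set)
    categories: list = field(default_factory=list)
    mge_flag: bool = False

    @property
    def category(self) -> str:
        if not self.categories:
            return ""
        counts = Counter(self.categories)
        top = max(counts.values())
        return sorted(c for c, v in counts.items() if v == top)[0]


@dataclass
class FamilyMatrix:
    families: list  # of Family
    genome_ids: list
    genome_kinds: dict  # genome_id -> "SAG" | "MAG"

    @property
    def presence(self) -> pd.DataFrame:
        data = {
            f.family_id: [g in f.genomes for g in self.genome_ids] for f in self.families
        }
        return pd.DataFrame(data, index=self.genome_ids).T

    def sag_count(self, fam: Family) -> int:
        return sum(1 for g in fam.genomes if self.genome_kinds.get(g) == "SAG")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family_id": f.family_id,
                    "representative": f.representative,
                    "n_members": len(f.members),
                    "n_genomes": len(f.genomes),
                    "n_sags": self.sag_count(f),
                    "category": f.category,
                    "mge_flag": f.mge_flag,
                    "members": ";".join(f.members),
                }
                for f in self.families
            ]
        )


def _kmers(seq: str, k: int = PREFILTER_K) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(
    genes: list[Gene],
    identity: float = 0.8,
    coverage: float = 0.8,
    genome_kinds: Optional[dict] = None,
) -> FamilyMatrix:
    """Greedy incremental clustering, deterministic given the longest-first
    (then gene_id) processing order.

    A gene joins the first family whose representative it matches: the
    full gene (the shorter of the two) is aligned as an infix of the
    representative, so coverage of the shorter sequence is complete and
    the decision reduces to identity >= threshold.
    """
    if not genes:
        raise ValueError("no genes to cluster")
    order = sorted(genes, key=lambda g: (-len(g.seq), g.gene_id))
    families: list[Family] = []
    index: dict[str, set] = {}  # kmer -> family indices
    for gene in order:
        gk = _kmers(gene.seq)
        candidates = set()
        for km in gk:
            candidates |= index.get(km, set())
        hit = None
        for fi in sorted(candidates):
            fam = families[fi]
            short, long_ = (
                (gene.seq, fam.rep_seq)
                if len(gene.seq) <= len(fam.rep_seq)
                else (fam.rep_seq, gene.seq)
            )
            res = edlib.align(short, long_, mode="HW", task="distance")
            ident = 1.0 - res["editDistance"] / len(short)
            if ident >= identity:
                hit = fam
                break
        if hit is None:
            fam = Family(
                family_id=f"fam{len(families):05d}",
                representative=gene.gene_id,
                rep_seq=gene.seq,
            )
            families.append(fam)
            fi = len(families) - 1
            for km in gk:
                index.setdefault(km, set()).add(fi)
            hit = fam
        hit.members.append(gene.gene_id)
        hit.genomes.add(gene.genome_id)
        if gene.category:
            hit.categories.append(gene.category)
        hit.mge_flag = hit.mge_flag or gene.mge_flag
    genome_ids = sorted({g.genome_id for g in genes})
    kinds = genome_kinds or {g: "SAG" for g in genome_ids}
    return FamilyMatrix(families=families, genome_ids=genome_ids, genome_kinds=kinds)


def drop_singletons(
    fm: FamilyMatrix, min_genomes: int = 2, sag_only_rule: bool = True
) -> FamilyMatrix:
    """Remove families observed in fewer than min_genomes SAGs (the
    two-SAG rule); with sag_only_rule, MAG presence does not rescue a
    family."""
    kept = []
    for f in fm.families:
        count = fm.sag_count(f) if sag_only_rule else len(f.genomes)
        if count >= min_genomes:
            kept.append(f)
    return FamilyMatrix(families=kept, genome_ids=list(fm.genome_ids), genome_kinds=dict(fm.genome_kinds))


def rarefaction(
    fm: FamilyMatrix,
    genomes_subset: Optional[list[str]] = None,
    mode: str = "closed_form",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Expected number of unique families vs genomes sampled.

    closed_form: E[k] = sum_f (1 - C(n-m_f, k)/C(n, k)) where m_f is the
    number of subset genomes carrying family f.  permutation: mean over
    n_perm random orderings of cumulative unique-family counts.
    """
    subset = genomes_subset or [
        g for g in fm.genome_ids if fm.genome_kinds.get(g) == "SAG"
    ]
    n = len(subset)
    if n < 2:
        raise ValueError("need at least 2 genomes for rarefaction")
    sset = set(subset)
    m = np.array([len(f.genomes & sset) for f in fm.families], dtype=np.int64)
    m = m[m > 0]
    ks = np.arange(1, n + 1)
    if mode == "closed_form":
        expected = []
        for k in ks:
            denom = math.comb(n, int(k))
            e = sum(1.0 - math.comb(n - int(mf), int(k)) / denom for mf in m)
            expected.append(e)
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        membership = np.zeros((len(m), n), dtype=bool)
        idx = {g: i for i, g in enumerate(subset)}
        fi = 0
        for f in fm.families:
            inter = f.genomes & sset
            if not inter:
                continue
            for g in inter:
                membership[fi, idx[g]] = True
            fi += 1
        acc = np.zeros(n)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            seen = np.maximum.accumulate(membership[:, perm], axis=1)
            acc += seen.sum(axis=0)
        expected = acc / n_perm
    else:
        raise ValueError(f"unknown rarefaction mode {mode!r}")
    return pd.DataFrame({"k": ks, "expected_families": expected})


def compare_sag_mag(fm: FamilyMatrix, mag_id: str, min_sag_genomes: int = 2) -> dict:
    """Compare collective SAG gene content against the single MAG.

    sag_only: families passing the >=min_sag_genomes SAG rule but absent
    from the MAG.  shared: passing the rule and present in the MAG.
    mag_only: present in the MAG and in zero SAGs.  Reports per-category
    counts and the mobile-element fraction of sag_only.
    """
    mags = [g for g in fm.genome_ids if fm.genome_kinds.get(g) == "MAG"]
    if mags != [mag_id]:
        raise ValueError(
            f"matrix must contain exactly the one MAG {mag_id!r}; found {mags}"
        )
    sag_only, shared, mag_only = [], [], []
    for f in fm.families:
        in_mag = mag_id in f.genomes
        n_sag = fm.sag_count(f)
        if n_sag >= min_sag_genomes:
            (shared if in_mag else sag_only).append(f)
        elif in_mag and n_sag == 0:
            mag_only.append(f)

    def cat_counts(fams):
        return dict(Counter(f.category for f in fams))

    n_so = len(sag_only)
    return {
        "sag_only": [f.family_id for f in sag_only],
        "shared": [f.family_id for f in shared],
        "mag_only": [f.family_id for f in mag_only],
        "sag_only_categories": cat_counts(sag_only),
        "shared_categories": cat_counts(shared),
        "mag_only_categories": cat_counts(mag_only),
        "sag_only_mge_fraction": (
            sum(1 for f in sag_only if f.mge_flag) / n_so if n_so else float("nan")
        ),
    }
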