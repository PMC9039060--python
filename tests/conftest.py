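import numpy as np
import pytest

from sagpop.simulate import (
    SagParams,
    SimParams,
    plain_population,
    sagify,
    simulate_community,
    simulate_population,
)
from sagpop.snp import SnpMatrix
from sagpop.types import GenomeAssembly, GenomeKind, GenomeMeta, SeqRecord


def random_seq(n: int, rng) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def make_genome(genome_id: str, seqs, kind=GenomeKind.SAG, lineage="", completeness=1.0, contamination=0.0):
    contigs = [SeqRecord(id=f"{genome_id}_c{i}", seq=s) for i, s in enumerate(seqs)]
    return GenomeAssembly(
        genome_id=genome_id,
        contigs=contigs,
        meta=GenomeMeta(kind=kind, completeness=completeness, contamination=contamination, lineage=lineage),
    )


def snps_from_codes(codes: np.ndarray, ids, min_minor_count: int = 2) -> SnpMatrix:
    """Independent SNP-matrix construction straight from genotype codes
    (no missing data): the oracle used to cross-check the pipeline path."""
    counts = np.stack([(codes == b).sum(0) for b in range(4)])
    called = counts.sum(0)
    nall = (counts > 0).sum(0)
    order = np.argsort(-counts, axis=0, kind="stable")
    minor_ct = np.take_along_axis(counts, order[1][None], 0)[0]
    keep = np.flatnonzero((nall == 2) & (minor_ct >= min_minor_count))
    geno = (codes[:, keep] == order[1][keep][None, :]).astype(np.int8)
    return SnpMatrix(
        reference_id="oracle",
        cells=list(ids),
        contig_names=["chr"],
        site_contig=np.zeros(len(keep), dtype=int),
        site_pos=keep.astype(np.int64),
        major=order[0][keep].astype(np.uint8),
        minor=order[1][keep].astype(np.uint8),
        minor_count=minor_ct[keep].astype(np.int64),
        called_count=called[keep].astype(np.int64),
        geno=geno,
    )


@pytest.fixture(scope="session")
def community():
    """The default three-species synthetic community used by the
    integration-style checks (one fixed seed for the whole session)."""
    return simulate_community(seed=11)


@pytest.fixture(scope="session")
def small_population():
    params = SimParams(
        pop_size=60, genome_length=20_000, mut_rate=2.5e-5, recomb_rate=0.0,
        generations=600, sample_n=12, seed=5,
    )
    return simulate_population(params)


@pytest.fixture(scope="session")
def dropout_sags(small_population):
    rng = np.random.default_rng(17)
    aug = plain_population(small_population, pop_id="p", lineage="L")
    return aug, sagify(aug, SagParams(breadth_mean=0.7, breadth_sd=0.1), rng)
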