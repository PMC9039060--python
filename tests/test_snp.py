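import numpy as np
import pytest

from sagpop.simulate import SagParams, plain_population, sagify
from sagpop.snp import (
    AlleleMatrix,
    build_allele_matrix,
    call_snps,
    compose_segments,
    select_reference,
)
from sagpop.types import AlignmentSegment, GenomeKind

from conftest import make_genome, snps_from_codes


def test_select_reference_prefers_complete_low_contamination():
    gs = [
        make_genome("g1", ["A" * 100], completeness=0.90, contamination=0.02),
        make_genome("g2", ["A" * 100], completeness=0.95, contamination=0.06),
        make_genome("g3", ["A" * 100], completeness=0.80, contamination=0.01),
    ]
    assert select_reference(gs) == "g1"  # g2 excluded: contamination >= 0.05


def test_select_reference_single_and_tie_rules():
    only = [make_genome("solo", ["A" * 50], completeness=0.5, contamination=0.0)]
    assert select_reference(only) == "solo"
    tie = [
        make_genome("b", ["A" * 50], completeness=0.9, contamination=0.01),
        make_genome("a", ["A" * 50], completeness=0.9, contamination=0.01),
    ]
    assert select_reference(tie) == "a"


def test_select_reference_no_eligible_sag_lists_candidates():
    gs = [make_genome("g1", ["A" * 50], contamination=0.5)]
    with pytest.raises(ValueError, match="g1"):
        select_reference(gs)


def _tiling_segments(genomes, ref):
    segs = []
    for g in genomes:
        off = 0
        for c in g.contigs:
            segs.append(
                AlignmentSegment(g.genome_id, c.id, 0, len(c), ref.contigs[0].id, off, off + len(c), "+")
            )
            off += len(c)
    return segs


def test_full_tiling_gives_zero_missing_and_zero_mismatch():
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    ref = make_genome("ref", [seq])
    other = make_genome("o", [seq[:150], seq[150:]])
    segs = [
        AlignmentSegment("ref", "ref_c0", 0, 400, "ref_c0", 0, 400, "+"),
        AlignmentSegment("o", "o_c0", 0, 150, "ref_c0", 0, 150, "+"),
        AlignmentSegment("o", "o_c1", 0, 250, "ref_c0", 150, 400, "+"),
    ]
    am = build_allele_matrix([ref, other], "ref", segs)
    assert (am.calls != 4).all()
    assert (am.calls[0] == am.calls[1]).all()


def test_conflicting_overlap_becomes_missing(caplog):
    ref = make_genome("ref", ["AAAAAAAAAA"])
    q = make_genome("q", ["AAAAA", "AATAA"])
    segs = [
        AlignmentSegment("ref", "ref_c0", 0, 10, "ref_c0", 0, 10, "+"),
        AlignmentSegment("q", "q_c0", 0, 5, "ref_c0", 0, 5, "+"),
        AlignmentSegment("q", "q_c1", 0, 5, "ref_c0", 0, 5, "+"),  # disagrees at pos 2
    ]
    with caplog.at_level("INFO"):
        am = build_allele_matrix([ref, q], "ref", segs)
    qrow = am.cells.index("q")
    assert am.calls[qrow, 2] == 4
    assert am.n_conflicts == 1


def test_minus_strand_segment_complements_bases():
    ref = make_genome("ref", ["ACGTACGT"])
    q = make_genome("q", ["ACGTACGT"])  # reverse complement of itself
    segs = [
        AlignmentSegment("ref", "ref_c0", 0, 8, "ref_c0", 0, 8, "+"),
        AlignmentSegment("q", "q_c0", 0, 8, "ref_c0", 0, 8, "-"),
    ]
    am = build_allele_matrix([ref, q], "ref", segs)
    assert (am.calls[am.cells.index("q")] == am.calls[am.cells.index("ref")]).all()


def test_unknown_contig_in_alignment_errors():
    ref = make_genome("ref", ["ACGT" * 10])
    segs = [
        AlignmentSegment("ref", "ref_c0", 0, 5, "ref_c0", 0, 5, "+"),
        AlignmentSegment("ref", "ref_c0", 0, 5, "nope", 0, 5, "+"),
    ]
    with pytest.raises(ValueError, match="nope"):
        build_allele_matrix([ref], "ref", segs)
    segs2 = [AlignmentSegment("ref", "phantom", 0, 5, "ref_c0", 0, 5, "+")]
    with pytest.raises(ValueError, match="phantom"):
        build_allele_matrix([ref], "ref", segs2)


def test_call_snps_toy_filters():
    # 5 cells x 3 sites: monomorphic; biallelic minor count 1; minor count 2
    calls = np.array(
        [
            [0, 0, 0],
            [0, 0, 0],
            [0, 0, 1],
            [0, 1, 1],
            [0, 0, 0],
        ],
        dtype=np.uint8,
    )
    am = AlleleMatrix(
        reference_id="r", cells=[f"c{i}" for i in range(5)], contig_names=["k"],
        contig_index=np.zeros(3, dtype=int), pos=np.arange(3), calls=calls,
    )
    snp = call_snps(am, min_called_cells=5, min_called_frac=0.5, min_minor_count=2)
    assert snp.n_sites == 1 and snp.site_pos[0] == 2
    assert snp.minor_count[0] == 2


def test_call_snps_excludes_triallelic_and_all_missing():
    calls = np.array(
        [
            [0, 4],
            [1, 4],
            [2, 4],
            [0, 4],
            [1, 4],
        ],
        dtype=np.uint8,
    )
    am = AlleleMatrix(
        reference_id="r", cells=[f"c{i}" for i in range(5)], contig_names=["k"],
        contig_index=np.zeros(2, dtype=int), pos=np.arange(2), calls=calls,
    )
    snp = call_snps(am, min_called_cells=2, min_called_frac=0.0, min_minor_count=1)
    assert snp.n_sites == 0


def test_major_allele_tie_goes_to_alphabetically_first_base():
    calls = np.array([[3], [3], [0], [0]], dtype=np.uint8)  # 2 T vs 2 A
    am = AlleleMatrix(
        reference_id="r", cells=list("wxyz"), contig_names=["k"],
        contig_index=np.zeros(1, dtype=int), pos=np.arange(1), calls=calls,
    )
    snp = call_snps(am, min_called_cells=2, min_called_frac=0.0, min_minor_count=1)
    assert snp.major[0] == 0 and snp.minor[0] == 3


def test_snp_calls_match_truth_at_full_breadth(small_population):
    """With 100% breadth and no contamination, pipeline SNP positions must
    equal the truth's segregating sites under the same filters."""
    truth = small_population
    aug = plain_population(truth, pop_id="p")
    res = sagify(aug, SagParams(breadth_mean=1.0, breadth_sd=0.0), np.random.default_rng(1))
    ref = select_reference(res.assemblies)
    am = build_allele_matrix(res.assemblies, ref, res.segments)
    snp = call_snps(am, min_called_cells=2, min_called_frac=1.0, min_minor_count=2)
    oracle = snps_from_codes(truth.sample_codes, truth.sample_ids, min_minor_count=2)
    assert set(snp.site_pos) == set(oracle.site_pos)
    # genotypes agree site by site (cells sorted identically)
    order = np.argsort(snp.site_pos)
    o_order = np.argsort(oracle.site_pos)
    cell_map = [oracle.cells.index(c) for c in snp.cells]
    assert np.array_equal(snp.geno[:, order], oracle.geno[cell_map][:, o_order])


def test_relabeling_cells_permutes_rows_only(small_population):
    truth = small_population
    aug = plain_population(truth, pop_id="p")
    res = sagify(aug, SagParams(breadth_mean=1.0, breadth_sd=0.0), np.random.default_rng(1))
    ref = select_reference(res.assemblies)
    am = build_allele_matrix(res.assemblies, ref, res.segments)
    a = call_snps(am, min_called_cells=2, min_called_frac=1.0)
    # relabel by reversing ids
    mapping = {c: f"zz_{i}" for i, c in enumerate(reversed(am.cells))}
    for g in res.assemblies:
        g.genome_id = mapping[g.genome_id]
    segs = [
        AlignmentSegment(mapping[s.query_genome], s.query_contig, s.query_start,
                         s.query_end, s.ref_contig, s.ref_start, s.ref_end, s.strand)
        for s in res.segments
    ]
    am2 = build_allele_matrix(res.assemblies, mapping[ref], segs)
    b = call_snps(am2, min_called_cells=2, min_called_frac=1.0)
    assert np.array_equal(a.site_pos, b.site_pos)
    assert np.array_equal(np.sort(a.minor_count), np.sort(b.minor_count))


def test_compose_segments_reexpresses_common_frame():
    seg_ref = AlignmentSegment("R", "Rc", 10, 60, "core", 100, 150, "+")
    seg_q = AlignmentSegment("Q", "Qc", 0, 100, "core", 80, 180, "+")
    out = compose_segments([seg_ref, seg_q], "R")
    q = [s for s in out if s.query_genome == "Q"]
    assert len(q) == 1
    s = q[0]
    assert (s.ref_contig, s.ref_start, s.ref_end) == ("Rc", 10, 60)
    assert (s.query_start, s.query_end) == (20, 70)
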