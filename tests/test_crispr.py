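import numpy as np
import pandas as pd
import pytest

from sagpop._seq import revcomp
from sagpop.crispr import (
    find_arrays,
    hits_to_frame,
    match_spacers,
    spacer_rarefaction,
)

from conftest import make_genome, random_seq


def planted_array(rng, n_spacers=3, repeat_len=28, spacer_len=33):
    repeat = random_seq(repeat_len, rng)
    spacers = [random_seq(spacer_len, rng) for _ in range(n_spacers)]
    seq = repeat
    for sp in spacers:
        seq += sp + repeat
    return repeat, spacers, seq


def test_planted_array_recovered_exactly():
    rng = np.random.default_rng(0)
    repeat, spacers, arr = planted_array(rng)
    contig = random_seq(5000, rng) + arr + random_seq(5000, rng)
    g = make_genome("g1", [contig])
    found = find_arrays(g)
    assert len(found) == 1
    a = found[0]
    assert a.repeat_consensus == repeat
    assert [s for s, _, _ in a.spacers] == spacers
    assert a.n_repeats == 4
    assert contig[a.start : a.start + 28] == repeat


def test_variable_spacer_lengths_are_handled():
    rng = np.random.default_rng(1)
    repeat = random_seq(30, rng)
    spacers = [random_seq(l, rng) for l in (20, 35, 48)]
    arr = repeat + spacers[0] + repeat + spacers[1] + repeat + spacers[2] + repeat
    g = make_genome("g1", [random_seq(3000, rng) + arr + random_seq(3000, rng)])
    found = find_arrays(g)
    assert len(found) == 1
    assert [s for s, _, _ in found[0].spacers] == spacers


def test_tandem_repeat_rejected_by_distinctness_guard():
    rng = np.random.default_rng(2)
    unit = random_seq(60, rng)  # period admissible, "spacers" identical
    g = make_genome("g1", [random_seq(2000, rng) + unit * 6 + random_seq(2000, rng)])
    assert find_arrays(g) == []


def test_random_sequence_has_no_arrays():
    rng = np.random.default_rng(3)
    g = make_genome("g1", [random_seq(50_000, rng)])
    assert find_arrays(g) == []


def _community_with_spacers(rng):
    phage = random_seq(12_000, rng)
    repeat = random_seq(28, rng)
    spacer_from_b = phage[4000:4033]
    chromA = random_seq(30_000, rng)
    self_target = chromA[20_000:20_033]
    spacer3 = random_seq(33, rng)
    arr = repeat + spacer_from_b + repeat + self_target + repeat + spacer3 + repeat
    chromA = chromA[:5000] + arr + chromA[5000:]
    gA = make_genome("A", [chromA], lineage="L1")
    gB = make_genome("B", [random_seq(20_000, rng), phage], lineage="L1")
    gC = make_genome("C", [random_seq(20_000, rng)], lineage="L2")
    groups = {"A": "g1", "B": "g1", "C": "g2"}
    return gA, gB, gC, groups, spacer_from_b, self_target


def test_spacer_hit_classification_by_construction():
    rng = np.random.default_rng(4)
    gA, gB, gC, groups, sp_mge, sp_self = _community_with_spacers(rng)
    arrays = find_arrays(gA)
    assert len(arrays) == 1
    spacers = pd.DataFrame(
        [
            {
                "spacer_id": f"A_s{i}",
                "genome_id": "A",
                "contig_id": arrays[0].contig_id,
                "array_start": arrays[0].start,
                "array_end": arrays[0].end,
                "seq": s,
            }
            for i, (s, _, _) in enumerate(arrays[0].spacers)
        ]
    )
    hits = hits_to_frame(match_spacers(spacers, [gA, gB, gC], species_groups=groups))
    mge_hits = hits[hits["spacer_id"] == "A_s0"]
    assert (mge_hits["hit_class"] == "within_lineage").all()
    assert (mge_hits["target_genome"] == "B").all()
    assert (mge_hits["mismatches"] == 0).all()
    self_hits = hits[hits["spacer_id"] == "A_s1"]
    assert len(self_hits) == 1 and self_hits.iloc[0]["hit_class"] == "self"
    assert not (hits["hit_class"] == "cross_lineage").any()


def test_hits_inside_source_array_are_excluded():
    rng = np.random.default_rng(5)
    gA, gB, gC, groups, *_ = _community_with_spacers(rng)
    arrays = find_arrays(gA)
    (arr,) = arrays
    spacers = pd.DataFrame(
        [
            {
                "spacer_id": "A_s0",
                "genome_id": "A",
                "contig_id": arr.contig_id,
                "array_start": arr.start,
                "array_end": arr.end,
                "seq": arr.spacers[2][0],  # random spacer: only array copy exists
            }
        ]
    )
    hits = match_spacers(spacers, [gA], species_groups=groups)
    assert hits == []


def test_reverse_strand_hits_are_found():
    rng = np.random.default_rng(6)
    spacer = random_seq(33, rng)
    target = make_genome("T", [random_seq(1000, rng) + revcomp(spacer) + random_seq(1000, rng)], lineage="L")
    spacers = pd.DataFrame(
        [{"spacer_id": "s", "genome_id": "S", "contig_id": "none", "array_start": 0, "array_end": 0, "seq": spacer}]
    )
    hits = match_spacers(spacers, [target], species_groups={"S": "g1", "T": "g1"})
    assert len(hits) == 1 and hits[0].strand == "-"


def test_one_mismatch_matching_and_short_spacer_error():
    rng = np.random.default_rng(7)
    spacer = random_seq(33, rng)
    mutated = list(spacer)
    mutated[10] = "ACGT"[("ACGT".index(mutated[10]) + 1) % 4]
    target = make_genome("T", [random_seq(500, rng) + "".join(mutated) + random_seq(500, rng)], lineage="L")
    spacers = pd.DataFrame(
        [{"spacer_id": "s", "genome_id": "S", "contig_id": "none", "array_start": 0, "array_end": 0, "seq": spacer}]
    )
    hits = match_spacers(spacers, [target], max_mismatch=1, species_groups={"S": "g", "T": "g"})
    assert len(hits) == 1 and hits[0].mismatches == 1
    bad = spacers.assign(seq="ACGTACGTACGT")
    with pytest.raises(ValueError, match="shorter than 17"):
        match_spacers(bad, [target], species_groups={"S": "g", "T": "g"})


def test_spacer_rarefaction_examples():
    shared = {"g1": {"AAACCCGGGTTTAAACCCGGG"}, "g2": {"AAACCCGGGTTTAAACCCGGG"}}
    flat = spacer_rarefaction(shared)
    assert np.allclose(flat["expected_spacers"], 1.0)
    # reverse-complement duplicates count once
    rc = {"g1": {"AAACCCGGGTTTAAACCCGGG"}, "g2": {revcomp("AAACCCGGGTTTAAACCCGGG")}}
    assert np.allclose(spacer_rarefaction(rc)["expected_spacers"], 1.0)
    rng = np.random.default_rng(8)
    disjoint = {f"g{i}": {random_seq(25, rng) for _ in range(10)} for i in range(4)}
    curve = spacer_rarefaction(disjoint)
    assert np.allclose(curve["expected_spacers"], 10 * curve["k"])


def test_spacer_rarefaction_permutation_agreement():
    rng = np.random.default_rng(9)
    pool = [random_seq(25, rng) for _ in range(60)]
    sets = {
        f"g{i:02d}": {pool[j] for j in rng.choice(60, rng.integers(3, 25), replace=False)}
        for i in range(20)
    }
    closed = spacer_rarefaction(sets, mode="closed_form")
    perm = spacer_rarefaction(sets, mode="permutation", n_perm=5000, seed=1)
    assert np.max(np.abs(closed["expected_spacers"] - perm["expected_spacers"])) < 0.5
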