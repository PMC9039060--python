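import numpy as np
import pytest

from sagpop.simulate import (
    CrisprPlan,
    FeaturePlan,
    MgeSpec,
    SagParams,
    SimParams,
    SsuPlan,
    embed_features,
    mock_mag,
    plain_population,
    replay,
    sagify,
    simulate_population,
)

WATTERSON_PARAMS = SimParams(
    pop_size=100, genome_length=10_000, mut_rate=2.5e-5, recomb_rate=0.0,
    generations=1000, sample_n=20,
)


def _feature_plan(self_frac=0.2, mm_frac=0.2, intron_frac=0.2, carriage=0.8):
    return FeaturePlan(
        mge_pool=[
            MgeSpec("ph", "phage", 12_000, 0.30, carriage),
            MgeSpec("pl", "plasmid", 11_000, 0.35, carriage),
            MgeSpec("pr", "prophage", 12_000, 0.30, carriage),
        ],
        crispr=CrisprPlan(self_frac=self_frac),
        ssu=SsuPlan(mismatch_frac=mm_frac, intron_frac=intron_frac),
    )


def test_same_seed_gives_identical_genomes():
    p = SimParams(pop_size=30, genome_length=5000, generations=120, sample_n=8, seed=9)
    a, b = simulate_population(p), simulate_population(p)
    assert np.array_equal(a.sample_codes, b.sample_codes)
    assert a.sample_ids == b.sample_ids


def test_no_recombination_leaves_tract_log_empty():
    p = SimParams(pop_size=30, genome_length=5000, recomb_rate=0.0, generations=120, sample_n=5, seed=2)
    truth = simulate_population(p)
    assert truth.events.n_tracts() == 0


def test_event_log_replay_reproduces_sampled_genomes_exactly():
    p = SimParams(
        pop_size=40, genome_length=8000, mut_rate=5e-5, recomb_rate=0.05,
        generations=400, sample_n=10, seed=4,
    )
    truth = simulate_population(p)
    assert truth.events.n_tracts() > 0
    assert np.array_equal(replay(truth), truth.sample_codes)


def test_segregating_sites_match_watterson_expectation():
    """Mean S over replicates ~ 2*N*mu*L*a_{n-1} (neutral equilibrium)."""
    n = WATTERSON_PARAMS.sample_n
    theta_l = 2 * WATTERSON_PARAMS.pop_size * WATTERSON_PARAMS.mut_rate * WATTERSON_PARAMS.genome_length
    expected = theta_l * sum(1 / i for i in range(1, n))
    ss = []
    for seed in range(50):
        p = SimParams(**{**WATTERSON_PARAMS.__dict__, "seed": seed})
        g = simulate_population(p).sample_codes
        ss.append(int((g != g[0]).any(axis=0).sum()))
    mean_s = np.mean(ss)
    assert abs(mean_s - expected) / expected < 0.15


def test_equilibrium_warning_for_short_runs(caplog):
    p = SimParams(pop_size=50, genome_length=2000, generations=50, sample_n=5, seed=1)
    with caplog.at_level("WARNING"):
        simulate_population(p)
    assert any("equilibrium" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# feature embedding


@pytest.fixture(scope="module")
def base_truth():
    return simulate_population(
        SimParams(pop_size=50, genome_length=50_000, generations=500, sample_n=10, seed=21)
    )


def test_self_fraction_zero_has_no_self_origins(base_truth):
    aug = embed_features(base_truth, _feature_plan(self_frac=0.0), np.random.default_rng(1))
    assert not (aug.spacer_origins["origin"] == "self").any()


def test_full_carriage_places_plasmid_in_every_cell(base_truth):
    aug = embed_features(base_truth, _feature_plan(carriage=1.0), np.random.default_rng(2))
    plasmid = aug.mge_carriage[aug.mge_carriage["label"] == "plasmid"]
    assert set(plasmid["cell"]) == set(base_truth.sample_ids)


def test_planned_mismatch_fraction_hits_exact_cell_count(base_truth):
    aug = embed_features(base_truth, _feature_plan(mm_frac=0.3, intron_frac=0.0), np.random.default_rng(3))
    n_mm = (aug.ssu_edits["planned_class"] == "mismatch").sum()
    assert n_mm == round(0.3 * len(base_truth.sample_ids))


# ---------------------------------------------------------------------------
# sagify


def test_full_breadth_recovers_whole_genome(base_truth):
    aug = plain_population(base_truth)
    res = sagify(aug, SagParams(breadth_mean=1.0, breadth_sd=0.0, contam_prob=0.0), np.random.default_rng(4))
    for asm, cell in zip(res.assemblies, aug.cells):
        joined = "".join(c.seq for c in asm.contigs)
        assert joined == "".join("ACGT"[b] for b in cell.chrom)


def test_mean_recovered_fraction_tracks_breadth_mean():
    truth = simulate_population(
        SimParams(pop_size=100, genome_length=20_000, generations=200, sample_n=100, seed=7)
    )
    res = sagify(plain_population(truth), SagParams(breadth_mean=0.6, breadth_sd=0.1), np.random.default_rng(8))
    assert 0.55 <= res.recovery["recovered_frac"].mean() <= 0.65


def test_contamination_probability_one_adds_one_foreign_contig(base_truth):
    res = sagify(
        plain_population(base_truth),
        SagParams(breadth_mean=0.8, breadth_sd=0.05, contam_prob=1.0),
        np.random.default_rng(9),
    )
    contam = res.contig_truth[res.contig_truth["source"] == "contaminant"]
    assert len(contam) == len(base_truth.sample_ids)
    assert contam.groupby("cell").size().eq(1).all()


def test_infeasible_breadth_sd_raises_with_feasible_range():
    with pytest.raises(ValueError, match="sd"):
        sagify(
            plain_population(
                simulate_population(SimParams(pop_size=10, genome_length=2000, generations=20, sample_n=3, seed=0))
            ),
            SagParams(breadth_mean=0.5, breadth_sd=0.6),
            np.random.default_rng(0),
        )


# ---------------------------------------------------------------------------
# mock MAG


def test_mock_mag_excludes_low_gc_mge_as_tnf_outlier(base_truth):
    aug = embed_features(base_truth, _feature_plan(carriage=1.0), np.random.default_rng(10))
    _, _, excl = mock_mag(aug, tnf_z_cutoff=2.0, rng=np.random.default_rng(11))
    outliers = set(excl[excl["reason"] == "tnf_outlier"]["contig_id"])
    assert "mag_ph" in outliers


def test_mock_mag_min_contig_rule(base_truth):
    aug = plain_population(base_truth)
    _, _, excl = mock_mag(aug, tnf_z_cutoff=50.0, min_contig=2500, frag_mean=3000, rng=np.random.default_rng(12))
    small = excl[excl["reason"] == "min_contig"]
    assert (small["length"] < 2500).all()
    assert len(small) > 0


def test_mock_mag_homogeneous_composition_has_no_tnf_outliers(base_truth):
    aug = plain_population(base_truth)  # no MGEs planted
    asm, segs, excl = mock_mag(aug, tnf_z_cutoff=3.5, rng=np.random.default_rng(13))
    assert not (excl["reason"] == "tnf_outlier").any()
    # consensus fragments map back onto the core frame
    assert all(s.ref_contig == aug.core_name for s in segs)
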