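import math

import numpy as np
import pytest

from sagpop.ld import (
    BELOW_MIN,
    NOT_REACHED,
    LdCurve,
    _all_pairs_r2,
    bootstrap_ld50,
    filter_maf,
    ld50,
    ld_profile,
    pair_r2,
    unlinked_fraction_distance,
)
from sagpop.snp import SnpMatrix


def _matrix(geno: np.ndarray, pos=None, contig=None) -> SnpMatrix:
    n, s = geno.shape
    pos = np.arange(s, dtype=np.int64) if pos is None else np.asarray(pos, dtype=np.int64)
    contig = np.zeros(s, dtype=int) if contig is None else np.asarray(contig)
    called = (geno >= 0).sum(axis=0)
    minor = np.where(geno > 0, 1, 0).sum(axis=0)
    return SnpMatrix(
        reference_id="t", cells=[f"c{i}" for i in range(n)], contig_names=["k", "l"],
        site_contig=contig, site_pos=pos, major=np.zeros(s, dtype=np.uint8),
        minor=np.ones(s, dtype=np.uint8), minor_count=minor, called_count=called,
        geno=geno.astype(np.int8),
    )


def brute_force_r2(gi, gj):
    """Independent 2x2 haplotype-table oracle."""
    ok = (gi >= 0) & (gj >= 0)
    gi, gj = gi[ok], gj[ok]
    n = len(gi)
    if n == 0:
        return None
    n_ab = int(((gi == 1) & (gj == 1)).sum())
    n_a = int((gi == 1).sum())
    n_b = int((gj == 1).sum())
    pa, pb, pab = n_a / n, n_b / n, n_ab / n
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom == 0:
        return None
    d = pab - pa * pb
    return n, d * d / denom


@pytest.mark.parametrize(
    "counts,expected",
    [
        ({"AB": 4, "ab": 4}, 1.0),
        ({"AB": 2, "Ab": 2, "aB": 2, "ab": 2}, 0.0),
        ({"AB": 3, "Ab": 1, "aB": 1, "ab": 3}, 0.25),
    ],
)
def test_pair_r2_hand_examples(counts, expected):
    gi, gj = [], []
    for hap, k in counts.items():
        for _ in range(k):
            gi.append(1 if hap[0] == "A" else 0)
            gj.append(1 if hap[1] == "B" else 0)
    r = pair_r2(np.array(gi, dtype=np.int8), np.array(gj, dtype=np.int8), min_cells=2)
    assert r.r2 == pytest.approx(expected, abs=1e-12)


def test_pair_r2_exclusions():
    mono = np.zeros(8, dtype=np.int8)
    poly = np.array([0, 1] * 4, dtype=np.int8)
    assert pair_r2(mono, poly) is None
    few = np.array([0, 1, -1, -1, -1, -1, -1, -1], dtype=np.int8)
    assert pair_r2(few, poly, min_cells=5) is None


def test_all_pairs_matches_brute_force_with_missingness():
    """Vectorized r^2 equals the haplotype-table oracle on randomized
    matrices with 30% missing data, exact to 1e-12."""
    rng = np.random.default_rng(42)
    for _ in range(5):
        geno = rng.integers(0, 2, (20, 15)).astype(np.int8)
        geno[rng.random((20, 15)) < 0.3] = -1
        snp = _matrix(geno, pos=np.sort(rng.choice(10_000, 15, replace=False)))
        dist, r2, ncells = _all_pairs_r2(snp, min_cells=5)
        got = {(d, n): r for d, r, n in zip(dist, r2, ncells)}
        expected = {}
        for i in range(15):
            for j in range(i + 1, 15):
                res = brute_force_r2(snp.geno[:, i], snp.geno[:, j])
                if res is None or res[0] < 5:
                    continue
                n, r = res
                expected[(abs(int(snp.site_pos[j] - snp.site_pos[i])), n)] = r
        assert set(got) == set(expected)
        for key in got:
            assert got[key] == pytest.approx(expected[key], abs=1e-12)


def test_profile_two_sites_single_bin():
    geno = np.array([[0, 0]] * 4 + [[1, 1]] * 4, dtype=np.int8)
    snp = _matrix(geno, pos=[100, 157])
    curve = ld_profile(snp, bins=np.array([10.0, 100.0, 1000.0]), min_cells=2)
    assert curve.pair_count.tolist() == [1, 0]
    assert curve.mean_r2[0] == pytest.approx(1.0)


def test_profile_invariant_under_cell_duplication():
    rng = np.random.default_rng(1)
    geno = rng.integers(0, 2, (12, 8)).astype(np.int8)
    snp = _matrix(geno, pos=np.sort(rng.choice(5000, 8, replace=False)))
    doubled = _matrix(np.vstack([geno, geno]), pos=snp.site_pos)
    c1 = ld_profile(snp, min_cells=2)
    c2 = ld_profile(doubled, min_cells=2)
    np.testing.assert_allclose(c1.mean_r2, c2.mean_r2, equal_nan=True)


def test_cross_contig_pairs_are_not_scored():
    geno = np.array([[0, 0], [0, 0], [1, 1], [1, 1], [0, 1], [1, 0]], dtype=np.int8)
    snp = _matrix(geno, pos=[0, 50], contig=[0, 1])
    with pytest.raises(ValueError):
        ld_profile(snp, min_cells=2)


def test_ld50_log_interpolation_hand_value():
    # edges 80/125/320 -> geometric midpoints exactly 100 and 200
    curve = LdCurve(
        bin_edges=np.array([80.0, 125.0, 320.0]),
        mean_r2=np.array([0.8, 0.2]),
        pair_count=np.array([50, 50]),
    )
    np.testing.assert_allclose(curve.midpoints, [100.0, 200.0])
    expected = 10 ** (2 + math.log10(2) * (0.8 - 0.5) / (0.8 - 0.2))
    assert ld50(curve) == pytest.approx(expected)  # ~141.4 bp


def test_ld50_sentinels():
    high = LdCurve(np.array([10.0, 100.0, 1000.0]), np.array([0.9, 0.6]), np.array([40, 40]))
    assert ld50(high) == NOT_REACHED
    low = LdCurve(np.array([10.0, 100.0, 1000.0]), np.array([0.3, 0.2]), np.array([40, 40]))
    assert ld50(low) == BELOW_MIN
    assert low.ld50_upper_bound == pytest.approx(math.sqrt(10 * 100))
    sparse = LdCurve(np.array([10.0, 100.0]), np.array([0.9]), np.array([3]))
    with pytest.raises(ValueError):
        ld50(sparse, min_pairs_per_bin=10)


def test_ld50_takes_first_crossing_of_nonmonotone_curve():
    curve = LdCurve(
        bin_edges=np.array([10.0, 100.0, 1000.0, 10_000.0, 100_000.0]),
        mean_r2=np.array([0.9, 0.3, 0.8, 0.2]),
        pair_count=np.array([50, 50, 50, 50]),
    )
    v = ld50(curve)
    assert isinstance(v, float)
    assert v < 1000  # between the first two midpoints, not the later crossing


def test_filter_maf_keeps_common_sites_only():
    geno = np.array(
        [[1, 1], [1, 0], [1, 0], [0, 0], [0, 0], [0, 0], [0, 0], [0, 0]], dtype=np.int8
    )
    snp = _matrix(geno)
    kept = filter_maf(snp, 0.25)
    assert kept.n_sites == 1 and kept.site_pos[0] == 0


def test_bootstrap_identical_cells_yields_undefined_ci(caplog):
    geno = np.zeros((10, 6), dtype=np.int8)  # monomorphic everywhere
    snp = _matrix(geno)
    with caplog.at_level("WARNING"):
        b = bootstrap_ld50(snp, n_boot=20, seed=0)
    assert b.ci_low is None and b.sentinel_rate == 1.0


def test_bootstrap_is_seed_deterministic():
    rng = np.random.default_rng(5)
    geno = rng.integers(0, 2, (15, 10)).astype(np.int8)
    snp = _matrix(geno, pos=np.sort(rng.choice(20_000, 10, replace=False)))
    a = bootstrap_ld50(snp, n_boot=30, seed=7)
    b = bootstrap_ld50(snp, n_boot=30, seed=7)
    assert (a.ci_low, a.ci_high, a.sentinel_rate) == (b.ci_low, b.ci_high, b.sentinel_rate)


def test_unlinked_fraction_secondary_statistic():
    # 8 cells; tightly linked close pair, independent far pair
    geno = np.array(
        [
            [0, 0, 0, 0],
            [0, 0, 0, 1],
            [1, 1, 1, 0],
            [1, 1, 1, 1],
            [0, 0, 1, 0],
            [0, 0, 1, 1],
            [1, 1, 0, 0],
            [1, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    snp = _matrix(geno, pos=[0, 20, 5000, 20_000])
    d = unlinked_fraction_distance(snp, min_cells=4)
    assert d == pytest.approx(5000)
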