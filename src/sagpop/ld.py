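"""Linkage-disequilibrium decay: pairwise r^2 between biallelic SNP sites,
distance-binned decay curves, and the distance at which the curve crosses
r^2 = 0.5 (the 50%-unlinked distance, LD50).

Haploid genomes are phased haplotypes, so r^2 comes straight from 2x2
haplotype counts restricted to cells called at both sites:
D = p_AB - p_A p_B, r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .snp import SnpMatrix

logger = logging.getLogger(__name__)

BELOW_MIN = "below_min"
NOT_REACHED = "not_reached"

Ld50Result = Union[float, str]


@dataclass
class LdPair:
    site_i: int
    site_j: int
    distance: int
    n_cells: int
    r2: float


def pair_r2(geno_i: np.ndarray, geno_j: np.ndarray, min_cells: int = 5) -> Optional[LdPair]:
    """r^2 for one site pair from haplotype counts over co-called cells.

    Returns None (excluded) when fewer than min_cells are co-called or
    either site is monomorphic within the co-called subset (undefined
    denominator) -- exclusion is a value, not an error.
    """
    ok = (geno_i >= 0) & (geno_j >= 0)
    n = int(ok.sum())
    if n < min_cells:
        return None
    gi, gj = geno_i[ok], geno_j[ok]
    pa = gi.mean()
    pb = gj.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    pab = (gi * gj).mean()
    d = pab - pa * pb
    r2 = (d * d) / (pa * (1 - pa) * pb * (1 - pb))
    return LdPair(site_i=-1, site_j=-1, distance=-1, n_cells=n, r2=float(r2))


def _all_pairs_r2(snp: SnpMatrix, min_cells: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized r^2 for every valid within-contig site pair.

    Returns (distance, r2, n_cells) arrays over the included pairs.
    """
    G = snp.geno
    called = (G >= 0).astype(np.float64)
    X = np.where(G > 0, 1.0, 0.0) * called  # minor-allele indicator, 0 where missing
    N = called.T @ called  # co-called counts
    NA = X.T @ called  # minor at i among co-called
    NB = called.T @ X
    NAB = X.T @ X
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = NA / N
        pb = NB / N
        pab = NAB / N
        D = pab - pa * pb
        denom = pa * (1 - pa) * pb * (1 - pb)
        r2 = (D * D) / denom
    same_contig = snp.site_contig[:, None] == snp.site_contig[None, :]
    valid = (N >= min_cells) & (denom > 0) & same_contig
    iu = np.triu_indices(snp.n_sites, k=1)
    mask = valid[iu]
    dist = np.abs(snp.site_pos[:, None] - snp.site_pos[None, :])[iu][mask]
    return dist.astype(np.int64), r2[iu][mask], N[iu][mask].astype(np.int64)


@dataclass
class LdCurve:
    """Distance-binned LD decay curve (left-closed, right-open bins)."""

    bin_edges: np.ndarray
    mean_r2: np.ndarray  # nan for empty bins
    pair_count: np.ndarray
    ld50: Optional[Ld50Result] = None
    ld50_upper_bound: Optional[float] = None  # set when ld50 == below_min

    @property
    def midpoints(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "midpoint": self.midpoints,
                "mean_r2": self.mean_r2,
                "pair_count": self.pair_count,
            }
        )


def default_bins(lo: float = 10.0, hi: float = 50_000.0, n: int = 20) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n)


def ld_profile(
    snp: SnpMatrix, bins: Optional[np.ndarray] = None, min_cells: int = 5
) -> LdCurve:
    """Distance-binned mean r^2 over all valid within-contig site pairs."""
    if snp.n_sites < 2:
        raise ValueError("need at least 2 SNP sites for an LD profile")
    bins = default_bins() if bins is None else np.asarray(bins, dtype=float)
    dist, r2, _n = _all_pairs_r2(snp, min_cells)
    if dist.size == 0:
        raise ValueError(
            "no valid site pairs (all excluded by min_cells or monomorphic "
            "subsets); consider loosening filters"
        )
    which = np.digitize(dist, bins) - 1  # bin i: [edge_i, edge_{i+1})
    nb = len(bins) - 1
    inside = (which >= 0) & (which < nb)
    counts = np.bincount(which[inside], minlength=nb)
    sums = np.bincount(which[inside], weights=r2[inside], minlength=nb)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdCurve(bin_edges=bins, mean_r2=means, pair_count=counts)


def filter_maf(snp: SnpMatrix, min_maf: float) -> SnpMatrix:
    """Restrict to intermediate-frequency sites (minor-allele frequency
    relative to the full sample >= min_maf).  Rare variants carry almost
    no linkage information and their r^2 is strongly biased, so LD decay
    is assessed on common variants; the full-sample denominator also
    discards sparsely called sites whose frequency is poorly estimated."""
    if min_maf <= 0:
        return snp
    maf = snp.minor_count / max(snp.n_cells, 1)
    idx = np.flatnonzero(maf >= min_maf)
    return SnpMatrix(
        reference_id=snp.reference_id,
        cells=list(snp.cells),
        contig_names=list(snp.contig_names),
        site_contig=snp.site_contig[idx],
        site_pos=snp.site_pos[idx],
        major=snp.major[idx],
        minor=snp.minor[idx],
        minor_count=snp.minor_count[idx],
        called_count=snp.called_count[idx],
        geno=snp.geno[:, idx],
    )


def ld50(curve: LdCurve, threshold: float = 0.5, min_pairs_per_bin: int = 10) -> Ld50Result:
    """Distance where the binned curve first crosses below the threshold.

    Interpolates linearly in log10 distance between the geometric bin
    midpoints flanking the first >=threshold -> <threshold transition.
    Bins with fewer than min_pairs_per_bin pairs are too noisy to anchor
    a crossing and are treated as empty.  Returns the sentinel below_min
    when the first usable bin is already below threshold, and not_reached
    when the curve never drops below it.
    """
    mids = curve.midpoints
    ok = curve.pair_count >= max(1, min_pairs_per_bin)
    if not ok.any():
        raise ValueError("all LD bins are empty (or below the pair-count floor)")
    m = mids[ok]
    r = curve.mean_r2[ok]
    if r[0] < threshold:
        curve.ld50_upper_bound = float(m[0])
        curve.ld50 = BELOW_MIN
        return BELOW_MIN
    for i in range(len(r) - 1):
        if r[i] >= threshold and r[i + 1] < threshold:
            lx0, lx1 = math.log10(m[i]), math.log10(m[i + 1])
            frac = (r[i] - threshold) / (r[i] - r[i + 1])
            val = 10 ** (lx0 + (lx1 - lx0) * frac)
            curve.ld50 = float(val)
            return float(val)
    curve.ld50 = NOT_REACHED
    return NOT_REACHED


def unlinked_fraction_distance(
    snp: SnpMatrix, threshold: float = 0.5, min_cells: int = 5
) -> Ld50Result:
    """Secondary statistic: smallest distance d such that among pairs at
    distance <= d, the fraction with r^2 < threshold exceeds 0.5."""
    dist, r2, _n = _all_pairs_r2(snp, min_cells)
    if dist.size == 0:
        raise ValueError("no valid site pairs")
    order = np.argsort(dist, kind="stable")
    low = (r2[order] < threshold).cumsum()
    frac = low / np.arange(1, dist.size + 1)
    hit = np.flatnonzero(frac > 0.5)
    if hit.size == 0:
        return NOT_REACHED
    return float(dist[order][hit[0]])


def ld50_ordering_value(result: Ld50Result, curve: Optional[LdCurve] = None) -> float:
    """Map LD50 results onto a totally ordered scale for comparisons:
    numeric values as-is, below_min -> its upper bound (or 0), not_reached
    -> +inf."""
    if result == NOT_REACHED:
        return math.inf
    if result == BELOW_MIN:
        if curve is not None and curve.ld50_upper_bound is not None:
            return curve.ld50_upper_bound
        return 0.0
    return float(result)


@dataclass
class BootstrapLd50:
    point: Ld50Result
    ci_low: Optional[float]
    ci_high: Optional[float]
    sentinel_rate: float
    n_boot: int


def bootstrap_ld50(
    snp: SnpMatrix,
    n_boot: int = 200,
    seed: int = 0,
    bins: Optional[np.ndarray] = None,
    min_cells: int = 5,
    threshold: float = 0.5,
    min_pairs_per_bin: int = 10,
) -> BootstrapLd50:
    """Percentile bootstrap over cells for the LD50 statistic.

    Cells are resampled with replacement; replicates whose LD50 is a
    sentinel (or that admit no valid pairs) count toward sentinel_rate.
    The CI is undefined (None bounds, with a warning) when more than half
    of the replicates are sentinels.
    """
    if snp.n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    try:
        curve = ld_profile(snp, bins=bins, min_cells=min_cells)
        point = ld50(curve, threshold, min_pairs_per_bin)
    except ValueError:
        point = BELOW_MIN
    vals = []
    n_sentinel = 0
    for _ in range(n_boot):
        idx = rng.integers(0, snp.n_cells, snp.n_cells)
        boot = SnpMatrix(
            reference_id=snp.reference_id,
            cells=[f"b{i}" for i in range(snp.n_cells)],
            contig_names=snp.contig_names,
            site_contig=snp.site_contig,
            site_pos=snp.site_pos,
            major=snp.major,
            minor=snp.minor,
            minor_count=snp.minor_count,
            called_count=snp.called_count,
            geno=snp.geno[idx],
        )
        try:
            c = ld_profile(boot, bins=bins, min_cells=min_cells)
            v = ld50(c, threshold, min_pairs_per_bin)
        except ValueError:
            n_sentinel += 1
            continue
        if isinstance(v, str):
            n_sentinel += 1
        else:
            vals.append(v)
    rate = n_sentinel / n_boot
    if rate > 0.5 or not vals:
        logger.warning(
            "bootstrap LD50 CI undefined: %.0f%% of replicates were sentinels",
            100 * rate,
        )
        return BootstrapLd50(point, None, None, rate, n_boot)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return BootstrapLd50(point, float(lo), float(hi), rate, n_boot)
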