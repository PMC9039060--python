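"""Population structure within a species group: pairwise SNP distances,
neighbor-joining trees, a silhouette-selected hierarchical clustering used
as the sub-population labeller, and the PERMANOVA concordance test between
distances and cluster labels.

PERMANOVA uses the Anderson pseudo-F on squared distances:
SS_total = (1/n) sum_{i<j} d_ij^2,
SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2,
F = ((SS_total - SS_within)/(k-1)) / (SS_within/(n-k)),
with a permutation p-value (b+1)/(m+1), switching to exhaustive
enumeration over all distinct label assignments when there are at most
10,000 of them.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode
from sklearn.metrics import silhouette_score

from .snp import SnpMatrix

logger = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    n_shared: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.d, columns=self.ids)
        df.insert(0, "id", self.ids)
        return df


def snp_distance(snp: SnpMatrix, min_shared: int = 20) -> DistanceMatrix:
    """Normalized SNP distance: mismatches / co-called sites per pair.

    Pairs sharing fewer than min_shared co-called sites are undefined and
    raise, listing the offending pairs (drop cells and retry).
    """
    if snp.n_cells < 3:
        raise ValueError("need at least 3 cells")
    G = snp.geno
    called = (G >= 0).astype(np.float64)
    X = np.where(G > 0, 1.0, 0.0) * called
    shared = called @ called.T
    # mismatches = minor-vs-major in either direction among co-called sites
    agree11 = X @ X.T
    minor_i = X @ called.T
    mismatch = (minor_i - agree11) + (minor_i.T - agree11)
    bad = []
    n = snp.n_cells
    for i in range(n):
        for j in range(i + 1, n):
            if shared[i, j] < min_shared:
                bad.append((snp.cells[i], snp.cells[j], int(shared[i, j])))
    if bad:
        listing = "; ".join(f"{a}-{b} ({s} shared)" for a, b, s in bad[:20])
        raise ValueError(
            f"{len(bad)} cell pair(s) share fewer than {min_shared} called "
            f"SNP sites: {listing}"
        )
    with np.errstate(invalid="ignore"):
        d = mismatch / shared
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # numeric symmetry
    return DistanceMatrix(ids=list(snp.cells), d=d, n_shared=shared.astype(np.int64))


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The Q-criterion minimum is chosen; ties go to the lowest (i, j) index
    pair in the current node ordering.  Negative branch lengths are
    clamped to zero with the deficit moved to the sibling branch.
    """
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 leaves")
    D = dm.d.copy()
    nodes = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i,j) among ties
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ai, aj = min((int(a), int(b)) for a, b in ties if a < b)
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        lj = max(lj, 0.0)
        parent = TreeNode()
        ni, nj_ = nodes[i], nodes[j]
        ni.length = float(li)
        nj_.length = float(lj)
        parent.extend([ni, nj_])
        # distances from the new node
        newrow = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, newrow])
        D = np.hstack([D, np.append(newrow, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [D.shape[0] - 1]
    i, j = active
    root = TreeNode()
    length = max(float(D[i, j]), 0.0)
    a, b = nodes[i], nodes[j]
    if b.children and not a.children:
        a, b = b, a
    a.length = 0.0
    b.length = length
    root.extend([a, b])
    return root


def cophenetic_distance(tree: TreeNode, ids: list[str]) -> DistanceMatrix:
    """Patristic (sum-of-branch-length) distances between tips."""
    skdm = tree.tip_tip_distances(endpoints=list(ids))
    order = [list(skdm.ids).index(i) for i in ids]
    d = skdm.data[np.ix_(order, order)]
    return DistanceMatrix(ids=list(ids), d=d)


# ---------------------------------------------------------------------------
# Clustering stand-in for the Bayesian population-structure labeller


def cluster_cells(dm: DistanceMatrix, k_max: int = 10) -> np.ndarray:
    """Average-linkage hierarchical clustering; k chosen to maximize the
    mean silhouette over k in [2, k_max].  Returns integer labels
    (0-based).  When all distances are (near) equal there is no structure
    to find: k=1 with a warning."""
    n = len(dm.ids)
    if n < 4:
        raise ValueError("need at least 4 cells to cluster")
    off = squareform(dm.d, checks=False)
    if np.allclose(off, off[0]):
        logger.warning("all pairwise distances equal; returning a single cluster")
        return np.zeros(n, dtype=int)
    Z = linkage(off, method="average")
    best_k, best_s, best_labels = 1, -np.inf, np.zeros(n, dtype=int)
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(dm.d, labels, metric="precomputed")
        if s > best_s + 1e-12:
            best_k, best_s, best_labels = k, s, labels - 1
    if best_k == 1:
        logger.warning("no k in [2, k_max] produced a valid clustering")
    return np.asarray(best_labels, dtype=int)


# ---------------------------------------------------------------------------
# PERMANOVA


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = d2.shape[0]
    k = len(groups)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))


def _pseudo_f_batch(d2: np.ndarray, label_matrix: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """F for a batch of label vectors (B x n integer matrix)."""
    n = d2.shape[0]
    k = sizes.size
    ss_total = d2.sum() / (2 * n)
    B = label_matrix.shape[0]
    ss_within = np.zeros(B)
    for gi in range(k):
        H = (label_matrix == gi).astype(np.float64)  # (B, n)
        ss_within += np.einsum("bi,ij,bj->b", H, d2, H) / (2 * sizes[gi])
    return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))


def n_distinct_assignments(sizes: np.ndarray) -> int:
    total = math.factorial(int(sizes.sum()))
    for s in sizes:
        total //= math.factorial(int(s))
    return total


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Anderson pseudo-F and permutation p-value for group labels.

    p = (1 + #{permuted F >= observed}) / (1 + n_perm) under random label
    permutation; when the number of distinct assignments is at most
    10,000 the permutation distribution is enumerated exhaustively and
    p is the exact tail fraction.
    """
    labels = np.asarray(labels)
    ids, inv = np.unique(labels, return_inverse=True)
    sizes = np.bincount(inv)
    if len(ids) < 2:
        raise ValueError("need at least 2 groups")
    if sizes.min() < 2:
        raise ValueError("every group needs at least 2 members (F undefined)")
    d2 = dm.d**2
    groups = np.arange(len(ids))
    f_obs = _pseudo_f(d2, inv, groups)
    n = len(inv)
    if n_distinct_assignments(sizes) <= EXHAUSTIVE_LIMIT:
        perms = np.array(list(_multiset_permutations(inv)), dtype=int)
        f_all = _pseudo_f_batch(d2, perms, sizes)
        p = float(np.mean(f_all >= f_obs - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        perms = inv[perm_idx]
        f_perm = _pseudo_f_batch(d2, perms, sizes)
        b = int(np.sum(f_perm >= f_obs - 1e-12))
        p = (b + 1) / (n_perm + 1)
    return float(f_obs), p


def _multiset_permutations(labels: np.ndarray):
    """All distinct arrangements of a label multiset (lexicographic)."""
    n = len(labels)
    counts = np.bincount(labels)

    def rec(prefix, counts):
        if len(prefix) == n:
            yield list(prefix)
            return
        for v in range(len(counts)):
            if counts[v] > 0:
                counts[v] -= 1
                prefix.append(v)
                yield from rec(prefix, counts)
                prefix.pop()
                counts[v] += 1

    yield from rec([], list(counts))


def concordance_test(
    dm: DistanceMatrix,
    tree: TreeNode,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    distance: str = "cophenetic",
) -> dict:
    """Tree-vs-clustering concordance: PERMANOVA of tree (cophenetic) or
    SNP distances against cluster labels.  Returns a dict with F, p and
    whether the test was applicable (needs >=2 groups of >=2)."""
    labels = np.asarray(labels)
    if distance == "cophenetic":
        test_dm = cophenetic_distance(tree, dm.ids)
    elif distance == "snp":
        test_dm = dm
    else:
        raise ValueError(f"unknown distance {distance!r}")
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2 or counts.min() < 2:
        return {"applicable": False, "F": None, "p": None, "k": int(len(counts))}
    f, p = permanova(test_dm, labels, n_perm=n_perm, seed=seed)
    return {"applicable": True, "F": f, "p": p, "k": int(len(counts))}
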