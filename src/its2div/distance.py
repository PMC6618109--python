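"""Between-sample and between-profile distances and ordination.

Distances are computed per clade, because ITS2 sequences from different
Symbiodiniaceae genera are effectively unalignable.  Two metrics are
offered: Bray-Curtis on sequence abundances, and weighted (normalized)
UniFrac evaluated on a bootstrapped neighbour-joining tree summarised as a
50% majority-rule consensus.  Classical principal coordinate analysis
turns either distance matrix into ordination coordinates.

The multiple aligner, neighbour joining, UniFrac, Bray-Curtis and PCoA are
implemented here; :class:`skbio.DistanceMatrix` and
:class:`skbio.TreeNode` serve as the matrix and tree containers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import majority_rule

__all__ = [
    "align_sequences",
    "pairwise_distances",
    "nj_tree",
    "consensus_tree",
    "bootstrap_consensus_tree",
    "weighted_unifrac",
    "bray_curtis",
    "pcoa",
    "PCoAResult",
]


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

_ALPHA = "ACGT-"
# Column scoring for profile-profile alignment: match +1, mismatch -1,
# base/gap -2, gap/gap 0.
_SCORE = np.array([
    [1, -1, -1, -1, -2],
    [-1, 1, -1, -1, -2],
    [-1, -1, 1, -1, -2],
    [-1, -1, -1, 1, -2],
    [-2, -2, -2, -2, 0],
], dtype=float)
_GAP = -2.0


def _profile(rows: list[str]) -> np.ndarray:
    """Per-column character frequencies over the ACGT- alphabet."""
    idx = {c: i for i, c in enumerate(_ALPHA)}
    arr = np.zeros((len(rows[0]), 5))
    for row in rows:
        for j, c in enumerate(row):
            arr[j, idx.get(c, 4)] += 1
    return arr / len(rows)


def _nw_profiles(rows_a: list[str], rows_b: list[str]
                 ) -> tuple[list[str], list[str]]:
    """Global alignment of two alignment blocks; returns gapped blocks."""
    fa, fb = _profile(rows_a), _profile(rows_b)
    la, lb = fa.shape[0], fb.shape[0]
    S = fa @ _SCORE @ fb.T
    H = np.zeros((la + 1, lb + 1))
    P = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    H[:, 0] = np.arange(la + 1) * _GAP
    H[0, :] = np.arange(lb + 1) * _GAP
    P[1:, 0] = 1
    P[0, 1:] = 2
    for i in range(1, la + 1):
        Hi, Hp = H[i], H[i - 1]
        Si = S[i - 1]
        for j in range(1, lb + 1):
            diag = Hp[j - 1] + Si[j - 1]
            up = Hp[j] + _GAP
            left = Hi[j - 1] + _GAP
            best = diag
            ptr = 0
            if up > best:
                best, ptr = up, 1
            if left > best:
                best, ptr = left, 2
            Hi[j] = best
            P[i, j] = ptr
    # traceback
    ops = []
    i, j = la, lb
    while i > 0 or j > 0:
        p = P[i, j]
        ops.append(p)
        if p == 0:
            i, j = i - 1, j - 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for p in ops:
        if p in (0, 1):
            for k, row in enumerate(rows_a):
                out_a[k].append(row[i])
            i += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
        if p in (0, 2):
            for k, row in enumerate(rows_b):
                out_b[k].append(row[j])
            j += 1
        else:
            for k in range(len(rows_b)):
                out_b[k].append("-")
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _kmer_distance(a: str, b: str, k: int = 4) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / len(ka | kb)


def align_sequences(sequences: Sequence[str]) -> list[str]:
    """Progressive multiple alignment of same-clade sequences.

    Guide order comes from average-linkage clustering of pairwise k-mer
    (Jaccard) distances; blocks are merged by global profile alignment
    (match +1, mismatch -1, gap -2).  Ungapping any output row recovers
    the corresponding input exactly.
    """
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences to align")
    if len({len(s) for s in seqs}) == 1 and len(set(seqs)) >= 1:
        # equal-length inputs: positional columns are already consistent
        return seqs
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(seqs[i], seqs[j])
    blocks: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)}
    if n == 2:
        merges = [(0, 1)]
    else:
        Z = linkage(squareform(dm, checks=False), method="average")
        merges = [(int(a), int(b)) for a, b, _, _ in Z]
    next_id = n
    for a, b in merges:
        ia, ra = blocks.pop(a)
        ib, rb = blocks.pop(b)
        ga, gb = _nw_profiles(ra, rb)
        blocks[next_id] = (ia + ib, ga + gb)
        next_id += 1
    indices, rows = blocks.popitem()[1]
    ordered = [None] * n
    for idx, row in zip(indices, rows):
        ordered[idx] = row
    return ordered


# ---------------------------------------------------------------------------
# Pairwise distances from an alignment
# ---------------------------------------------------------------------------

def pairwise_distances(alignment: Sequence[str],
                       labels: Sequence[str] | None = None,
                       ignore_terminal_gaps: bool = True) -> DistanceMatrix:
    """Uncorrected p-distances between aligned rows.

    Columns where both rows hold a gap are never compared; with
    ``ignore_terminal_gaps`` (mothur's ``countends=F``), columns falling in
    either row's leading or trailing gap run are excluded from both the
    numerator and the denominator.
    """
    rows = list(alignment)
    n = len(rows)
    if labels is None:
        labels = [str(i) for i in range(n)]
    arr = np.array([list(r) for r in rows])
    gaps = arr == "-"
    starts = np.zeros(n, dtype=int)
    ends = np.full(n, arr.shape[1], dtype=int)
    for i in range(n):
        nz = np.flatnonzero(~gaps[i])
        if nz.size == 0:
            raise ValueError(f"row {labels[i]} is all gaps")
        starts[i], ends[i] = nz[0], nz[-1] + 1
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if ignore_terminal_gaps:
                lo, hi = max(starts[i], starts[j]), min(ends[i], ends[j])
            else:
                lo, hi = 0, arr.shape[1]
            if hi <= lo:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}")
            a, b = arr[i, lo:hi], arr[j, lo:hi]
            comparable = ~((a == "-") & (b == "-"))
            ncomp = int(comparable.sum())
            if ncomp == 0:
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}")
            diffs = int(((a != b) & comparable).sum())
            out[i, j] = out[j, i] = diffs / ncomp
    return DistanceMatrix(out, ids=list(labels))


# ---------------------------------------------------------------------------
# Neighbour joining and consensus
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree with negative branch estimates clamped.

    Standard agglomeration on the Q criterion; when a branch-length
    estimate is negative it is set to zero and the deficit moved to the
    sibling branch so the path length between the joined nodes is kept.
    Two-leaf input yields the single edge split evenly across the root.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two leaves")
    nodes = {i: TreeNode(name=ids[i]) for i in range(n)}
    d = {(i, j): dm[ids[i], ids[j]] for i in range(n) for j in range(n)}
    active = list(range(n))
    next_id = n

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        u = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        u.extend([nodes[i], nodes[j]])
        nodes[next_id] = u
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[next_id, k] = d[k, next_id] = max(duk, 0.0)
        d[next_id, next_id] = 0.0
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    root = TreeNode()
    if len(active) == 2:
        i, j = active
        half = d[i, j] / 2
        nodes[i].length = nodes[j].length = half
        root.extend([nodes[i], nodes[j]])
    else:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
            node.length = max(ln, 0.0)
            root.append(node)
    return root


def consensus_tree(trees: Sequence[TreeNode],
                   threshold: float = 0.5) -> TreeNode:
    """Majority-rule consensus (bipartitions in > ``threshold`` of trees).

    Branch lengths are averaged over the trees containing each
    bipartition; node ``support`` holds the number of supporting trees.
    """
    if not trees:
        raise ValueError("no trees given")
    forest = majority_rule(list(trees), cutoff=threshold)
    tree = max(forest, key=lambda t: t.count(tips=True))
    for node in tree.traverse():
        if node.length is None and not node.is_root():
            node.length = 0.0
    return tree


def bootstrap_consensus_tree(alignment: Sequence[str],
                             labels: Sequence[str],
                             n_replicates: int = 100,
                             seed: int = 0,
                             ignore_terminal_gaps: bool = True) -> TreeNode:
    """Consensus of NJ trees built from column-resampled alignments.

    Column resampling with a seeded generator makes the whole procedure
    reproducible: the same seed yields the identical consensus tree.
    """
    rng = np.random.default_rng(seed)
    ncol = len(alignment[0])
    trees = []
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = ["".join(row[c] for c in cols) for row in alignment]
        try:
            dm = pairwise_distances(rows, labels=labels,
                                    ignore_terminal_gaps=ignore_terminal_gaps)
        except ValueError:
            continue  # a replicate may lose all comparable columns
        trees.append(nj_tree(dm))
    return consensus_tree(trees, threshold=0.5)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def weighted_unifrac(tree: TreeNode, a: Mapping[str, float],
                     b: Mapping[str, float]) -> float:
    """Normalized weighted UniFrac distance between two abundance maps.

    Each map assigns abundance to tree leaf names; maps are normalized to
    sum to 1.  The distance is sum(l * |pA - pB|) / sum(l * (pA + pB))
    over branches, where p is the fraction of a community's abundance
    descending through the branch.  Symmetric, zero iff the normalized
    vectors coincide, and at most 1.
    """
    if not a or not b:
        raise ValueError("empty abundance map")
    ta, tb = sum(a.values()), sum(b.values())
    if ta <= 0 or tb <= 0:
        raise ValueError("abundance maps must have positive totals")
    leaves = {leaf.name for leaf in tree.tips()}
    for m in (a, b):
        missing = set(m) - leaves
        if missing:
            raise ValueError(f"abundances for unknown leaves: {sorted(missing)}")
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._wu = (a.get(node.name, 0.0) / ta, b.get(node.name, 0.0) / tb)
        else:
            pa = sum(c._wu[0] for c in node.children)
            pb = sum(c._wu[1] for c in node.children)
            node._wu = (pa, pb)
        length = node.length or 0.0
        pa, pb = node._wu
        num += length * abs(pa - pb)
        den += length * (pa + pb)
    for node in tree.postorder(include_self=False):
        del node._wu
    return num / den if den > 0 else 0.0


def bray_curtis(a: Mapping[object, float], b: Mapping[object, float]) -> float:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min)/(sum(a)+sum(b)); in [0,1]."""
    ta, tb = sum(a.values()), sum(b.values())
    if ta <= 0 and tb <= 0:
        raise ValueError("both abundance maps are empty")
    shared = sum(min(a[k], b[k]) for k in a.keys() & b.keys())
    return 1.0 - 2.0 * shared / (ta + tb)


# ---------------------------------------------------------------------------
# Principal coordinate analysis
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    """Classical-scaling ordination of a distance matrix."""

    labels: list[str]
    coordinates: np.ndarray        # shape (n, k), axes with positive eigenvalues
    eigenvalues: np.ndarray        # all eigenvalues, decreasing
    proportion_explained: np.ndarray  # per retained axis


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Classical (Torgerson) scaling of a distance matrix.

    The doubly centred matrix -D^2/2 is eigendecomposed; coordinates are
    eigenvectors scaled by the square roots of their (positive)
    eigenvalues.  Negative eigenvalues - possible for non-Euclidean
    distances such as Bray-Curtis - are reported but their axes dropped.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total_pos = evals[pos].sum()
    prop = evals[pos] / total_pos if total_pos > 0 else evals[pos]
    return PCoAResult(labels=list(dm.ids), coordinates=coords,
                      eigenvalues=evals, proportion_explained=prop)


# ---------------------------------------------------------------------------
# Collection- and profile-level matrices
# ---------------------------------------------------------------------------

def sample_distance_matrix(collections, registry, metric: str = "braycurtis",
                           n_bootstrap: int = 100, seed: int = 0
                           ) -> DistanceMatrix:
    """Distance matrix between same-clade collections of different samples.

    Abundance vectors are each collection's post-QC sequence relative
    abundances.  For ``metric="unifrac"`` all sequences of the clade are
    aligned, a bootstrapped NJ consensus tree is built, and weighted
    UniFrac evaluated on it; ``"braycurtis"`` works directly on the
    vectors.
    """
    clades = {c.clade for c in collections}
    if len(clades) != 1:
        raise ValueError("collections must be of a single clade")
    ids = [c.sample_id for c in collections]
    vecs = [c.relative_abundances() for c in collections]
    n = len(collections)
    if metric == "braycurtis":
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = bray_curtis(vecs[i], vecs[j])
        return DistanceMatrix(out, ids=ids)
    if metric != "unifrac":
        raise ValueError(f"unknown metric {metric!r}")
    uids = sorted({u for v in vecs for u in v})
    if len(uids) < 2:
        raise ValueError("need at least two distinct sequences for UniFrac")
    seqs = [registry.get(u).sequence for u in uids]
    labels = [str(u) for u in uids]
    aln = align_sequences(seqs)
    tree = bootstrap_consensus_tree(aln, labels, n_replicates=n_bootstrap,
                                    seed=seed)
    out = np.zeros((n, n))
    str_vecs = [{str(u): x for u, x in v.items()} for v in vecs]
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = weighted_unifrac(tree, str_vecs[i],
                                                     str_vecs[j])
    return DistanceMatrix(out, ids=ids)


def profile_distance_matrix(profiles, registry, metric: str = "braycurtis",
                            n_bootstrap: int = 100, seed: int = 0
                            ) -> DistanceMatrix:
    """Distance matrix between same-clade type profiles.

    Each profile is represented by the midpoints of its DIV abundance
    ranges, renormalized to sum to one.
    """
    clades = {p.clade for p in profiles}
    if len(clades) != 1:
        raise ValueError("profiles must be of a single clade")
    ids = [p.name or str(p.uid) for p in profiles]
    vecs = []
    for p in profiles:
        mid = {u: (lo + hi) / 2 for u, (lo, hi) in p.ranges.items()}
        tot = sum(mid.values())
        vecs.append({u: x / tot for u, x in mid.items()} if tot else mid)
    n = len(profiles)
    out = np.zeros((n, n))
    if metric == "braycurtis":
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = bray_curtis(vecs[i], vecs[j])
        return DistanceMatrix(out, ids=ids)
    if metric != "unifrac":
        raise ValueError(f"unknown metric {metric!r}")
    uids = sorted({u for v in vecs for u in v})
    if len(uids) < 2:
        raise ValueError("need at least two distinct DIVs for UniFrac")
    aln = align_sequences([registry.get(u).sequence for u in uids])
    tree = bootstrap_consensus_tree(aln, [str(u) for u in uids],
                                    n_replicates=n_bootstrap, seed=seed)
    str_vecs = [{str(u): x for u, x in v.items()} for v in vecs]
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = weighted_unifrac(tree, str_vecs[i],
                                                     str_vecs[j])
    return DistanceMatrix(out, ids=ids)
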