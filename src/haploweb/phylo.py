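"""Haplotype trees: K2P distances, neighbor-joining, bootstrap, rooting.

The tree machinery here is deliberately plain: identical-sequence
collapsing, Kimura two-parameter distances with pairwise or complete
deletion of gapped/missing sites, Saitou-Nei neighbor-joining with
deterministic lexicographic tie-breaking, nonparametric bootstrap
support on internal bipartitions, outgroup rooting, and single-linkage
distance-threshold clustering (a barcode-gap surrogate for delimiting
strongly divergent clades on the clonal marker).

Trees are :class:`dendropy.Tree` objects throughout and serialise to
newick; bootstrap supports are stored as internal node labels (integer
percentages).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

GAPLIKE = {"-", "N"}
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

#: distances beyond saturation of the K2P log terms are capped here
SATURATION_CAP = 5.0


class PhyloError(ValueError):
    pass


@dataclass(frozen=True)
class Alignment:
    """Ordered aligned sequences over {A, C, G, T, -, N}."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise PhyloError("empty alignment")
        if len(self.ids) != len(self.seqs):
            raise PhyloError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise PhyloError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise PhyloError(f"rows differ in length: {sorted(lengths)}")
        alphabet = set("ACGT-N")
        for sid, s in zip(self.ids, self.seqs):
            bad = set(s) - alphabet
            if bad:
                raise PhyloError(f"{sid}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def get(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    def to_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.seqs], dtype="<U1")

    @classmethod
    def from_pairs(cls, pairs) -> "Alignment":
        ids, seqs = zip(*pairs)
        return cls(tuple(ids), tuple(seqs))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a deletion-mode tag."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    mode: str = "pairwise"

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.ids)
        if m.shape != (n, n):
            raise PhyloError("matrix shape does not match id count")
        if not np.allclose(np.diag(m), 0):
            raise PhyloError("diagonal must be zero")
        if not np.allclose(m, m.T):
            raise PhyloError("matrix must be symmetric")
        if (m < 0).any():
            raise PhyloError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))


# ---------------------------------------------------------------------------
# collapsing and distances


def collapse_haplotypes(aln: Alignment) -> tuple[Alignment, dict[str, list[str]]]:
    """One representative per identical aligned string.

    Returns the collapsed alignment and a map representative id ->
    sorted list of member ids; the representative is the
    lexicographically smallest member.
    """
    groups: dict[str, list[str]] = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        groups.setdefault(seq, []).append(sid)
    reps = []
    membership: dict[str, list[str]] = {}
    for seq, members in groups.items():
        rep = min(members)
        reps.append((rep, seq))
        membership[rep] = sorted(members)
    reps.sort()
    return Alignment.from_pairs(reps), membership


def _k2p_pair(x: np.ndarray, y: np.ndarray) -> float:
    valid = ~(np.isin(x, list(GAPLIKE)) | np.isin(y, list(GAPLIKE)))
    n = int(valid.sum())
    if n == 0:
        raise PhyloError("zero comparable sites for a sequence pair")
    xv, yv = x[valid], y[valid]
    diff = xv != yv
    x_pur = np.isin(xv, list(PURINES))
    y_pur = np.isin(yv, list(PURINES))
    transitions = int((diff & (x_pur == y_pur)).sum())
    transversions = int((diff & (x_pur != y_pur)).sum())
    P, Q = transitions / n, transversions / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        logger.warning("K2P saturation (P=%.3f, Q=%.3f); capping at %.1f", P, Q, SATURATION_CAP)
        return SATURATION_CAP
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(aln: Alignment, mode: str = "pairwise") -> DistanceMatrix:
    """Kimura two-parameter distances, d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

    ``mode="pairwise"`` drops gap/N sites per pair; ``mode="complete"``
    drops any column with a gap/N in *any* sequence before comparing.
    """
    if mode not in ("pairwise", "complete"):
        raise PhyloError(f"unknown deletion mode {mode!r}")
    if len(aln) < 2:
        raise PhyloError("need at least two sequences")
    arr = aln.to_array()
    if mode == "complete":
        keep = ~np.isin(arr, list(GAPLIKE)).any(axis=0)
        if not keep.any():
            raise PhyloError("complete deletion removed every column")
        arr = arr[:, keep]
    n = len(aln)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _k2p_pair(arr[i], arr[j])
    return DistanceMatrix(aln.ids, m, mode)


# ---------------------------------------------------------------------------
# neighbor-joining


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    # negative branch clamped to zero, deficit moved to the sister branch
    if la < 0:
        lb, la = lb + la, 0.0
    if lb < 0:
        la, lb = la + lb, 0.0
    return max(la, 0.0), max(lb, 0.0)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining, deterministic under ties.

    Pair choice minimises the Q criterion with ties broken on the
    lexicographically smallest (cluster label, cluster label) pair;
    cluster labels are the smallest leaf id they contain.  Negative
    branch lengths are clamped to zero with the deficit moved to the
    adjacent branch.  The result is unrooted (trifurcating seed node).
    """
    if len(dm) < 3:
        raise PhyloError("neighbor-joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    for sid in dm.ids:
        taxon = tns.new_taxon(sid)
        nodes[sid] = dendropy.Node(taxon=taxon)
    D: dict[tuple[str, str], float] = {}

    def key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    for i, a in enumerate(dm.ids):
        for j in range(i + 1, len(dm.ids)):
            b = dm.ids[j]
            D[key(a, b)] = float(dm.matrix[i, j])

    active = sorted(dm.ids)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[key(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            q = (n - 2) * D[key(a, b)] - r[a] - r[b]
            cand = (q, a, b)
            if best is None or cand < best:
                best = cand
        _, a, b = best
        d_ab = D[key(a, b)]
        la = d_ab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = d_ab - la
        la, lb = _clamp_pair(la, lb)
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = la
        parent.add_child(nodes[b])
        nodes[b].edge.length = lb
        label = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            D[key(label, c) if label != a else key(a, c)] = max(
                (D[key(a, c)] + D[key(b, c)] - d_ab) / 2, 0.0
            )
        active = sorted(set(active) - {a, b} | {label})
        nodes[label] = parent

    x, y, z = active
    dxy, dxz, dyz = D[key(x, y)], D[key(x, z)], D[key(y, z)]
    lx = max((dxy + dxz - dyz) / 2, 0.0)
    ly = max((dxy + dyz - dxz) / 2, 0.0)
    lz = max((dxz + dyz - dxy) / 2, 0.0)
    root = dendropy.Node()
    for lbl, ln in ((x, lx), (y, ly), (z, lz)):
        root.add_child(nodes[lbl])
        nodes[lbl].edge.length = ln
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, rooting


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def edge_bipartitions(
    tree: dendropy.Tree, include_trivial: bool = False, skip_zero_length: bool = False
) -> dict[frozenset[str], dendropy.Edge]:
    """Map canonical bipartition -> edge, for an unrooted view of the tree.

    A bipartition is canonicalised as the side *not* containing the
    lexicographically smallest taxon.  Trivial bipartitions (single
    leaf) are skipped unless requested; edges of length 0 can be skipped
    to treat collapsed polytomies as unresolved.
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = labels[0]
    total = set(labels)
    out: dict[frozenset[str], dendropy.Edge] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if skip_zero_length and not node.is_leaf() and not (node.edge.length or 0) > 0:
            continue
        side = _leafset(node)
        if ref in side:
            side = frozenset(total - side)
        if not side or len(side) == len(total):
            continue
        if not include_trivial and (len(side) < 2 or len(side) > len(total) - 2):
            continue
        out[side] = node.edge
    return out


def bootstrap_nj(
    aln: Alignment,
    n_replicates: int = 1000,
    seed: int = 0,
    mode: str = "pairwise",
) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap supports.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal bipartition of the original tree is the
    percentage of replicate trees containing it (zero-length replicate
    edges count as unresolved).  Supports are attached as internal node
    labels.  With fewer than 4 taxa there is no internal bipartition and
    the plain tree is returned.
    """
    if n_replicates < 1:
        raise PhyloError("need at least one bootstrap replicate")
    tree = nj_tree(k2p_distance(aln, mode))
    if len(aln) < 4:
        return tree
    orig = edge_bipartitions(tree)
    counts = {bp: 0 for bp in orig}
    rng = np.random.default_rng(seed)
    arr = aln.to_array()
    L = arr.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_aln = Alignment(
            aln.ids, tuple("".join(row) for row in arr[:, cols])
        )
        try:
            rep_tree = nj_tree(k2p_distance(rep_aln, mode))
        except PhyloError:
            continue  # e.g. zero comparable sites after resampling
        rep_bps = edge_bipartitions(rep_tree, skip_zero_length=True)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for bp, edge in orig.items():
        pct = 100.0 * counts[bp] / n_replicates
        edge.head_node.label = str(int(round(pct)))
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup_ids) -> dendropy.Tree:
    """Root the tree on the edge separating a monophyletic outgroup."""
    outgroup = frozenset(outgroup_ids)
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = outgroup - labels
    if missing:
        raise PhyloError(f"outgroup taxa absent from tree: {sorted(missing)}")
    if outgroup == labels:
        raise PhyloError("outgroup cannot contain every taxon")
    bps = edge_bipartitions(tree, include_trivial=True)
    target = None
    for side, edge in bps.items():
        if side == outgroup or side == frozenset(labels - outgroup):
            target = edge
            break
    if target is None:
        # name the smallest bipartition side containing the outgroup
        conflict = min(
            (s for s in bps if outgroup < s), key=len, default=frozenset(labels)
        )
        raise PhyloError(
            f"outgroup {sorted(outgroup)} is not monophyletic; smallest "
            f"containing bipartition is {sorted(conflict)}"
        )
    tree = tree.clone(depth=1)
    # re-find the matching edge in the clone
    bps = edge_bipartitions(tree, include_trivial=True)
    for side, edge in bps.items():
        if side == outgroup or side == frozenset(labels - outgroup):
            target = edge
            break
    length = target.length or 0.0
    tree.reroot_at_edge(target, length1=length / 2, length2=length / 2)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# distance-threshold clade partitioning


def cluster_by_distance(dm: DistanceMatrix, threshold="auto") -> list[set[str]]:
    """Single-linkage components of pairs closer than the threshold.

    With ``threshold="auto"`` the cut is placed at the midpoint of the
    largest gap in the sorted pairwise distances (barcode-gap
    heuristic); all-identical distances make the heuristic meaningless
    and raise an error demanding an explicit threshold.

    Returns clusters as sets of ids, sorted by (descending size,
    smallest member id).
    """
    import networkx as nx

    n = len(dm)
    values = sorted(dm.matrix[np.triu_indices(n, k=1)])
    if threshold == "auto":
        distinct = sorted(set(values))
        if len(distinct) < 2:
            raise PhyloError(
                "all pairwise distances identical; supply an explicit threshold"
            )
        gaps = [(b - a, a, b) for a, b in zip(distinct, distinct[1:])]
        gap, lo, hi = max(gaps)
        t = (lo + hi) / 2
        logger.info("auto distance threshold t=%.5f (largest gap %.5f)", t, gap)
    else:
        t = float(threshold)
        if t <= 0:
            raise PhyloError("threshold must be positive")
    g = nx.Graph()
    g.add_nodes_from(dm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if dm.matrix[i, j] < t:
                g.add_edge(dm.ids[i], dm.ids[j])
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def ladderized_tip_order(tree: dendropy.Tree) -> list[str]:
    """Leaf labels after ladderizing by clade size (ties by smallest id)."""
    t = tree.clone(depth=1)

    def sort_key(node):
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        return (len(leaves), leaves[0])

    for node in t.postorder_node_iter():
        if not node.is_leaf():
            node._child_nodes.sort(key=sort_key)
    return [lf.taxon.label for lf in t.leaf_node_iter()]
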