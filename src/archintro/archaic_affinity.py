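"""Archaic-affinity analyses: pairwise differences, allele-sharing tracks,
haplotype deduplication, nearest-archaic assignment, and a rooted
neighbor-joining tree with site-resampling bootstrap support.

The tree substitutes a distance method (NJ on Hamming counts, branch
lengths in differences per retained site) for likelihood inference; at the
scale of interest (tens of segregating sites, shallow divergence) the
topologies coincide for the clustering claims being tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from archintro.core_io import ANCESTRAL, HaplotypePanel


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-difference counts over a fixed site set."""

    labels: list[str]
    values: np.ndarray  # (n, n) float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def per_site(self, n_sites: int) -> "DistanceMatrix":
        """Distances normalized to differences per retained site."""
        if n_sites < 1:
            raise ValueError("n_sites must be positive")
        return DistanceMatrix(labels=list(self.labels), values=self.values / n_sites)


def pairwise_differences(hap_a: np.ndarray, hap_b: np.ndarray) -> int:
    """Hamming count between two missing-free allele vectors."""
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("haplotypes must be missing-free")
    return int(np.count_nonzero(a != b))


def distance_matrix(alleles: np.ndarray, labels: list[str]) -> DistanceMatrix:
    """All-pairs Hamming counts for a 0/1 haplotype × site matrix."""
    X = np.asarray(alleles, dtype=np.float64)
    if np.any(X < 0):
        raise ValueError("allele matrix must be missing-free")
    # for 0/1 data: d(a,b) = sum a + sum b - 2 a.b
    g = X @ X.T
    s = X.sum(axis=1)
    D = s[:, None] + s[None, :] - 2 * g
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    return DistanceMatrix(labels=list(labels), values=np.round(D))


def panel_distance_matrix(panel: HaplotypePanel) -> DistanceMatrix:
    return distance_matrix(panel.alleles, panel.haplotype_ids)


def dedup_haplotypes(panel: HaplotypePanel) -> tuple[HaplotypePanel, dict[str, int]]:
    """Collapse identical haplotype rows, keeping first occurrences.

    Returns the deduplicated panel and a map from each kept haplotype id to
    its multiplicity (multiplicities sum to the original haplotype count).
    """
    if np.any(panel.alleles < 0):
        raise ValueError("panel must be missing-free before deduplication")
    seen: dict[bytes, str] = {}
    keep: list[int] = []
    counts: dict[str, int] = {}
    for i in range(panel.n_haplotypes):
        key = panel.alleles[i].tobytes()
        if key in seen:
            counts[seen[key]] += 1
        else:
            hid = panel.haplotype_ids[i]
            seen[key] = hid
            counts[hid] = 1
            keep.append(i)
    unique = HaplotypePanel(
        haplotype_ids=[panel.haplotype_ids[i] for i in keep],
        alleles=panel.alleles[keep, :],
        sites=list(panel.sites),
        group_labels=[panel.group_labels[i] for i in keep],
    )
    return unique, counts


@dataclass(frozen=True)
class NearestArchaic:
    labels: tuple[str, ...]  # argmin set (>1 on ties)
    count: int
    all_counts: dict[str, int]


def nearest_archaic(query_hap: np.ndarray, archaic_haps: dict[str, np.ndarray]) -> NearestArchaic:
    """Nearest archaic by Hamming distance; ties reported as a set."""
    if not archaic_haps:
        raise ValueError("need at least one archaic haplotype")
    counts = {label: pairwise_differences(query_hap, h) for label, h in archaic_haps.items()}
    best = min(counts.values())
    winners = tuple(sorted(label for label, c in counts.items() if c == best))
    return NearestArchaic(labels=winners, count=best, all_counts=counts)


def allele_sharing_track(
    panel: HaplotypePanel,
    group_a: list[str],
    group_b: list[str],
    archaic_id: str,
) -> pd.DataFrame:
    """Per-site table of whether the archaic allele is shared with each group.

    The group allele is the strict majority within the group; exact ties are
    flagged in ``tie_a``/``tie_b`` and the corresponding ``shared`` column is
    left NA rather than broken arbitrarily.
    """
    if not group_a or not group_b:
        raise ValueError("groups must be nonempty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    lookup = {h: i for i, h in enumerate(panel.haplotype_ids)}
    ia = [lookup[h] for h in group_a]
    ib = [lookup[h] for h in group_b]
    iarch = lookup[archaic_id]

    A = panel.alleles
    if np.any(A < 0):
        raise ValueError("panel must be missing-free; run filter_sites first")
    arch = A[iarch, :]

    def majority(rows):
        ones = (A[rows, :] == 1).sum(axis=0)
        n = len(rows)
        maj = np.where(ones * 2 > n, 1, 0)
        tie = ones * 2 == n
        return maj, tie

    maj_a, tie_a = majority(ia)
    maj_b, tie_b = majority(ib)

    shared_a = pd.array(maj_a == arch, dtype="boolean")
    shared_b = pd.array(maj_b == arch, dtype="boolean")
    shared_a[tie_a] = pd.NA
    shared_b[tie_b] = pd.NA

    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in panel.sites],
            "pos": panel.positions,
            "archaic_allele": arch,
            "shared_with_a": shared_a,
            "shared_with_b": shared_b,
            "tie_a": tie_a,
            "tie_b": tie_b,
        }
    )


# ---------------------------------------------------------------------------
# Neighbor joining with site-resampling bootstrap
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of a rooted tree; ``length`` is the edge to the parent."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.leaves())

    def to_newick(self, include_support: bool = True) -> str:
        return self._newick(include_support) + ";"

    def _newick(self, include_support: bool) -> str:
        if self.is_leaf:
            return f"{_quote(self.name)}:{self.length:.6g}"
        inner = ",".join(c._newick(include_support) for c in self.children)
        label = ""
        if include_support and self.support is not None:
            label = f"{self.support:.3g}"
        return f"({inner}){label}:{self.length:.6g}"


def _quote(name: str | None) -> str:
    name = name or ""
    if any(ch in name for ch in "(),:;' \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


@dataclass
class TreeResult:
    """Rooted NJ tree with per-internal-edge bootstrap support."""

    root: TreeNode
    labels: list[str]
    outgroup: str
    n_bootstrap: int = 0
    support: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def newick(self) -> str:
        return self.root.to_newick()

    def clade_support(self, taxa) -> float | None:
        """Bootstrap support of the split isolating exactly ``taxa`` (if present)."""
        return self.support.get(frozenset(taxa))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classic NJ (Saitou–Nei with the Studier–Keppler Q-criterion).

    Negative branch lengths are clamped to zero. The returned tree is the
    unrooted topology represented with an arbitrary binary root on the last
    joined edge; reroot on an outgroup for presentation.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.values.astype(np.float64).copy()
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]
    active = list(range(n))

    while len(active) > 2:
        k = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(Q)), k)
        i, j = idx[i_loc], idx[j_loc]

        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = li, lj
        parent.children = [ci, cj]

        # distances from the new node to every other active node
        for m_loc, m in enumerate(idx):
            if m in (i, j):
                continue
            d = 0.5 * (D[i, m] + D[j, m] - dij)
            D[i, m] = D[m, i] = max(d, 0.0)
        nodes[i] = parent
        active.remove(j)

    i, j = active
    root = TreeNode()
    half = max(D[i, j], 0.0) / 2.0
    nodes[i].length = half
    nodes[j].length = half
    root.children = [nodes[i], nodes[j]]
    return root


def reroot(root: TreeNode, outgroup: str) -> TreeNode:
    """Reroot an (effectively unrooted) binary tree on the outgroup's edge.

    The outgroup edge is split evenly between the outgroup and the rest of
    the tree.
    """
    # build parent links
    parent: dict[int, TreeNode | None] = {id(root): None}
    stack = [root]
    target = None
    while stack:
        node = stack.pop()
        if node.is_leaf and node.name == outgroup:
            target = node
        for c in node.children:
            parent[id(c)] = node
            stack.append(c)
    if target is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")

    # walk from target to old root, reversing edges
    path = [target]
    node = target
    while parent[id(node)] is not None:
        node = parent[id(node)]
        path.append(node)

    if len(path) == 1:  # already the root (degenerate)
        return root

    new_root = TreeNode()
    rest = path[1]
    rest.children = [c for c in rest.children if c is not target]

    if len(path) == 2 and len(rest.children) == 1:
        # outgroup hung directly off the (midpoint) NJ root: the true edge is
        # target.length + sibling.length
        sibling = rest.children[0]
        total = target.length + sibling.length
        target.length = total / 2.0
        sibling.length = total / 2.0
        new_root.children = [target, sibling]
        return new_root

    # reverse the chain above `rest`; edge lengths live on the child, so the
    # original lengths must be captured before they are overwritten
    lengths = [n.length for n in path]
    carry = rest
    for i, above in enumerate(path[2:], start=2):
        above.children = [c for c in above.children if c is not carry]
        carry.children.append(above)
        above.length = lengths[i - 1]
        carry = above
    # collapse the now-degree-1 old root left at the end of the chain
    _suppress_unifurcations(rest)

    half = target.length / 2.0
    target.length = half
    rest.length = half
    new_root.children = [target, rest]
    return new_root


def _suppress_unifurcations(node: TreeNode) -> None:
    for i, child in enumerate(list(node.children)):
        _suppress_unifurcations(child)
        if not child.is_leaf and len(child.children) == 1:
            grand = child.children[0]
            grand.length += child.length
            node.children[i] = grand


def _splits(root: TreeNode) -> set[frozenset[str]]:
    """Nontrivial bipartitions, each encoded as the leaf set under an edge."""
    all_leaves = root.leaf_names()
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            out.add(_canon(below, all_leaves))
        return below

    for c in root.children:
        walk(c)
    return out


def _canon(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    # canonical representative: lexicographically smaller of the two sides at equal
    # size, otherwise the smaller side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def nj_tree(
    dm: DistanceMatrix,
    outgroup_label: str,
    bootstrap: int = 0,
    seed: int | None = None,
    alleles: np.ndarray | None = None,
) -> TreeResult:
    """Rooted NJ tree with optional site-resampling bootstrap support.

    ``alleles`` (rows ordered as ``dm.labels``) is required when
    ``bootstrap > 0``: each replicate resamples site columns with
    replacement, rebuilds the Hamming distance matrix and the NJ tree, and
    support for each internal edge of the main tree is the fraction of
    replicates containing the same bipartition.
    """
    if outgroup_label not in dm.labels:
        raise ValueError(f"outgroup {outgroup_label!r} not among labels")
    root = reroot(neighbor_joining(dm), outgroup_label)
    result = TreeResult(
        root=root, labels=list(dm.labels), outgroup=outgroup_label, n_bootstrap=bootstrap
    )
    if bootstrap <= 0:
        return result
    if alleles is None:
        raise ValueError("site matrix required for bootstrap resampling")
    X = np.asarray(alleles)
    if X.shape[0] != len(dm.labels):
        raise ValueError("allele matrix rows must match distance-matrix labels")

    rng = np.random.default_rng(seed)
    main_splits = _splits(root)
    counts = {s: 0 for s in main_splits}
    n_sites = X.shape[1]
    for _ in range(bootstrap):
        cols = rng.integers(0, n_sites, size=n_sites)
        dm_b = distance_matrix(X[:, cols], dm.labels)
        root_b = reroot(neighbor_joining(dm_b), outgroup_label)
        for s in _splits(root_b):
            if s in counts:
                counts[s] += 1
    result.support = {s: c / bootstrap for s, c in counts.items()}
    _annotate_support(root, result.support, root.leaf_names())
    return result


def _annotate_support(root: TreeNode, support, universe) -> None:
    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        key = _canon(below, universe)
        if key in support:
            node.support = support[key]
        return below

    for c in root.children:
        walk(c)


def ancestral_haplotype(panel: HaplotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Inferred ancestral allele vector and the mask of sites where it is known.

    Sites with unknown ancestral state are excluded (mask False); callers
    should drop them before rooting a tree on the ancestral sequence.
    """
    known = np.array([s.ancestral_state != "unknown" for s in panel.sites])
    anc = np.array(
        [0 if s.ancestral_state == "ref" else 1 if s.ancestral_state == "alt" else -1
         for s in panel.sites],
        dtype=np.int8,
    )
    return anc, known


def panel_with_ancestral(panel: HaplotypePanel, label: str = "ancestral") -> HaplotypePanel:
    """Append the inferred ancestral sequence as an outgroup pseudo-haplotype.

    Sites with unknown ancestral state are dropped from every haplotype so
    the outgroup row is fully defined.
    """
    anc, known = ancestral_haplotype(panel)
    sub = panel.subset_sites(np.flatnonzero(known))
    return HaplotypePanel(
        haplotype_ids=list(sub.haplotype_ids) + [label],
        alleles=np.vstack([sub.alleles, anc[known][None, :]]),
        sites=list(sub.sites),
        group_labels=list(sub.group_labels) + [ANCESTRAL],
    )
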