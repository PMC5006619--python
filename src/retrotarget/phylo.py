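"""Desk-scale tree building: p-distances, neighbor joining, bootstrap.

Distances are amino-acid p-distances after complete gap deletion (every
column containing a gap or missing datum is removed before any distance
is computed).  Trees are built with the Saitou–Nei neighbor-joining
agglomeration; support values come from column bootstrap over the
retained sites.  Dendropy provides the tree container, rooting and
newick serialisation; the NJ agglomeration itself is implemented here
so tie-breaking and negative-branch clamping are fully specified.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

log = logging.getLogger(__name__)

MISSING = set("-X?.")


@dataclass
class DistanceMatrix:
    taxa: list
    d: np.ndarray
    n_sites_used: int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")


def _complete_deletion(rows: Sequence[Tuple[str, str]]) -> Tuple[list, np.ndarray]:
    taxa = [name for name, _ in rows]
    arr = np.array([list(seq.upper()) for _, seq in rows])
    keep = ~np.any(np.isin(arr, list(MISSING)), axis=0)
    return taxa, arr[:, keep]


def pdistance(rows: Sequence[Tuple[str, str]]) -> DistanceMatrix:
    """Pairwise p-distance after complete gap deletion.

    Requires >= 3 sequences of equal aligned length; raises if no
    columns survive deletion.
    """
    if len(rows) < 3:
        raise ValueError("need >= 3 sequences")
    if len({len(s) for _, s in rows}) != 1:
        raise ValueError("aligned sequences must have equal length")
    taxa, cols = _complete_deletion(rows)
    m = cols.shape[1]
    if m == 0:
        raise ValueError("no columns retained after complete gap deletion")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(cols[i] != cols[j])
    return DistanceMatrix(taxa=taxa, d=d, n_sites_used=m)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei NJ with the standard Q-criterion.

    Q-minimum ties resolve to the lexicographically smallest cluster
    pair (clusters named by their smallest leaf label); negative branch
    lengths are clamped to zero and the clamped amount logged.  Returns
    an unrooted dendropy tree (trifurcating seed node for n >= 3).
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    ns = dendropy.TaxonNamespace(list(D.taxa))
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for name in D.taxa:
        nd = dendropy.Node(taxon=ns.get_taxon(name))
        nodes.append(nd)
    keys = list(D.taxa)  # cluster names: smallest leaf label
    d = D.d.copy()
    active = list(range(n))
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and pair_key < best[1]):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        li = d[i, j] / 2 + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = clamp(li)
        parent.add_child(nodes[j])
        nodes[j].edge.length = clamp(lj)
        # replace cluster i with the new node, deactivate j
        for k in active:
            if k not in (i, j):
                d[i, k] = d[k, i] = (d[i, k] + d[j, k] - d[i, j]) / 2
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    root = tree.seed_node
    for idx, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(length)
    tree.is_rooted = False
    if clamped > 0:
        log.info("NJ clamped %.4g of negative branch length to zero", clamped)
    return tree


def bipartitions(tree: dendropy.Tree) -> Set[frozenset]:
    """Non-trivial bipartitions as canonical leaf-label frozensets.

    Each internal edge is represented by the side of the split that does
    not contain the lexicographically smallest taxon.
    """
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = labels[0]
    all_set = set(labels)
    out: Set[frozenset] = set()
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node or nd.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in nd.leaf_iter()}
        if len(below) <= 1 or len(below) >= len(all_set) - 1:
            continue
        side = below if ref not in below else all_set - below
        out.add(frozenset(side))
    return out


# ---------------------------------------------------------------------------
# bootstrap

def _pdist_from_cols(taxa: list, cols: np.ndarray) -> DistanceMatrix:
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(cols[i] != cols[j])
    return DistanceMatrix(taxa=taxa, d=d, n_sites_used=cols.shape[1])


def bootstrap(rows: Sequence[Tuple[str, str]], n_reps: int = 1000,
              seed: int = 0) -> dendropy.Tree:
    """NJ point tree with bootstrap support on internal edges.

    Columns are resampled with replacement after complete deletion;
    support is the percentage of replicates containing each internal
    bipartition of the point tree, attached as internal node labels.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa, cols = _complete_deletion(rows)
    if cols.shape[1] == 0:
        raise ValueError("no columns retained after complete gap deletion")
    point = neighbor_joining(_pdist_from_cols(taxa, cols))
    target = bipartitions(point)
    counts: Dict[frozenset, int] = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    m = cols.shape[1]
    for _ in range(n_reps):
        idx = rng.integers(0, m, size=m)
        rep = neighbor_joining(_pdist_from_cols(taxa, cols[:, idx]))
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    ref = sorted(t for t in taxa)[0]
    all_set = set(taxa)
    for nd in point.preorder_node_iter():
        if nd is point.seed_node or nd.is_leaf():
            continue
        below = {leaf.taxon.label for leaf in nd.leaf_iter()}
        side = below if ref not in below else all_set - below
        bp = frozenset(side)
        if bp in counts:
            nd.label = str(int(round(100.0 * counts[bp] / n_reps)))
    return point


# ---------------------------------------------------------------------------
# rooting

def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=False)
    t.is_rooted = True
    return t


def root_on(tree: dendropy.Tree, outgroup: Sequence[str]) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the rest.

    A single-taxon outgroup bisects its pendant edge.  A
    non-monophyletic outgroup draws a warning and the root goes on the
    edge that best separates outgroup from ingroup (the outgroup MRCA
    edge).
    """
    t = tree.clone(depth=1)
    t.is_rooted = True  # treat the seed as a provisional root for MRCA math
    outgroup = list(outgroup)
    labels = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    missing = [o for o in outgroup if o not in labels]
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {missing}")
    if len(outgroup) == 1:
        leaf = next(l for l in t.leaf_node_iter() if l.taxon.label == outgroup[0])
        L = leaf.edge.length or 0.0
        t.reroot_at_edge(leaf.edge, length1=L / 2, length2=L / 2,
                         update_bipartitions=False)
    else:
        mrca = t.mrca(taxon_labels=outgroup)
        if mrca is t.seed_node:
            # outgroup spans the current (arbitrary) root; root on the
            # ingroup MRCA edge instead, which separates the two sets
            ingroup = sorted(labels - set(outgroup))
            mrca = t.mrca(taxon_labels=ingroup)
        below = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        if below not in (set(outgroup), labels - set(outgroup)):
            log.warning("outgroup not monophyletic; rooting on the edge "
                        "maximizing outgroup separation")
        L = mrca.edge.length or 0.0
        t.reroot_at_edge(mrca.edge, length1=L / 2, length2=L / 2,
                         update_bipartitions=False)
    t.is_rooted = True
    return t
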